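"""Mass-action equilibrium speciation and the light-scattering forward model.

A :class:`BindingModel` holds two monomer species — the SK2 CaM-binding
peptide (``P``, SKp) and a calmodulin construct (``C``) — plus a set of
complex stoichiometries ``PiCj`` with overall association constants
``K_A = [PiCj] / ([P]^i [C]^j)`` (reference state 1 M, reported as log10).
:func:`solve_speciation` finds the free monomer concentrations satisfying
both mass-conservation equations, and the weight-average molar mass

    M_w = sum_k n_k M_k^2 / sum_k n_k M_k

over every free and complexed species is what composition-gradient
multi-angle light scattering (CG-MALS) measures at each mixing ratio.

The solver works in log-free-concentration space (variables ln[P], ln[C])
with damped Newton iteration, so association constants spanning tens of
decades never underflow; a nested-bisection fallback handles the rare
stalled case.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

__all__ = [
    "MonomerSpecies",
    "ComplexSpec",
    "BindingModel",
    "Composition",
    "SpeciationState",
    "OpticalConstants",
    "complex_label",
    "solve_speciation",
    "weight_average_mass",
    "kstar",
    "excess_rayleigh",
    "mw_from_rayleigh",
    "mole_fraction_curves",
    "no_interaction_mw",
    "SpeciationError",
]

_EXP_CLIP = 350.0  # exp() guard: products of two clipped terms stay finite


class SpeciationError(RuntimeError):
    """Raised when the equilibrium solver fails to satisfy conservation."""

    def __init__(self, message: str, residuals: tuple[float, float] | None = None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class MonomerSpecies:
    name: str
    molar_mass: float  # kDa

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar mass must be > 0")


@dataclass(frozen=True)
class ComplexSpec:
    """Stoichiometry (i peptides, j CaMs) with overall log10 K_A.

    K_A has units M^(1-i-j); ``i + j >= 2`` so every entry is a true complex.
    """

    n_peptide: int
    n_cam: int
    log10_KA: float

    def __post_init__(self) -> None:
        if self.n_peptide < 0 or self.n_cam < 0 or self.n_peptide + self.n_cam < 2:
            raise ValueError("complex needs i >= 0, j >= 0, i + j >= 2")
        if not math.isfinite(self.log10_KA):
            raise ValueError("log10_KA must be finite")

    @property
    def key(self) -> tuple[int, int]:
        return (self.n_peptide, self.n_cam)


_NAMED_COMPLEXES = {(1, 1): "P-C", (2, 1): "P-C-P", (1, 2): "C-P-C", (2, 2): "2xP-C"}


def complex_label(i: int, j: int) -> str:
    """Human-readable label for a stoichiometry ((2,1) -> 'P-C-P' etc.)."""
    return _NAMED_COMPLEXES.get((i, j), f"{i}P{j}C")


@dataclass(frozen=True)
class BindingModel:
    peptide: MonomerSpecies
    cam: MonomerSpecies
    complexes: tuple[ComplexSpec, ...]
    condition_label: str = ""

    def __post_init__(self) -> None:
        keys = [c.key for c in self.complexes]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate complex stoichiometries in model")

    def complex_mass(self, i: int, j: int) -> float:
        """Molar mass of the PiCj complex, kDa."""
        return i * self.peptide.molar_mass + j * self.cam.molar_mass

    def with_constants(self, log10_kas: Mapping[tuple[int, int], float]) -> "BindingModel":
        """Copy of the model with some log10 K_A values replaced."""
        new = tuple(
            replace(c, log10_KA=log10_kas.get(c.key, c.log10_KA))
            for c in self.complexes
        )
        return replace(self, complexes=new)

    def to_json(self) -> str:
        return json.dumps(
            {
                "peptide": {"name": self.peptide.name, "mass_kda": self.peptide.molar_mass},
                "cam": {"name": self.cam.name, "mass_kda": self.cam.molar_mass},
                "complexes": [
                    {"i": c.n_peptide, "j": c.n_cam, "log10_KA": c.log10_KA}
                    for c in self.complexes
                ],
                "condition": self.condition_label,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BindingModel":
        d = json.loads(text)
        return cls(
            peptide=MonomerSpecies(d["peptide"]["name"], d["peptide"]["mass_kda"]),
            cam=MonomerSpecies(d["cam"]["name"], d["cam"]["mass_kda"]),
            complexes=tuple(
                ComplexSpec(c["i"], c["j"], c["log10_KA"]) for c in d["complexes"]
            ),
            condition_label=d.get("condition", ""),
        )


@dataclass(frozen=True)
class Composition:
    """Total (analytic) monomer concentrations at one gradient point, mol/L."""

    peptide_total: float
    cam_total: float

    def __post_init__(self) -> None:
        if self.peptide_total < 0 or self.cam_total < 0:
            raise ValueError("total concentrations must be >= 0")


@dataclass(frozen=True)
class SpeciationState:
    """Solved free/complex concentrations (mol/L) and derived M_w (kDa)."""

    free_peptide: float
    free_cam: float
    complex_concentrations: Mapping[tuple[int, int], float]
    m_w: float
    model: BindingModel

    def species(self) -> list[tuple[str, float, float]]:
        """(label, molar mass kDa, concentration M) for every species."""
        out = [
            ("P", self.model.peptide.molar_mass, self.free_peptide),
            ("C", self.model.cam.molar_mass, self.free_cam),
        ]
        for (i, j), conc in self.complex_concentrations.items():
            out.append((complex_label(i, j), self.model.complex_mass(i, j), conc))
        return out


@dataclass(frozen=True)
class OpticalConstants:
    """Light-scattering optical constants for the K* prefactor.

    dn/dc in ml/g, wavelength in nm (converted to cm internally, CGS
    convention).  ``form_factor`` is P(theta), fixed at 1 in the small-
    particle regime used throughout.
    """

    dn_dc: float = 0.186
    n0: float = 1.33
    lambda0_nm: float = 660.0
    form_factor: float = 1.0
    avogadro: float = Avogadro

    def __post_init__(self) -> None:
        if self.dn_dc < 0 or self.n0 < 1 or self.lambda0_nm <= 0:
            raise ValueError("invalid optical constants")


def _terms(
    model: BindingModel, x: float, y: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complex concentrations and stoichiometry vectors at ln-free (x, y)."""
    ii = np.array([c.n_peptide for c in model.complexes], dtype=float)
    jj = np.array([c.n_cam for c in model.complexes], dtype=float)
    lnk = np.array([c.log10_KA * math.log(10.0) for c in model.complexes])
    ln_conc = np.clip(lnk + ii * x + jj * y, -_EXP_CLIP, _EXP_CLIP)
    return ii, jj, np.exp(ln_conc)


def _residuals(model, x, y, p_tot, c_tot):
    ii, jj, conc = _terms(model, x, y)
    p, c = math.exp(min(x, _EXP_CLIP)), math.exp(min(y, _EXP_CLIP))
    f1 = p + float(np.dot(ii, conc)) - p_tot
    f2 = c + float(np.dot(jj, conc)) - c_tot
    return f1, f2, ii, jj, conc, p, c


def _solve_1d(model, total, which: Literal["p", "c"], tol: float) -> float:
    """Solve a single-monomer system (the other total is zero), returns ln conc."""
    # only complexes made purely of this monomer can form
    if which == "p":
        subs = [(c.n_peptide, c.log10_KA) for c in model.complexes if c.n_cam == 0]
    else:
        subs = [(c.n_cam, c.log10_KA) for c in model.complexes if c.n_peptide == 0]
    if not subs or total == 0.0:
        return math.log(total) if total > 0 else -math.inf

    def g(z: float) -> float:
        s = math.exp(z)
        for n, logk in subs:
            s += n * math.exp(min(logk * math.log(10.0) + n * z, _EXP_CLIP))
        return s - total

    hi = math.log(total)
    lo = _bracket_lo(model, hi)
    for _ in range(260):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
        if abs(g(mid)) <= tol * total:
            return mid
    return 0.5 * (lo + hi)


def _bracket_lo(model, hi: float) -> float:
    """Lower log-concentration bound guaranteed to bracket the root.

    Large association constants push free concentrations far below the
    totals; extend the bracket by the largest ln K so K p^i c^j can always
    be driven under the totals within it.
    """
    lnk_max = max(
        (c.log10_KA * math.log(10.0) for c in model.complexes), default=0.0
    )
    return hi - 200.0 - max(0.0, lnk_max)


def _bisection_fallback(model, p_tot, c_tot, tol) -> tuple[float, float]:
    """Nested bisection on the two conservation equations, in log space."""

    def p_of_c(y: float) -> float:
        hi = math.log(p_tot)
        lo = _bracket_lo(model, hi)

        def f1(x: float) -> float:
            f1v, _, *_ = _residuals(model, x, y, p_tot, c_tot)
            return f1v

        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f1(mid) > 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    y_hi = math.log(c_tot)
    y_lo = _bracket_lo(model, y_hi)
    for _ in range(260):
        y_mid = 0.5 * (y_lo + y_hi)
        x_mid = p_of_c(y_mid)
        _, f2v, *_ = _residuals(model, x_mid, y_mid, p_tot, c_tot)
        if f2v > 0:
            y_hi = y_mid
        else:
            y_lo = y_mid
    y = 0.5 * (y_lo + y_hi)
    return p_of_c(y), y


def solve_speciation(
    model: BindingModel,
    comp: Composition,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> SpeciationState:
    """Solve mass-action equilibrium at one composition.

    Returns the free monomer concentrations, each complex concentration
    ``[PiCj] = K_ij [P]^i [C]^j``, and the weight-average molar mass.  Both
    conservation equations are satisfied to relative tolerance ``tol``.
    Deterministic: no randomness, fixed initial guess (free = totals).
    """
    p_tot, c_tot = comp.peptide_total, comp.cam_total

    # degenerate axes: one or both totals zero
    if p_tot == 0.0 and c_tot == 0.0:
        return _finish(model, -math.inf, -math.inf, p_tot, c_tot)
    if p_tot == 0.0:
        y = _solve_1d(model, c_tot, "c", tol)
        return _finish(model, -math.inf, y, p_tot, c_tot)
    if c_tot == 0.0:
        x = _solve_1d(model, p_tot, "p", tol)
        return _finish(model, x, -math.inf, p_tot, c_tot)

    x, y = math.log(p_tot), math.log(c_tot)
    f1, f2, ii, jj, conc, p, c = _residuals(model, x, y, p_tot, c_tot)

    def norm(f1: float, f2: float) -> float:
        return max(abs(f1) / p_tot, abs(f2) / c_tot)

    res = norm(f1, f2)
    for _ in range(max_iter):
        if res <= tol:
            return _finish(model, x, y, p_tot, c_tot)
        # Newton step for the Jacobian wrt (ln p, ln c),
        #   J = diag(p, c) + sum_k T_k (i_k, j_k)(i_k, j_k)^T,
        # written in cancellation-free form: the naive det and numerators
        # subtract near-equal O(T^2) products when one complex dominates
        # (J is then nearly rank one), so the Cauchy-Schwarz-type pair sums
        # below — exactly zero for a single complex — are used instead.
        s20 = float(np.dot(ii * ii, conc))
        s02 = float(np.dot(jj * jj, conc))
        # pairwise terms: sum_{a<b} T_a T_b * (cross-stoichiometry factors)
        q_det = q_x = q_y = 0.0
        n_cx = conc.size
        for a in range(n_cx):
            for b in range(a + 1, n_cx):
                tt = conc[a] * conc[b]
                cross = ii[a] * jj[b] - ii[b] * jj[a]
                q_det += tt * cross * cross
                q_x += tt * (jj[a] - jj[b]) * (ii[b] * jj[a] - ii[a] * jj[b])
                q_y += tt * (ii[a] - ii[b]) * (jj[b] * ii[a] - jj[a] * ii[b])
        det = p * c + p * s02 + c * s20 + q_det
        if det <= 0 or not math.isfinite(det):
            break
        n_x = (
            p * c
            - c * p_tot
            + p * s02
            + c * float(np.dot(ii * (1.0 - jj), conc))
            + q_x
            + float(np.dot(jj * (ii * c_tot - jj * p_tot), conc))
        )
        n_y = (
            p * c
            - p * c_tot
            + c * s20
            + p * float(np.dot(jj * (1.0 - ii), conc))
            + q_y
            + float(np.dot(ii * (jj * p_tot - ii * c_tot), conc))
        )
        dx = -n_x / det
        dy = -n_y / det
        # trust region in log space: huge steps mean the local model is junk
        biggest = max(abs(dx), abs(dy))
        if biggest > 50.0:
            dx, dy = dx * 50.0 / biggest, dy * 50.0 / biggest
        # damping: halve the step until the residual norm decreases
        step = 1.0
        for _ in range(60):
            xn, yn = x + step * dx, y + step * dy
            f1n, f2n, iin, jjn, concn, pn, cn = _residuals(
                model, xn, yn, p_tot, c_tot
            )
            if norm(f1n, f2n) < res:
                x, y, f1, f2, ii, jj, conc, p, c = (
                    xn, yn, f1n, f2n, iin, jjn, concn, pn, cn,
                )
                res = norm(f1, f2)
                break
            step *= 0.5
        else:
            break  # Newton stalled -> bisection fallback

    if res > tol:
        x, y = _bisection_fallback(model, p_tot, c_tot, tol)
        f1, f2, *_ = _residuals(model, x, y, p_tot, c_tot)
        res = norm(f1, f2)
        if res > max(tol, 1e-7):
            raise SpeciationError(
                f"speciation did not converge (relative residual {res:.3g})",
                residuals=(f1, f2),
            )
    return _finish(model, x, y, p_tot, c_tot)


def _finish(model, x, y, p_tot, c_tot) -> SpeciationState:
    p = math.exp(x) if math.isfinite(x) else 0.0
    c = math.exp(y) if math.isfinite(y) else 0.0
    concs: dict[tuple[int, int], float] = {}
    for spec in model.complexes:
        i, j = spec.key
        if (i > 0 and p == 0.0) or (j > 0 and c == 0.0):
            concs[(i, j)] = 0.0
        else:
            ln = spec.log10_KA * math.log(10.0) + i * (x if i else 0.0) + j * (y if j else 0.0)
            concs[(i, j)] = math.exp(min(ln, _EXP_CLIP))
    state = SpeciationState(
        free_peptide=p,
        free_cam=c,
        complex_concentrations=concs,
        m_w=float("nan"),
        model=model,
    )
    if p_tot > 0 or c_tot > 0:
        state = replace(state, m_w=weight_average_mass(state))
    return state


def weight_average_mass(state: SpeciationState) -> float:
    """Weight-average molar mass over all species, kDa.

    M_w = sum n_k M_k^2 / sum n_k M_k with n_k molar concentrations; this is
    the mass light scattering reports in the P(theta) = 1 regime.
    """
    num = den = 0.0
    for _, mass, conc in state.species():
        num += conc * mass * mass
        den += conc * mass
    if den == 0.0:
        raise ValueError("all-zero composition: M_w undefined")
    return num / den


def kstar(optics: OpticalConstants) -> float:
    """Optical prefactor K* = 4 pi^2 (dn/dc)^2 n0^2 / (N_A lambda0^2).

    Evaluated exactly as written, in CGS units: dn/dc in ml/g, lambda0
    converted to cm.  Note K* cancels in the simulate -> invert round trip
    (``mw_from_rayleigh(excess_rayleigh(s), w_tot)``), so every M_w result
    in this package is independent of the prefactor convention.
    """
    lam_cm = optics.lambda0_nm * 1e-7
    return (
        4.0
        * math.pi**2
        * optics.dn_dc**2
        * optics.n0**2
        / (optics.avogadro * lam_cm**2)
    )


def _mass_concentrations(state: SpeciationState) -> list[tuple[float, float]]:
    """(molar mass g/mol, mass concentration g/ml) per species."""
    out = []
    for _, mass_kda, conc in state.species():
        m_g_mol = mass_kda * 1000.0
        w_g_ml = conc * m_g_mol / 1000.0  # mol/L * g/mol -> g/L -> g/ml
        out.append((m_g_mol, w_g_ml))
    return out


def excess_rayleigh(state: SpeciationState, optics: OpticalConstants) -> float:
    """Excess Rayleigh ratio R(theta, c) = K* P(theta) sum_k w_k M_k."""
    ks = kstar(optics)
    return optics.form_factor * ks * sum(m * w for m, w in _mass_concentrations(state))


def mw_from_rayleigh(
    rayleigh: float, total_mass_concentration_g_ml: float, optics: OpticalConstants
) -> float:
    """Invert the Rayleigh ratio to M_w (kDa): M = R / (P(theta) K* c)."""
    if total_mass_concentration_g_ml <= 0:
        raise ValueError("total mass concentration must be > 0")
    ks = kstar(optics)
    m_g_mol = rayleigh / (optics.form_factor * ks * total_mass_concentration_g_ml)
    return m_g_mol / 1000.0


def no_interaction_mw(model: BindingModel, comp: Composition) -> float:
    """M_w if nothing binds: the monomers-only reference curve."""
    empty = replace(model, complexes=())
    return solve_speciation(empty, comp).m_w


_BASES = ("particle_molar", "peptide_monomer", "cam_monomer")


def mole_fraction_curves(
    model: BindingModel,
    gradient: Sequence[Composition],
    basis: str = "particle_molar",
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Per-species fraction at every gradient point.

    ``basis`` chooses the normalization: ``particle_molar`` divides each
    species' molar concentration by the total particle concentration;
    ``peptide_monomer`` (resp. ``cam_monomer``) apportions total peptide
    (CaM) monomers among the species carrying them.  Fractions are >= 0 and
    sum to 1 at every point.
    """
    if basis not in _BASES:
        raise ValueError(f"basis must be one of {_BASES}")
    if len(gradient) == 0:
        raise ValueError("empty gradient")
    rows = []
    for comp in gradient:
        state = solve_speciation(model, comp, tol=tol)
        entries: dict[str, float] = {}
        if basis == "particle_molar":
            total = state.free_peptide + state.free_cam + sum(
                state.complex_concentrations.values()
            )
            entries["P"] = state.free_peptide / total if total else 0.0
            entries["C"] = state.free_cam / total if total else 0.0
            for (i, j), conc in state.complex_concentrations.items():
                entries[complex_label(i, j)] = conc / total if total else 0.0
        else:
            total = (
                comp.peptide_total if basis == "peptide_monomer" else comp.cam_total
            )
            weight = (lambda i, j: i) if basis == "peptide_monomer" else (lambda i, j: j)
            free = (
                state.free_peptide if basis == "peptide_monomer" else state.free_cam
            )
            entries["P" if basis == "peptide_monomer" else "C"] = (
                free / total if total else 0.0
            )
            for (i, j), conc in state.complex_concentrations.items():
                entries[complex_label(i, j)] = (
                    weight(i, j) * conc / total if total else 0.0
                )
        entries["peptide_total_M"] = comp.peptide_total
        entries["cam_total_M"] = comp.cam_total
        rows.append(entries)
    return pd.DataFrame(rows).fillna(0.0)
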