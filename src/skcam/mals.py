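"""Cross-over gradient construction and association-constant fitting.

A cross-over CG-MALS experiment steps from peptide excess to CaM excess by
mixing two protein stocks in varying volume fractions; at each step the
instrument reports a weight-average molar mass.  This module builds such
gradients, fits the per-complex ``log10 K_A`` values by Levenberg–Marquardt
least squares against the equilibrium forward model, profiles the residual
surface to flag constants outside the detection limit, compares candidate
stoichiometry sets by parsimony, and aggregates independent trials into
"mean (standard error) n" summaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd

from .binding import (
    BindingModel,
    ComplexSpec,
    Composition,
    MonomerSpecies,
    complex_label,
    solve_speciation,
)

__all__ = [
    "Gradient",
    "MALSDataset",
    "FitResult",
    "ProfileResult",
    "TrialSummary",
    "build_crossover_gradient",
    "predict_mw",
    "fit_association_constants",
    "detection_limit_scan",
    "compare_models",
    "aggregate_trials",
]

#: default grid of stock volume fractions (peptide stock share)
DEFAULT_F_RANGE = (0.05, 0.95)
DEFAULT_N_STEPS = 41

#: accept a smaller candidate model if its RSS is within this factor of the best
MODEL_TOLERANCE_FACTOR = 1.05

#: a parameter is unconstrained if the RSS profile stays within threshold of its
#: minimum over at least this many log10 units
FLAT_SPAN_LOG_UNITS = 2.0


def mg_ml_to_molar(mg_ml: float, mass_kda: float) -> float:
    """mg/ml (= g/L) to mol/L given the monomer molar mass in kDa."""
    return mg_ml / (mass_kda * 1000.0)


@dataclass(frozen=True)
class Gradient:
    """Mixing series between a peptide stock and a CaM stock.

    ``fractions`` are volume fractions of the peptide stock, strictly
    monotonic; each step's composition is the convex combination
    ``f * stock_P + (1 - f) * stock_C`` expressed in molar units.
    """

    peptide: MonomerSpecies
    cam: MonomerSpecies
    stock_peptide_mg_ml: float
    stock_cam_mg_ml: float
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions)
        if len(f) < 3:
            raise ValueError("gradient needs at least 3 steps")
        if not (np.all(np.diff(f) > 0) or np.all(np.diff(f) < 0)):
            raise ValueError("fractions must be strictly monotonic")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.stock_peptide_mg_ml <= 0 or self.stock_cam_mg_ml <= 0:
            raise ValueError("degenerate stock (zero concentration)")

    @property
    def stock_peptide_molar(self) -> float:
        return mg_ml_to_molar(self.stock_peptide_mg_ml, self.peptide.molar_mass)

    @property
    def stock_cam_molar(self) -> float:
        return mg_ml_to_molar(self.stock_cam_mg_ml, self.cam.molar_mass)

    def compositions(self) -> list[Composition]:
        return [
            Composition(
                peptide_total=f * self.stock_peptide_molar,
                cam_total=(1.0 - f) * self.stock_cam_molar,
            )
            for f in self.fractions
        ]

    def molar_ratio_cam_to_peptide(self) -> np.ndarray:
        comps = self.compositions()
        with np.errstate(divide="ignore"):
            return np.array(
                [
                    c.cam_total / c.peptide_total if c.peptide_total else np.inf
                    for c in comps
                ]
            )


def build_crossover_gradient(
    stock_peptide_mg_ml: float,
    stock_cam_mg_ml: float,
    peptide: MonomerSpecies,
    cam: MonomerSpecies,
    n_steps: int = DEFAULT_N_STEPS,
    f_min: float = DEFAULT_F_RANGE[0],
    f_max: float = DEFAULT_F_RANGE[1],
) -> Gradient:
    """Linear-in-volume-fraction cross-over gradient.

    The default 41 steps over f in [0.05, 0.95] span CaM:SKp molar ratios of
    roughly 0.07 to 12 for the standard 0.096/0.09 mg/ml stocks, covering
    peptide excess, the equimolar point, and CaM excess in one series.
    """
    if not 0 <= f_min < f_max <= 1:
        raise ValueError("need 0 <= f_min < f_max <= 1")
    if n_steps < 3:
        raise ValueError("n_steps must be >= 3")
    fractions = tuple(np.linspace(f_min, f_max, n_steps))
    return Gradient(
        peptide=peptide,
        cam=cam,
        stock_peptide_mg_ml=stock_peptide_mg_ml,
        stock_cam_mg_ml=stock_cam_mg_ml,
        fractions=fractions,
    )


@dataclass
class MALSDataset:
    """Measured (or simulated) M_w per gradient step, with replicates.

    ``measured_mw`` has shape (n_steps, n_replicates) in kDa.  ``sem_mw``
    is the per-step standard error (may be None).  ``incompetent_fraction``
    is reserved for a non-participating protein fraction; the analysis here
    never fits it and it defaults to None.
    """

    gradient: Gradient
    measured_mw: np.ndarray
    sem_mw: np.ndarray | None = None
    condition_label: str = ""
    incompetent_fraction: float | None = None

    def __post_init__(self) -> None:
        mw = np.atleast_2d(np.asarray(self.measured_mw, dtype=float))
        if mw.shape[0] != len(self.gradient.fractions):
            mw = mw.T
        if mw.shape[0] != len(self.gradient.fractions):
            raise ValueError("measured_mw row count must match gradient steps")
        if np.any(mw <= 0):
            raise ValueError("measured_mw must be positive")
        self.measured_mw = mw
        if self.sem_mw is not None:
            sem = np.asarray(self.sem_mw, dtype=float)
            if sem.shape != (mw.shape[0],) or np.any(sem < 0):
                raise ValueError("sem_mw must be one non-negative value per step")
            self.sem_mw = sem

    @property
    def n_replicates(self) -> int:
        return self.measured_mw.shape[1]

    def to_frame(self) -> pd.DataFrame:
        comps = self.gradient.compositions()
        ratios = self.gradient.molar_ratio_cam_to_peptide()
        rows = []
        for s, (f, comp) in enumerate(zip(self.gradient.fractions, comps)):
            for r in range(self.n_replicates):
                rows.append(
                    {
                        "step_index": s,
                        "f": f,
                        "peptide_total_uM": comp.peptide_total * 1e6,
                        "cam_total_uM": comp.cam_total * 1e6,
                        "molar_ratio_cam_to_peptide": ratios[s],
                        "replicate": r,
                        "mw_kda": self.measured_mw[s, r],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        peptide: MonomerSpecies,
        cam: MonomerSpecies,
        stock_peptide_mg_ml: float,
        stock_cam_mg_ml: float,
        condition_label: str = "",
    ) -> "MALSDataset":
        df = pd.read_csv(path)
        steps = np.sort(df["step_index"].unique())
        fractions = tuple(
            float(df.loc[df.step_index == s, "f"].iloc[0]) for s in steps
        )
        gradient = Gradient(
            peptide=peptide,
            cam=cam,
            stock_peptide_mg_ml=stock_peptide_mg_ml,
            stock_cam_mg_ml=stock_cam_mg_ml,
            fractions=fractions,
        )
        pivot = df.pivot_table(
            index="step_index", columns="replicate", values="mw_kda"
        ).loc[steps]
        return cls(
            gradient=gradient,
            measured_mw=pivot.to_numpy(),
            condition_label=condition_label,
        )


def predict_mw(
    model: BindingModel, gradient: Gradient, tol: float = 1e-9
) -> np.ndarray:
    """Forward-model M_w (kDa) at every gradient step."""
    return np.array(
        [solve_speciation(model, comp, tol=tol).m_w for comp in gradient.compositions()]
    )


@dataclass
class FitResult:
    """Outcome of a Levenberg–Marquardt association-constant fit."""

    log10_ka: dict[tuple[int, int], float]
    fixed: frozenset[tuple[int, int]]
    success: bool
    rss: float
    message: str
    stderr: dict[tuple[int, int], float | None]
    unconstrained: dict[tuple[int, int], bool]
    model: BindingModel
    nfev: int = 0

    def free_parameters(self) -> list[tuple[int, int]]:
        return [k for k in self.log10_ka if k not in self.fixed]

    def to_json(self) -> str:
        return json.dumps(
            {
                "log10_ka": {
                    complex_label(i, j): v for (i, j), v in self.log10_ka.items()
                },
                "fixed": sorted(complex_label(i, j) for i, j in self.fixed),
                "success": self.success,
                "rss": self.rss,
                "stderr": {
                    complex_label(i, j): v for (i, j), v in self.stderr.items()
                },
                "unconstrained": {
                    complex_label(i, j): v for (i, j), v in self.unconstrained.items()
                },
                "message": self.message,
            },
            indent=2,
        )


def _param_name(key: tuple[int, int]) -> str:
    return f"logka_{key[0]}_{key[1]}"


def _residual_fn(data: MALSDataset, template: BindingModel, weights: np.ndarray | None):
    keys = [c.key for c in template.complexes]

    def residual(params: lmfit.Parameters) -> np.ndarray:
        model = template.with_constants(
            {k: params[_param_name(k)].value for k in keys}
        )
        pred = predict_mw(model, data.gradient)
        resid = data.measured_mw - pred[:, None]
        if weights is not None:
            resid = resid * weights[:, None]
        return resid.ravel()

    return residual


def fit_association_constants(
    data: MALSDataset,
    model_spec: Sequence[tuple[int, int]],
    fixed: Mapping[tuple[int, int], float] | None = None,
    init: Mapping[tuple[int, int], float] | None = None,
    bounds: Mapping[tuple[int, int], tuple[float, float]] | None = None,
    weight_by_sem: bool = False,
    condition_label: str | None = None,
) -> FitResult:
    """Fit log10 K_A for each stoichiometry in ``model_spec`` to the data.

    Minimizes the sum over steps and replicates of (measured M_w - model
    M_w)^2 by Levenberg-Marquardt (lmfit/MINPACK ``leastsq``).  Entries of
    ``fixed`` are held at the given value; ``init`` sets starting values for
    free parameters (default 6.0); ``bounds`` optionally constrains them.
    Deterministic for fixed data and starting values.
    """
    if not model_spec:
        spec_complexes: tuple[ComplexSpec, ...] = ()
    else:
        fixed = dict(fixed or {})
        init = dict(init or {})
        for k in list(fixed) + list(init):
            if k not in model_spec:
                raise ValueError(f"fixed/init key {k} not in model_spec")
        spec_complexes = tuple(
            ComplexSpec(i, j, fixed.get((i, j), init.get((i, j), 6.0)))
            for i, j in model_spec
        )
    template = BindingModel(
        peptide=data.gradient.peptide,
        cam=data.gradient.cam,
        complexes=spec_complexes,
        condition_label=condition_label or data.condition_label,
    )
    fixed = dict(fixed or {})
    free_keys = [k for k in (model_spec or []) if k not in fixed]

    if not free_keys:
        # nothing to optimize: evaluate the (possibly empty) model as-is
        pred = predict_mw(template, data.gradient)
        rss = float(np.sum((data.measured_mw - pred[:, None]) ** 2))
        return FitResult(
            log10_ka={c.key: c.log10_KA for c in template.complexes},
            fixed=frozenset(fixed),
            success=True,
            rss=rss,
            message="no free parameters",
            stderr={c.key: None for c in template.complexes},
            unconstrained={c.key: False for c in template.complexes},
            model=template,
        )

    params = lmfit.Parameters()
    bounds = dict(bounds or {})
    for c in template.complexes:
        # default box keeps LM exploration inside the physically meaningful
        # range (K_A between 1e-5 and 1e40 M^(1-i-j))
        lo, hi = bounds.get(c.key, (-5.0, 40.0))
        params.add(
            _param_name(c.key),
            value=c.log10_KA,
            vary=c.key not in fixed,
            min=lo,
            max=hi,
        )
    weights = None
    if weight_by_sem and data.sem_mw is not None:
        weights = 1.0 / np.where(data.sem_mw > 0, data.sem_mw, np.inf)

    out = lmfit.minimize(
        _residual_fn(data, template, weights), params, method="leastsq"
    )
    estimates = {
        c.key: float(out.params[_param_name(c.key)].value) for c in template.complexes
    }
    stderr = {
        c.key: (
            float(out.params[_param_name(c.key)].stderr)
            if out.params[_param_name(c.key)].stderr is not None
            else None
        )
        for c in template.complexes
    }
    # a singular Jacobian leaves lmfit without error estimates: flag, don't hide
    unconstrained = {
        k: (k not in fixed and stderr[k] is None) for k in estimates
    }
    fitted_model = template.with_constants(estimates)
    rss = float(np.sum((data.measured_mw - predict_mw(fitted_model, data.gradient)[:, None]) ** 2))
    return FitResult(
        log10_ka=estimates,
        fixed=frozenset(fixed),
        success=bool(out.success),
        rss=rss,
        message=str(out.message),
        stderr=stderr,
        unconstrained=unconstrained,
        model=fitted_model,
        nfev=int(out.nfev),
    )


@dataclass
class ProfileResult:
    """RSS profile of one log10 K_A parameter (others re-minimized)."""

    parameter: tuple[int, int]
    grid: np.ndarray
    rss: np.ndarray
    threshold: float
    flat_span: float
    unconstrained: bool


def _rss_threshold(data: MALSDataset, resolution_cv: float) -> float:
    """RSS change considered indistinguishable from measurement error.

    One resolution_cv-sized relative deviation per observation; with the
    2% default this is the proportional-noise floor of the instrument.
    """
    return float(np.sum((resolution_cv * data.measured_mw) ** 2))


def detection_limit_scan(
    data: MALSDataset,
    fit: FitResult,
    parameter: tuple[int, int],
    grid: Sequence[float],
    resolution_cv: float = 0.02,
) -> ProfileResult:
    """Profile the RSS over ``grid`` values of one parameter.

    At each grid value the parameter is fixed and the remaining free
    parameters are re-minimized.  If the profile stays within the
    measurement-resolution threshold of its minimum over a contiguous span
    of at least 2 log10 units, the parameter is flagged as unconstrained
    (outside the detection limit) both in the returned profile and on the
    input ``fit``.
    """
    if parameter not in fit.log10_ka:
        raise ValueError(f"parameter {parameter} not in fit")
    grid = np.asarray(sorted(grid), dtype=float)
    spec = list(fit.log10_ka)
    rss = []
    for value in grid:
        fixed = {parameter: float(value)}
        for k in fit.fixed:
            fixed[k] = fit.log10_ka[k]
        sub = fit_association_constants(
            data,
            model_spec=spec,
            fixed=fixed,
            init={k: fit.log10_ka[k] for k in spec if k not in fixed},
        )
        rss.append(sub.rss)
    rss = np.asarray(rss)
    threshold = _rss_threshold(data, resolution_cv)
    within = rss <= rss.min() + threshold
    # longest contiguous flat span, in log units
    flat_span = 0.0
    start = None
    for idx, ok in enumerate(within):
        if ok and start is None:
            start = idx
        if (not ok or idx == len(within) - 1) and start is not None:
            end = idx if ok else idx - 1
            flat_span = max(flat_span, grid[end] - grid[start])
            start = None
    unconstrained = flat_span >= FLAT_SPAN_LOG_UNITS
    fit.unconstrained[parameter] = fit.unconstrained.get(parameter, False) or unconstrained
    return ProfileResult(
        parameter=parameter,
        grid=grid,
        rss=rss,
        threshold=threshold,
        flat_span=flat_span,
        unconstrained=unconstrained,
    )


def compare_models(
    data: MALSDataset,
    candidates: Sequence[Sequence[tuple[int, int]]],
    init: Mapping[tuple[int, int], float] | None = None,
) -> tuple[list[tuple[int, int]], dict[int, float]]:
    """Select the most parsimonious stoichiometry set that explains the data.

    Every candidate set is fitted; the smallest set whose RSS is within
    ``MODEL_TOLERANCE_FACTOR`` of the global best (plus a sub-resolution
    absolute floor, so near-zero noiseless RSS values compare sanely) wins.
    Ties go to the set with fewer parameters.
    """
    if not candidates:
        raise ValueError("no candidate models")
    rss_by_candidate: dict[int, float] = {}
    for idx, spec in enumerate(candidates):
        if init is not None:
            rss_by_candidate[idx] = fit_association_constants(
                data, list(spec), init=init
            ).rss
            continue
        # deterministic multi-start: per-contact scale s, each complex
        # started at s * (i + j - 1) (binding free energies roughly add per
        # monomer contact), so higher-order complexes start proportionally
        # higher and the LM fit is not hostage to one basin
        best_rss = math.inf
        for s in (4.0, 6.0, 8.0, 10.0, 12.0):
            starts = {(i, j): s * (i + j - 1) for i, j in spec}
            res = fit_association_constants(data, list(spec), init=starts)
            best_rss = min(best_rss, res.rss)
        rss_by_candidate[idx] = best_rss
    best = min(rss_by_candidate.values())
    floor = _rss_threshold(data, resolution_cv=0.001)
    acceptable = [
        idx
        for idx, rss in rss_by_candidate.items()
        if rss <= max(MODEL_TOLERANCE_FACTOR * best, best + floor)
    ]
    acceptable.sort(key=lambda idx: (len(candidates[idx]), idx))
    return list(candidates[acceptable[0]]), rss_by_candidate


@dataclass(frozen=True)
class TrialSummary:
    """Across-trial mean and SEM of one fitted constant."""

    parameter: tuple[int, int]
    mean: float
    sem: float | None
    n: int

    def formatted(self) -> str:
        """'mean (standard error) n' at one-decimal precision."""
        se = "n/a" if self.sem is None else f"{self.sem:.1f}"
        return f"{self.mean:.1f} ({se}){self.n}"


def aggregate_trials(fits: Sequence[FitResult]) -> dict[tuple[int, int], TrialSummary]:
    """Across-trial summaries for every parameter shared by the fits.

    SEM is the standard error of the mean across independent trial fits
    (sample SD / sqrt(n)); a single trial gets SEM None.
    """
    if not fits:
        raise ValueError("need at least one fit")
    keys = set(fits[0].log10_ka)
    for f in fits[1:]:
        keys &= set(f.log10_ka)
    out = {}
    for k in sorted(keys):
        values = np.array([f.log10_ka[k] for f in fits])
        n = len(values)
        sem = float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else None
        out[k] = TrialSummary(parameter=k, mean=float(values.mean()), sem=sem, n=n)
    return out
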