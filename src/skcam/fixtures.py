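"""Registry of the published study parameters that drive every pipeline stage.

Each entry is a :class:`Fixture` carrying the value, its units, and a short
citation string naming where in the study it was reported.  The registry is
read-only: analysis code imports values from here rather than hard-coding
numbers, and every exported result can name the fixtures it used.

Values fall into two groups:

* measured or fitted experimental quantities (monomer masses, the fitted
  ``log10 K_A`` table, extinction coefficients, spectral peak positions,
  current-recovery summaries) — these parameterize the synthetic-data
  generators and serve as comparison anchors;
* instrument/protocol constants (stock concentrations, laser wavelength,
  refractive-index increment, emission window).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from types import MappingProxyType
from typing import Any, Mapping

__all__ = [
    "Fixture",
    "FIXTURES",
    "SEQUENCES",
    "TABLE2_LOG_KA",
    "table2_model_dict",
    "export_fixtures_json",
]


@dataclass(frozen=True)
class Fixture:
    """A single published value with units and provenance."""

    value: Any
    units: str
    citation: str


# Printed construct sequences (one-letter codes).  N-CaM spans M0–D80 of
# wild-type CaM; C-CaM spans M76–K148; the two overlap at MKDTD, the middle
# of the interlobe linker.  NN-CaM and CC-CaM are the double-lobe constructs.
SEQUENCES: Mapping[str, str] = MappingProxyType(
    {
        "N-CaM": (
            "MADQLTEEQIAEFKEAFSLFDKDGDGTITTKELGTVMRSLGQNPTEAELQDMINEVDADGNGTI"
            "DFPEFLTMMARKMKDTD"
        ),
        "C-CaM": (
            "MKDTDSEEEIREAFRVFDKDGNGYISAAELRHVMTNLGEKLTDEEVDEMIREADIDGDGQVNYE"
            "EFVQMMTAK"
        ),
        "NN-CaM": (
            "MADQLTEEQIAEFKEAFSLFDKDGDGTITTKELGTVMRSLGQNPTEAELQDMINEVDADGNGTI"
            "DFPEFLTMMARKMKDTDQIAEFKEAFSLFDKDGDGTITTKELGTVMRSLGQNPTEAELQDMINE"
            "VDADGNGTIDFPEFLTMMARK"
        ),
        "CC-CaM": (
            "MASEEEIREAFRVFDKDGNGYISAAELRHVMTNLGEKLTDEEVDEMIREADIDGDGQVNYEEFV"
            "QMMTAKDTDSEEEIREAFRVFDKDGNGYISAAELRHVMTNLGEKLTDEEVDEMIREADIDGDGQ"
            "VNYEEFVQMMTAK"
        ),
    }
)


# Fitted association constants (mean log10 K_A) per CaM construct and Ca2+
# condition.  Keys are (construct, condition) with condition one of
# "EGTA" (trace Ca2+, 5 mM EGTA) or "Ca" (2 mM CaCl2); values map complex
# stoichiometry (n_peptide, n_cam) to mean log10 K_A.  Entries flagged as
# outside the detection limit in the source table are listed in
# ``TABLE2_UNCONSTRAINED``.
TABLE2_LOG_KA: Mapping[tuple[str, str], Mapping[tuple[int, int], float]] = (
    MappingProxyType(
        {
            ("WT-CaM", "EGTA"): MappingProxyType({(1, 1): 6.9, (2, 1): 12.2}),
            ("WT-CaM", "Ca"): MappingProxyType(
                {(1, 1): 10.4, (2, 1): 17.0, (1, 2): 16.0}
            ),
            ("NN-CaM", "EGTA"): MappingProxyType({(1, 1): 6.4, (2, 1): 11.5}),
            ("NN-CaM", "Ca"): MappingProxyType(
                {(1, 1): 7.0, (2, 1): 12.5, (1, 2): 12.3}
            ),
            ("CC-CaM", "EGTA"): MappingProxyType({(1, 1): 9.9, (2, 1): 15.1}),
            ("CC-CaM", "Ca"): MappingProxyType(
                {(1, 1): 9.7, (2, 1): 16.5, (1, 2): 14.8}
            ),
            ("N-CaM", "EGTA"): MappingProxyType({(1, 1): 5.1}),
            ("N-CaM", "Ca"): MappingProxyType({(1, 1): 8.9}),
            ("C-CaM", "EGTA"): MappingProxyType({(1, 1): 7.6}),
            ("C-CaM", "Ca"): MappingProxyType({(1, 1): 8.1}),
            ("CaM (E12Q)", "EGTA"): MappingProxyType({(1, 1): 8.2, (2, 1): 13.2}),
            ("CaM (E12Q)", "Ca"): MappingProxyType({(1, 1): 8.8, (2, 1): 14.0}),
            ("CaM (E34Q)", "EGTA"): MappingProxyType({(1, 1): 8.3, (2, 1): 13.1}),
            ("CaM (E34Q)", "Ca"): MappingProxyType(
                {(1, 1): 9.1, (2, 1): 15.8, (2, 2): 23.3}
            ),
        }
    )
)

# (construct, condition, (i, j)) triples italicized in the source table as
# outside the limit of detection / ill constrained.
TABLE2_UNCONSTRAINED: frozenset[tuple[str, str, tuple[int, int]]] = frozenset(
    {
        ("NN-CaM", "EGTA", (2, 1)),
        ("N-CaM", "Ca", (1, 1)),
        ("C-CaM", "EGTA", (1, 1)),
        ("C-CaM", "Ca", (1, 1)),
        ("CaM (E12Q)", "EGTA", (1, 1)),
        ("CaM (E12Q)", "Ca", (1, 1)),
        ("CaM (E34Q)", "EGTA", (1, 1)),
        ("CaM (E34Q)", "Ca", (1, 1)),
    }
)


FIXTURES: Mapping[str, Fixture] = MappingProxyType(
    {
        # monomer masses (measured / sequence-verified)
        "mass_skp_kda": Fixture(11.1, "kDa", "Results: SKp molar mass"),
        "mass_wt_cam_kda": Fixture(16.7, "kDa", "Results: WT-CaM molar mass"),
        "mass_n_cam_kda": Fixture(9.0, "kDa", "Results: N-CaM molar mass"),
        # extinction coefficients as used for concentration determination
        "eps_skp": Fixture(6990, "M-1 cm-1 @ 280 nm", "Methods: ε table, SKp"),
        "eps_wt_cam": Fixture(3020, "M-1 cm-1 @ 277 nm", "Methods: ε table, WT-CaM"),
        "eps_n_cam": Fixture(975, "M-1 cm-1 @ 258 nm", "Methods: ε table, N-CaM"),
        "eps_c_cam": Fixture(3020, "M-1 cm-1 @ 277 nm", "Methods: ε table, C-CaM"),
        "eps_nn_cam": Fixture(1950, "M-1 cm-1 @ 258 nm", "Methods: ε table, NN-CaM"),
        "eps_cc_cam": Fixture(5960, "M-1 cm-1 @ 277 nm", "Methods: ε table, CC-CaM"),
        "eps_e12q": Fixture(3020, "M-1 cm-1 @ 277 nm", "Methods: ε table, CaM(E12Q)"),
        "eps_e34q": Fixture(3020, "M-1 cm-1 @ 277 nm", "Methods: ε table, CaM(E34Q)"),
        # SKp aromatic composition: the single native Trp (W432) and one Tyr
        "skp_n_trp": Fixture(1, "count", "Methods: single native tryptophan in SKp"),
        "skp_n_tyr": Fixture(1, "count", "Methods: three Tyr between the proteins, two in C-CaM"),
        # light-scattering optics and stocks
        "dn_dc": Fixture(0.186, "ml/g", "Methods: measured dn/dc of CaM"),
        "lambda0_nm": Fixture(660.0, "nm", "Methods: laser vacuum wavelength"),
        "n0": Fixture(1.33, "", "Methods: solvent refractive index"),
        "stock_skp_mg_ml": Fixture(0.096, "mg/ml", "Methods: SKp working stock"),
        "stock_cam_mg_ml": Fixture(0.09, "mg/ml", "Methods: CaM working stock"),
        "detection_limit_log_ka": Fixture(
            7.0, "log10 KA", "Results: bimolecular log K_A above ~7.0 not well constrained"
        ),
        # tryptophan emission spectroscopy
        "excitation_nm": Fixture(265, "nm", "Methods: excitation wavelength"),
        "emission_window_nm": Fixture((315, 400), "nm", "Methods: 1-nm scan window"),
        "peak_skp_free_nm": Fixture(348, "nm", "Results: free SKp W432 peak"),
        "peak_skp_cam_egta_nm": Fixture(334, "nm", "Results: SKp+WT-CaM peak, trace Ca2+"),
        "peak_skp_cam_ca_nm": Fixture(329, "nm", "Results: SKp+WT-CaM peak, high Ca2+"),
        "amplitude_gain_egta_pct": Fixture(
            230.0, "%", "Results: SKp+WT-CaM amplitude vs SKp alone, trace Ca2+"
        ),
        # patch-clamp recovery summary (n, median, mean, SD of fractional recovery)
        "recovery_table": Fixture(
            {
                "WT": {"n": 25, "median": 0.95, "mean": 0.86, "sd": 0.21},
                "CaM (E34Q)": {"n": 4, "median": 0.54, "mean": 0.50, "sd": 0.16},
                "N-CaM": {"n": 4, "median": 0.02, "mean": 0.05, "sd": 0.09},
                "C-CaM": {"n": 4, "median": 0.007, "mean": 0.03, "sd": 0.08},
                "N-CaM + C-CaM": {"n": 5, "median": 0.05, "mean": 0.07, "sd": 0.06},
                "Double N-lobe": {"n": 4, "median": 0.09, "mean": 0.08, "sd": 0.04},
                "Double C-lobe": {"n": 4, "median": 0.21, "mean": 0.19, "sd": 0.12},
            },
            "fraction of recovered current",
            "Table: exogenous CaM effect on SK current recovery",
        ),
        "patch_sampling_interval_s": Fixture(
            3.0, "s", "Methods: -60 mV step every 3 s"
        ),
    }
)


def table2_model_dict(construct: str, condition: str) -> dict[tuple[int, int], float]:
    """Return the fitted ``{(i, j): log10 K_A}`` set for one construct/condition.

    Parameters
    ----------
    construct
        One of the CaM construct names (e.g. ``"WT-CaM"``, ``"NN-CaM"``).
    condition
        ``"EGTA"`` (trace Ca2+) or ``"Ca"`` (2 mM CaCl2).
    """
    key = (construct, condition)
    if key not in TABLE2_LOG_KA:
        raise KeyError(
            f"no fitted constants for {construct!r} in condition {condition!r}"
        )
    return dict(TABLE2_LOG_KA[key])


def export_fixtures_json() -> str:
    """Serialize the full registry (fixtures, sequences, K_A table) to JSON."""
    payload = {
        "fixtures": {k: asdict(v) for k, v in FIXTURES.items()},
        "sequences": dict(SEQUENCES),
        "log_ka_table": {
            f"{construct}|{condition}": {
                f"{i},{j}": v for (i, j), v in entries.items()
            }
            for (construct, condition), entries in TABLE2_LOG_KA.items()
        },
        "unconstrained": sorted(
            f"{c}|{cond}|{i},{j}" for (c, cond, (i, j)) in TABLE2_UNCONSTRAINED
        ),
    }
    return json.dumps(payload, indent=2, sort_keys=True)
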