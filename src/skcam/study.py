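"""Convenience constructors assembling study objects from the fixture registry.

These glue the fixture registry to the analysis types: a monomer mass for
any CaM construct (published value where one was printed, sequence-derived
otherwise), the fitted binding model for a construct/condition pair, and
the standard cross-over gradient from the published working stocks.
"""

from __future__ import annotations

from .binding import BindingModel, ComplexSpec, MonomerSpecies, OpticalConstants
from .fixtures import FIXTURES, SEQUENCES, table2_model_dict
from .mals import Gradient, build_crossover_gradient
from .seqprops import ProteinSequence, average_molar_mass

__all__ = [
    "skp_species",
    "cam_species",
    "study_binding_model",
    "study_gradient",
    "study_optics",
]

_PRINTED_MASSES = {
    "WT-CaM": FIXTURES["mass_wt_cam_kda"].value,
    "N-CaM": FIXTURES["mass_n_cam_kda"].value,
    # full-length Ca2+-site mutants: E->Q changes the mass negligibly at the
    # 0.1-kDa precision used throughout, so the WT mass applies
    "CaM (E12Q)": FIXTURES["mass_wt_cam_kda"].value,
    "CaM (E34Q)": FIXTURES["mass_wt_cam_kda"].value,
}


def skp_species() -> MonomerSpecies:
    return MonomerSpecies("SKp", FIXTURES["mass_skp_kda"].value)


def cam_species(construct: str) -> MonomerSpecies:
    """Monomer species for a CaM construct.

    Published masses are used where available; the double-lobe and C-lobe
    constructs get sequence-derived average masses (initiator Met retained,
    as for all purified constructs).
    """
    if construct in _PRINTED_MASSES:
        return MonomerSpecies(construct, _PRINTED_MASSES[construct])
    if construct in SEQUENCES:
        seq = ProteinSequence(construct, SEQUENCES[construct])
        return MonomerSpecies(construct, round(average_molar_mass(seq), 1))
    raise KeyError(f"unknown CaM construct {construct!r}")


def study_binding_model(construct: str, condition: str) -> BindingModel:
    """Binding model with the fitted log10 K_A set for construct/condition."""
    kas = table2_model_dict(construct, condition)
    label = {"EGTA": "5 mM EGTA", "Ca": "2 mM CaCl2"}.get(condition, condition)
    return BindingModel(
        peptide=skp_species(),
        cam=cam_species(construct),
        complexes=tuple(ComplexSpec(i, j, v) for (i, j), v in sorted(kas.items())),
        condition_label=label,
    )


def study_gradient(
    construct: str = "WT-CaM",
    n_steps: int = 41,
    f_min: float = 0.05,
    f_max: float = 0.95,
) -> Gradient:
    """Standard cross-over gradient between the published working stocks."""
    return build_crossover_gradient(
        stock_peptide_mg_ml=FIXTURES["stock_skp_mg_ml"].value,
        stock_cam_mg_ml=FIXTURES["stock_cam_mg_ml"].value,
        peptide=skp_species(),
        cam=cam_species(construct),
        n_steps=n_steps,
        f_min=f_min,
        f_max=f_max,
    )


def study_optics() -> OpticalConstants:
    return OpticalConstants(
        dn_dc=FIXTURES["dn_dc"].value,
        n0=FIXTURES["n0"].value,
        lambda0_nm=FIXTURES["lambda0_nm"].value,
    )
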