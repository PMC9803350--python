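import numpy as np
import pytest

from skcam import (
    BindingModel,
    ComplexSpec,
    ProteinSequence,
    cam_species,
    skp_species,
    study_binding_model,
    study_gradient,
)
from skcam.fixtures import SEQUENCES


@pytest.fixture(scope="session")
def wt_ca_model() -> BindingModel:
    """Three-complex SKp/WT-CaM model at saturating Ca2+."""
    return study_binding_model("WT-CaM", "Ca")


@pytest.fixture(scope="session")
def standard_gradient():
    """41-step cross-over gradient between the standard working stocks."""
    return study_gradient("WT-CaM")


@pytest.fixture(scope="session")
def n_cam_seq() -> ProteinSequence:
    return ProteinSequence("N-CaM", SEQUENCES["N-CaM"])


@pytest.fixture(scope="session")
def c_cam_seq() -> ProteinSequence:
    return ProteinSequence("C-CaM", SEQUENCES["C-CaM"])


@pytest.fixture
def single_complex_model():
    """Factory: SKp/WT-CaM model with one 1:1 complex at a given log K_A."""

    def make(log10_ka: float) -> BindingModel:
        return BindingModel(
            peptide=skp_species(),
            cam=cam_species("WT-CaM"),
            complexes=(ComplexSpec(1, 1, log10_ka),),
        )

    return make
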