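import numpy as np
import pytest

from capsidkinetics.kinetics import (
    KineticParameters,
    MixtureComposition,
    default_n_max,
)
from capsidkinetics.scattering import ContrastSet


@pytest.fixture
def ccmv_comp() -> MixtureComposition:
    """Reference composition: 24.6 uM subunits at molar ratio 150."""
    return MixtureComposition.from_mass_ratio(24.6e-6, rho=6.0, m_ratio=25.0)


@pytest.fixture
def ccmv_params(ccmv_comp) -> KineticParameters:
    """Reference rate constants: K_inv = 13.6 uM, tau_bind = 28 ms."""
    k_plus = 2.2e8
    return KineticParameters(
        k_plus=k_plus, k_minus=k_plus * 13.6e-6, n_max=default_n_max(ccmv_comp)
    )


@pytest.fixture
def simple_contrast() -> ContrastSet:
    return ContrastSet(db_G=3.0, db_S=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
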