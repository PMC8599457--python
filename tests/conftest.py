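import numpy as np
import pytest

from fiberindent.elastic import TransverseIsotropicConstants
from fiberindent.inversion import FixedParameters


@pytest.fixture
def fixed_params():
    """Literature/assumed constants held fixed during identification."""
    return FixedParameters(nu_LT=0.25, nu_TT=0.25, G_LT=2.51, theta=0.0)


@pytest.fixture
def pulp_constants():
    """A representative admissible kraft-pulp wall constant set."""
    return TransverseIsotropicConstants(
        E_L=8.0, E_T=1.1, nu_LT=0.25, nu_TT=0.25, G_LT=2.51
    )


def isotropic(E: float, nu: float) -> TransverseIsotropicConstants:
    return TransverseIsotropicConstants(
        E_L=E, E_T=E, nu_LT=nu, nu_TT=nu, G_LT=E / (2.0 * (1.0 + nu))
    )


def random_admissible(rng: np.random.Generator) -> TransverseIsotropicConstants:
    """Draw constants admissible for a stiff-axis transversely isotropic wall."""
    while True:
        E_L = rng.uniform(2.0, 40.0)
        E_T = rng.uniform(0.3, min(E_L, 6.0))
        nu_LT = rng.uniform(0.05, 0.4)
        nu_TT = rng.uniform(0.05, 0.45)
        G_LT = rng.uniform(0.3, 6.0)
        try:
            c = TransverseIsotropicConstants(E_L, E_T, nu_LT, nu_TT, G_LT)
            from fiberindent.elastic import compliance_from_engineering

            compliance_from_engineering(c)
            return c
        except Exception:
            continue
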