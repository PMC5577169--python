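import numpy as np
import pytest

from gazehmm import (
    AOILayout,
    BlockHMMParams,
    EmissionParams,
    default_layout,
    default_params,
)


@pytest.fixture
def layout() -> AOILayout:
    return default_layout()


@pytest.fixture
def table_params() -> BlockHMMParams:
    """The published-parameter generating model."""
    return default_params()


def make_emission(mu_fd=5.0, sigma_fd=0.5, mu_sl=4.0, sigma_sl=0.5,
                  p_aoi=(0.25, 0.25, 0.25, 0.25), p_sd=(0.25, 0.25, 0.25, 0.25)):
    return EmissionParams(mu_fd=mu_fd, sigma_fd=sigma_fd, mu_sl=mu_sl,
                          sigma_sl=sigma_sl, p_aoi=np.array(p_aoi),
                          p_sd=np.array(p_sd))


def make_params(pi, A, emissions, classes):
    return BlockHMMParams(pi=np.array(pi, dtype=float), A=np.array(A, dtype=float),
                          emissions=emissions, class_of_state=classes)


@pytest.fixture
def toy_params() -> BlockHMMParams:
    """2 states per class with well-separated SD emissions."""
    ems = [
        make_emission(mu_fd=4.5, p_sd=(0.7, 0.1, 0.1, 0.1)),
        make_emission(mu_fd=5.5, p_sd=(0.1, 0.7, 0.1, 0.1)),
        make_emission(mu_fd=4.5, p_sd=(0.1, 0.1, 0.7, 0.1)),
        make_emission(mu_fd=5.5, p_sd=(0.1, 0.1, 0.1, 0.7)),
    ]
    A = [
        [0.8, 0.2, 0.0, 0.0],
        [0.3, 0.7, 0.0, 0.0],
        [0.0, 0.0, 0.6, 0.4],
        [0.0, 0.0, 0.5, 0.5],
    ]
    p = make_params([0.3, 0.2, 0.4, 0.1], A, ems, ("LFRR", "LFRR", "RFLR", "RFLR"))
    p.validate()
    return p


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
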