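import numpy as np
import pytest

from neurohemo.dcs import DcsOpticalModel, G2Frame, default_tau_grid, g1_semiinfinite


@pytest.fixture
def optics() -> DcsOpticalModel:
    return DcsOpticalModel()


@pytest.fixture
def tau() -> np.ndarray:
    return default_tau_grid()


@pytest.fixture
def make_frame(optics, tau):
    """Factory for noiseless synthetic g2 frames at known (alpha_Db, beta)."""

    def _make(alpha_db: float = 1e-8, beta: float = 0.5, timestamp: float = 0.0,
              model: DcsOpticalModel | None = None) -> G2Frame:
        m = model or optics
        g1 = g1_semiinfinite(m, alpha_db, tau)
        return G2Frame(tau, 1.0 + beta * g1**2, timestamp)

    return _make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230919)
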