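import numpy as np
import pytest

from hbnet.hb_signal import compute_dependent_components
from hbnet.state_space import build_geometry
from hbnet.synthetic import SimConfig, generate_hb_series


@pytest.fixture(scope="session")
def geometry():
    return build_geometry()


@pytest.fixture(scope="session")
def small_series():
    """Deterministic small paired series for smoke/integration tests."""
    cfg = SimConfig(n_frames=200, n_voxels=120, seed=7)
    return generate_hb_series(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_series(oxy, deoxy, **kwargs):
    """Convenience wrapper used by several test modules."""
    return compute_dependent_components(np.asarray(oxy, dtype=float),
                                        np.asarray(deoxy, dtype=float), **kwargs)
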