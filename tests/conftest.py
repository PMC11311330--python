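import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermoflow as tf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_small():
    """A short drifting recording shared across tracking/flow tests."""
    cfg = tf.SimulationConfig(
        duration_s=8.0, seed=3, drift_velocity=(0.0, 0.12), drift_speed=0.03
    )
    seq, gt = tf.simulate_sequence(cfg)
    return cfg, seq, gt


@pytest.fixture(scope="session")
def tracked_small(sim_small):
    cfg, seq, gt = sim_small
    tparams = tf.tracking_norm_params(seq, gt)
    rois, state = tf.track_sequence(seq, gt.initial_roi, tparams)
    return rois, state, tparams


@pytest.fixture(scope="session")
def smooth_texture():
    """Smooth random texture in [0, 1] with trackable features (fixed seed)."""
    from scipy import ndimage

    gen = np.random.default_rng(99)
    tex = ndimage.gaussian_filter(gen.standard_normal((80, 100)), 3.0)
    tex = 0.5 + 0.5 * tex / np.abs(tex).max()
    return tex
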