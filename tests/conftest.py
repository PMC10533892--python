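import numpy as np
import pytest

from mitopulse.pipeline import fixture_config, make_fixture, run_pipeline
from mitopulse.simulate import SimParams, simulate_movie


@pytest.fixture(scope="session")
def tiny_fixture(tmp_path_factory):
    """Self-contained tiny dataset (20 frames, 6 mitochondria, noiseless)."""
    out = tmp_path_factory.mktemp("fixture_tiny")
    return make_fixture("tiny", seed=0, out_dir=out)


@pytest.fixture(scope="session")
def tiny_run(tiny_fixture, tmp_path_factory):
    """Pipeline output of the tiny fixture."""
    out = tmp_path_factory.mktemp("run_tiny")
    cfg = fixture_config(tiny_fixture, out, seed=0)
    manifest = run_pipeline(cfg)
    return out, manifest


@pytest.fixture(scope="session")
def small_sim():
    """A small noiseless movie + ground truth for oracle tests."""
    params = SimParams(
        image_shape=(256, 256), n_frames=10, n_mitos=5,
        mito_length_range=(0.7, 1.5), mito_width_range=(0.4, 0.55),
        motion_sigma=0.01, stim_frames=((4, 5.0),), decay_rate=0.54,
        plateau_duration=30.0, noise_shot=False, noise_read_sigma=0.0,
        background_offset=0.0, rng_seed=2,
    )
    movie, gt = simulate_movie(params)
    return params, movie, gt


def single_mito_params(**overrides) -> SimParams:
    """One static, noiseless mitochondrion; helper for placement-controlled tests."""
    base = dict(
        image_shape=(192, 192), n_frames=30, n_mitos=1,
        mito_length_range=(1.0, 1.0), mito_width_range=(0.5, 0.5),
        motion_sigma=0.0, stim_frames=((5, 5.0),), decay_rate=0.54,
        plateau_duration=30.0, elongation_factor=1.0,
        noise_shot=False, noise_read_sigma=0.0, background_offset=0.0,
        rng_seed=7,
    )
    base.update(overrides)
    return SimParams(**base)


def mito_position(params: SimParams) -> np.ndarray:
    """True centroid of the (static) single mitochondrion at frame 0."""
    _, gt = simulate_movie(params)
    rec = gt.records[gt.records["frame"] == 0].iloc[0]
    return np.array([rec["x_um"], rec["y_um"]])
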