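import numpy as np
import pytest

from evwell import census_filter, segment, simulate


@pytest.fixture(scope="session")
def small_array():
    """A 16x16-well array (256 wells) with the default kinetic mix, seed 1."""
    cfg = simulate.ArrayConfig(n_rows=16, n_cols=16, rng_seed=1)
    frames, truth = simulate.simulate_array(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def segmented(small_array):
    cfg, frames, truth = small_array
    objects = {f.time_h: segment.segment_frame(f) for f in frames}
    return cfg, frames, truth, objects


@pytest.fixture(scope="session")
def trajectories(segmented):
    cfg, frames, truth, objects = segmented
    occ = segment.census(objects, cfg)
    selected = census_filter.select_single_single(occ)
    trajs = census_filter.build_trajectories(selected, objects, frames)
    return truth, trajs


@pytest.fixture(scope="session")
def noiseless_array():
    """Noise-free 12x12 array: exact intensities, deterministic segmentation."""
    cfg = simulate.ArrayConfig(n_rows=12, n_cols=12, noise_sd=0.0, rng_seed=7)
    frames, truth = simulate.simulate_array(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def cohort():
    cfg = simulate.CohortConfig(signature_fold_change=1.5, rng_seed=5)
    return cfg, simulate.simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
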