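import numpy as np
import pytest

from bmsmaps import Cuboid, simulate_evidence_volumes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume_set():
    """6x6x6 grid, 8 subjects, 2 models, active 2x2x2 cuboid."""
    evset, truth = simulate_evidence_volumes(
        grid_shape=(6, 6, 6),
        voxel_size_mm=3.0,
        active_region=Cuboid((1, 1, 1), (3, 3, 3)),
        r_true_inside=[0.9, 0.1],
        r_true_outside=[0.5, 0.5],
        n_subjects=8,
        effect_mean=3.0,
        seed=7,
    )
    return evset, truth
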