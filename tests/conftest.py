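import numpy as np
import pytest

from qppdyn import (
    ImageSeries,
    MotifSpec,
    make_phantom_atlas,
    simulate_series,
)


@pytest.fixture(scope="session")
def small_phantom():
    """Small phantom atlas: 2 regions per network on a 12x12x3 grid."""
    return make_phantom_atlas((12, 12, 3), 2)


@pytest.fixture(scope="session")
def short_motif():
    return MotifSpec(
        window=6,
        region_amplitudes={"D1": -1.0, "D2": -1.0, "L1": 1.0, "L2": 1.0},
    )


@pytest.fixture(scope="session")
def motif_series(small_phantom, short_motif):
    """3 subjects x 400 frames with one embedded 6-frame motif at default SNR."""
    atlas, mask = small_phantom
    series, gt = simulate_series(
        atlas, mask, [short_motif], 1.0,
        n_subjects=3, n_frames=400, tr_seconds=0.5, noise_sd=1.0, seed=11,
    )
    return atlas, mask, series, gt


@pytest.fixture(scope="session")
def prepped_series(motif_series):
    """The motif fixture after the full preprocessing chain."""
    from qppdyn import preprocess_chain

    atlas, mask, series, gt = motif_series
    return atlas, mask, preprocess_chain(series), gt


@pytest.fixture(scope="session")
def noiseless_series(small_phantom, short_motif):
    """Same design with (numerically) zero noise, for construction checks."""
    atlas, mask = small_phantom
    series, gt = simulate_series(
        atlas, mask, [short_motif], 1.0,
        n_subjects=2, n_frames=400, tr_seconds=0.5, noise_sd=1e-9, seed=7,
    )
    return atlas, mask, series, gt


@pytest.fixture()
def random_series():
    """Small random multi-subject series for oracle tests."""
    rng = np.random.default_rng(5)
    V, T = 7, 80
    data = rng.normal(size=(V, T))
    coords = np.argwhere(np.ones((7, 1, 1), dtype=bool))
    return ImageSeries(
        data=data,
        tr_seconds=0.5,
        subjects=[("a", 0, 40), ("b", 40, 40)],
        voxel_coords=coords,
        mask_shape=(7, 1, 1),
    )
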