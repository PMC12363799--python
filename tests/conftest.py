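import numpy as np
import pytest

from alffkit import BandSpec, BoldSeries, SpatialRef


@pytest.fixture
def band():
    return BandSpec()  # 0.01-0.08 Hz band, 0.2 Hz cutoff


@pytest.fixture
def spatial_ref():
    return SpatialRef(np.diag([3.0, 3.0, 3.0, 1.0]), (6, 6, 6))


def series_from(data, tr=2.0, **kwargs):
    """Wrap a (M, N) array as a BoldSeries on a toy grid."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    m = data.shape[0]
    side = max(6, int(np.ceil(m ** (1 / 3))))
    shape = (side, side, side)
    coords = np.column_stack(np.unravel_index(np.arange(m), shape))
    ref = SpatialRef(np.diag([3.0, 3.0, 3.0, 1.0]), shape)
    return BoldSeries(data=data, tr=tr, voxel_index=coords, spatial_ref=ref, **kwargs)


def cosines(freqs_amps_phases, n=240, tr=2.0, m=1):
    """(M, N) matrix of summed cosines, identical across the M rows."""
    t = np.arange(n) * tr
    row = np.zeros(n)
    for f, a, ph in freqs_amps_phases:
        row = row + a * np.cos(2 * np.pi * f * t + ph)
    return np.tile(row, (m, 1))


@pytest.fixture
def random_series():
    """100 random Gaussian voxels, n=240, TR=2 s, demeaned upstream of use."""
    rng = np.random.default_rng(42)
    return series_from(rng.normal(size=(100, 240)), tr=2.0)
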