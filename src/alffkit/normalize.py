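"""Mean BOLD intensity, subject-level map normalization, and z-scoring.

ALFF carries the voxel's raw intensity scale: a subject scanned with a
higher gain has a proportionally larger amplitude spectrum, so mean BOLD
intensity (MBI) and ALFF move together across subjects. Dividing each
subject's map by its mask mean (so every subject's map averages 1) removes
that multiplicative effect. z-scoring a voxel's series divides its whole
spectrum by the temporal standard deviation sigma(m): fractional metrics are
untouched (sigma cancels), but the normalized ALFF maps change unless sigma
is constant across voxels — the z-then-normalize composite is exposed here
for that diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .bold_io import BoldSeries, VoxelMap

__all__ = [
    "SubjectSummary",
    "mbi_subject",
    "mbi_voxel",
    "normalize_map",
    "temporal_sigma",
    "zscore",
    "znorm_map",
    "shared_variance",
]


@dataclass
class SubjectSummary:
    """Per-subject normalizers: MBI, map means, per-voxel sigmas."""

    mbi: float
    mean_am_alff: float
    mean_qm_alff: float
    sigma: np.ndarray


def mbi_subject(series: BoldSeries) -> float:
    """Subject-level mean BOLD intensity: mean over voxels of temporal means.

    Uses raw (pre-demeaning) intensities; the means stored at demeaning time
    give the identical result.
    """
    return float(series.temporal_means().mean())


def mbi_voxel(subjects: list[BoldSeries]) -> VoxelMap:
    """Voxel-level MBI: per voxel, mean over subjects of its temporal mean."""
    if not subjects:
        raise ValueError("need at least one subject")
    first = subjects[0]
    for s in subjects[1:]:
        if not np.array_equal(s.voxel_index, first.voxel_index):
            raise ValueError("subjects do not share the same mask support")
    means = np.mean([s.temporal_means() for s in subjects], axis=0)
    return VoxelMap(means, "MBI", first.voxel_index, first.spatial_ref)


def _norm_name(name: str) -> str:
    return name if name.endswith("_norm") else name + "_norm"


def normalize_map(vmap: VoxelMap) -> VoxelMap:
    """Divide a map by its mask mean so the mean is exactly 1.

    Idempotent, and invariant under positive rescaling of the input map —
    any multiplicative subject-level factor (MBI, scanner gain, a global
    spectral constant) cancels.
    """
    mean = vmap.values.mean()
    if not mean > 0:
        raise ValueError(
            f"cannot normalize {vmap.metric_name}: mask mean is {mean}"
        )
    # bit-exact idempotence: a mean already at 1 (within fp dust) stays put
    if abs(mean - 1.0) < 1e-12:
        mean = 1.0
    return VoxelMap(
        vmap.values / mean,
        _norm_name(vmap.metric_name),
        vmap.voxel_index,
        vmap.spatial_ref,
    )


def temporal_sigma(series: BoldSeries, *, ddof: int = 0) -> np.ndarray:
    """Per-voxel temporal standard deviation sigma(m).

    Population convention (ddof=0) by default, so z-scored rows have RMS
    exactly 1; pass ddof=1 for the sample convention.
    """
    return series.data.std(axis=1, ddof=ddof)


def zscore(series: BoldSeries, *, ddof: int = 0) -> BoldSeries:
    """Demean each voxel's series and divide by its temporal sigma.

    Idempotent up to floating point; requires strictly positive variance
    (zero-variance voxels are dropped at read time).
    """
    sigma = temporal_sigma(series, ddof=ddof)
    if (sigma == 0).any():
        raise ValueError("zero temporal variance; cannot z-score")
    if series.demeaned:
        centered = series.data
        means = series.voxel_means
    else:
        means = series.data.mean(axis=1)
        centered = series.data - means[:, None]
    return replace(
        series,
        data=centered / sigma[:, None],
        demeaned=True,
        voxel_means=means,
    )


def znorm_map(vmap: VoxelMap, sigma: np.ndarray) -> VoxelMap:
    """The z-then-normalize composite: divide by per-voxel sigma, renormalize.

    Equals :func:`normalize_map` exactly iff sigma is constant across voxels;
    computing the metric on a z-scored series and normalizing gives the same
    map.
    """
    sigma = np.asarray(sigma, dtype=np.float64)
    if sigma.shape != vmap.values.shape:
        raise ValueError(
            f"sigma length {sigma.shape} does not match map ({vmap.values.shape})"
        )
    if (sigma <= 0).any():
        raise ValueError("sigma must be strictly positive")
    scaled = vmap.values / sigma
    mean = scaled.mean()
    if not mean > 0:
        raise ValueError("cannot normalize: mask mean is non-positive")
    base = vmap.metric_name.removesuffix("_norm")
    return VoxelMap(
        scaled / mean, base + "_norm_z", vmap.voxel_index, vmap.spatial_ref
    )


def shared_variance(map_a: VoxelMap, map_b: VoxelMap) -> float:
    """Squared Pearson correlation of two aligned voxel maps."""
    a, b = map_a.values, map_b.values
    if a.size != b.size:
        raise ValueError("maps are not aligned")
    if a.size < 3:
        raise ValueError("need at least 3 voxels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("shared variance undefined for a constant map")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)
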