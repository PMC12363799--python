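"""Frequency-domain ALFF estimators.

Given a demeaned BOLD series s(m, n) of a voxel m, the one-sided amplitude
spectrum is S(m, k) = |FFT(s)| at bins k = 0..N/2 with resolution
1/(N*TR) Hz. The per-bin amplitude of oscillation is 2*S/N for 0 < k < N/2
(the Nyquist bin, having no mirror, is scaled 1/N). Four band metrics follow:

- amALFF: arithmetic mean of the scaled amplitudes over [k_fl, k_fh];
- qmALFF: quadratic (root-mean-square) mean of the same amplitudes;
- amfALFF: sum of in-band amplitudes over the sum up to the preprocessing
  low-pass cutoff fc;
- qmfALFF: the same ratio on squared amplitudes, under a square root.

The fractional metrics start their denominator at k = 1: after demeaning the
DC bin is analytically zero and including it would only add floating-point
dust. Both fractional metrics lie in [0, 1] and are invariant under positive
rescaling of the series; the unscaled metrics scale with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .bold_io import BoldSeries, VoxelMap

__all__ = [
    "BandSpec",
    "FrequencyIndex",
    "SpectrumSet",
    "demean",
    "band_indices",
    "amplitude_spectrum",
    "am_alff",
    "am_falff",
    "qm_alff_freq",
    "qm_falff_freq",
]

#: The study band and cutoff: 0.01-0.08 Hz of interest, 0.2 Hz preprocessing
#: low-pass.
DEFAULT_FL = 0.01
DEFAULT_FH = 0.08
DEFAULT_FC = 0.2


@dataclass(frozen=True)
class BandSpec:
    """Analysis band in Hz: [fl, fh] of interest within (0, fc]."""

    fl: float = DEFAULT_FL
    fh: float = DEFAULT_FH
    fc: float = DEFAULT_FC

    def __post_init__(self) -> None:
        if not (0 < self.fl < self.fh < self.fc):
            raise ValueError(
                f"band must satisfy 0 < fl < fh < fc, got "
                f"fl={self.fl}, fh={self.fh}, fc={self.fc}"
            )


@dataclass(frozen=True)
class FrequencyIndex:
    """FFT-bin image of a :class:`BandSpec` for a given n and TR."""

    k_fl: int
    k_fh: int
    k_fc: int
    n: int
    delta_f: float

    def __post_init__(self) -> None:
        if not (1 <= self.k_fl <= self.k_fh <= self.k_fc <= self.n // 2):
            raise ValueError(
                f"bin indices must satisfy 1 <= k_fl <= k_fh <= k_fc <= n/2, "
                f"got ({self.k_fl}, {self.k_fh}, {self.k_fc}) with n={self.n}"
            )
        if not self.delta_f > 0:
            raise ValueError("delta_f must be positive")

    @property
    def n_band(self) -> int:
        """Number of bins in [k_fl, k_fh]."""
        return self.k_fh - self.k_fl + 1

    @property
    def band(self) -> slice:
        return slice(self.k_fl, self.k_fh + 1)

    @property
    def denominator(self) -> slice:
        """Bins of the fractional-metric denominator: 1..k_fc (DC excluded)."""
        return slice(1, self.k_fc + 1)


@dataclass
class SpectrumSet:
    """Per-voxel one-sided amplitude spectra |FFT| (unscaled)."""

    amplitudes: np.ndarray  # (M, n//2 + 1)
    freq_grid: np.ndarray  # Hz per bin
    n: int  # original timepoint count
    voxel_index: np.ndarray
    spatial_ref: object

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if (self.amplitudes < 0).any():
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_voxels(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.amplitudes.shape[1]

    def scaled(self) -> np.ndarray:
        """Amplitudes of oscillation: 2S/n at interior bins, S/n at DC/Nyquist."""
        return self.amplitudes * one_sided_scale(self.n)


def one_sided_scale(n: int) -> np.ndarray:
    """Per-bin factor turning raw |FFT| into amplitude of oscillation.

    Interior bins get 2/n (each has a conjugate mirror); the DC bin gets 1/n,
    and for even n so does the unpaired Nyquist bin. Odd n has no Nyquist bin
    and all k >= 1 are doubled.
    """
    n_bins = n // 2 + 1
    scale = np.full(n_bins, 2.0 / n)
    scale[0] = 1.0 / n
    if n % 2 == 0:
        scale[-1] = 1.0 / n
    return scale


def demean(series: BoldSeries) -> BoldSeries:
    """Remove each voxel's temporal mean, retaining the means for MBI.

    Idempotent: an already-demeaned series is returned unchanged.
    """
    if series.demeaned:
        return series
    means = series.data.mean(axis=1)
    return replace(
        series,
        data=series.data - means[:, None],
        demeaned=True,
        voxel_means=means,
    )


def band_indices(band: BandSpec, n: int, tr: float) -> FrequencyIndex:
    """Map band edges in Hz to FFT bin indices.

    Each edge maps to the integer k minimizing |k * delta_f - f| with
    delta_f = 1/(n*tr); ties round toward the larger k, and k_fl is clamped
    to >= 1 so the DC bin can never enter the band.
    """
    if n < 2:
        raise ValueError("need at least 2 timepoints")
    nyquist = 1.0 / (2.0 * tr)
    if band.fc > nyquist * (1 + 1e-12):
        raise ValueError(
            f"fc={band.fc} Hz exceeds the Nyquist frequency {nyquist} Hz "
            f"for tr={tr}"
        )
    delta_f = 1.0 / (n * tr)
    n_half = n // 2 if n % 2 == 0 else (n - 1) // 2

    def nearest(f: float) -> int:
        # round half toward the larger k
        return int(np.floor(f / delta_f + 0.5))

    k_fl = max(nearest(band.fl), 1)
    k_fh = nearest(band.fh)
    k_fc = min(nearest(band.fc), n_half)
    return FrequencyIndex(k_fl=k_fl, k_fh=k_fh, k_fc=k_fc, n=n, delta_f=delta_f)


def amplitude_spectrum(series: BoldSeries) -> SpectrumSet:
    """One-sided amplitude spectrum S(m, k) = |FFT(s(m, n))|, unscaled.

    Requires a demeaned series. Bins run 0..n/2 for even n and 0..(n-1)/2
    for odd n (no Nyquist bin).
    """
    if not series.demeaned:
        raise ValueError("amplitude_spectrum requires a demeaned series")
    amp = np.abs(np.fft.rfft(series.data, axis=1))
    freqs = np.fft.rfftfreq(series.n_timepoints, d=series.tr)
    return SpectrumSet(
        amplitudes=amp,
        freq_grid=freqs,
        n=series.n_timepoints,
        voxel_index=series.voxel_index,
        spatial_ref=series.spatial_ref,
    )


def _check_idx(spec: SpectrumSet, idx: FrequencyIndex) -> None:
    if idx.n != spec.n:
        raise ValueError(
            f"frequency index computed for n={idx.n}, spectrum has n={spec.n}"
        )


def am_alff(spec: SpectrumSet, idx: FrequencyIndex) -> VoxelMap:
    """Arithmetic-mean ALFF: mean of 2S(m,k)/n over the band."""
    _check_idx(spec, idx)
    values = spec.scaled()[:, idx.band].mean(axis=1)
    return VoxelMap(values, "amALFF", spec.voxel_index, spec.spatial_ref)


def qm_alff_freq(spec: SpectrumSet, idx: FrequencyIndex) -> VoxelMap:
    """Quadratic-mean ALFF: RMS of the scaled in-band amplitudes.

    Equals (2/n) * sqrt(mean of S^2 over the band) away from the Nyquist
    bin; by the power-mean inequality it is >= amALFF voxelwise, with
    equality only when all in-band amplitudes coincide.
    """
    _check_idx(spec, idx)
    scaled = spec.scaled()[:, idx.band]
    values = np.sqrt(np.mean(scaled**2, axis=1))
    return VoxelMap(values, "qmALFF", spec.voxel_index, spec.spatial_ref)


def _fractional(spec: SpectrumSet, idx: FrequencyIndex, power: int) -> np.ndarray:
    amp = spec.amplitudes**power
    num = amp[:, idx.band].sum(axis=1)
    den = amp[:, idx.denominator].sum(axis=1)
    zero = den == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} voxel(s) have zero spectral energy below fc; "
            "fractional metric set to NaN",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(zero, np.nan, num / np.where(zero, 1.0, den))
    return ratio


def am_falff(spec: SpectrumSet, idx: FrequencyIndex) -> VoxelMap:
    """Fractional amplitude: sum of S over [k_fl, k_fh] / sum over [1, k_fc]."""
    _check_idx(spec, idx)
    values = _fractional(spec, idx, power=1)
    return VoxelMap(values, "amfALFF", spec.voxel_index, spec.spatial_ref)


def qm_falff_freq(spec: SpectrumSet, idx: FrequencyIndex) -> VoxelMap:
    """Quadratic fractional amplitude: sqrt of the in-band share of power."""
    _check_idx(spec, idx)
    values = np.sqrt(_fractional(spec, idx, power=2))
    return VoxelMap(values, "qmfALFF", spec.voxel_index, spec.spatial_ref)
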