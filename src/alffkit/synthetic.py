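"""Synthetic BOLD fixtures with known spectral content.

Each voxel is a baseline intensity plus a sum of sinusoids plus Gaussian
white noise:

    s(t) = mbi_base * gain_j + gain_j * sum_i A_i cos(2 pi f_i t + phi_i) + e(t)

where gain_j is a per-subject multiplicative factor emulating
between-subject mean-BOLD-intensity (MBI) differences from scanner settings
and physiology, and e(t) ~ N(0, noise_sd^2). With ``snap_to_grid`` each
frequency is rounded to the nearest FFT bin k/(n*tr), so a noiseless
component's amplitude can be read off the spectrum exactly and its temporal
mean vanishes over the record.

Randomness is fully reproducible: each (subject, voxel) pair gets an
independent stream spawned from the master seed, so a dataset can be
regenerated in part without disturbing the rest.

What this generator does not emulate: hemodynamic response shapes, 1/f
spectral background, spatial autocorrelation, and cardiac/respiratory
physiological noise. Estimator tests against it therefore certify the
numerics, not robustness to realistic BOLD structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bold_io import BoldSeries, SpatialRef
from .spectral import BandSpec

__all__ = ["SyntheticSpec", "make_voxel", "make_dataset", "write_dataset"]

Component = tuple[float, float, float]  # (frequency Hz, amplitude, phase rad)

#: Toy grid defaults: 6x6x6 volume, 100-voxel mask, 240 timepoints at
#: TR = 2 s, giving delta_f = 1/480 Hz — comfortably below the 0.01 Hz band
#: edge — while keeping per-test cost in the milliseconds.
DEFAULT_GRID = (6, 6, 6)
DEFAULT_N_VOXELS = 100
DEFAULT_N_TIMEPOINTS = 240
DEFAULT_TR = 2.0


@dataclass
class SyntheticSpec:
    """Recipe for a reproducible multi-subject BOLD-like dataset.

    ``components`` is either one list of (frequency, amplitude, phase)
    triplets shared by every voxel, or a per-voxel list of such lists.
    ``mbi_gain`` defaults to 1 for every subject. With ``noise_gain_scaled``
    the white noise is multiplied by the subject gain too — the
    receiver-gain model, under which the fractional metrics carry no gain
    information; by default noise is additive and gain-independent.
    """

    seed: int
    n_subjects: int = 1
    n_voxels: int = DEFAULT_N_VOXELS
    n_timepoints: int = DEFAULT_N_TIMEPOINTS
    tr: float = DEFAULT_TR
    components: list = field(default_factory=lambda: [(0.04, 1.0, 0.0)])
    noise_sd: float = 0.0
    mbi_base: float = 500.0
    mbi_gain: np.ndarray | None = None
    snap_to_grid: bool = True
    noise_gain_scaled: bool = False
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    band: BandSpec = field(default_factory=BandSpec)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.mbi_gain is None:
            self.mbi_gain = np.ones(self.n_subjects)
        self.mbi_gain = np.asarray(self.mbi_gain, dtype=np.float64)
        if self.mbi_gain.shape != (self.n_subjects,):
            raise ValueError("mbi_gain must have one entry per subject")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mbi_base < 0:
            raise ValueError("mbi_base must be >= 0")
        if self.n_voxels > int(np.prod(self.grid_shape)):
            raise ValueError("n_voxels exceeds the grid size")
        nyq = 1.0 / (2.0 * self.tr)
        per_voxel = bool(self.components) and isinstance(self.components[0], list)
        groups = self.components if per_voxel else [self.components]
        for group in groups:
            for f, a, _ in group:
                if f >= nyq:
                    raise ValueError(
                        f"component frequency {f} Hz >= Nyquist {nyq} Hz"
                    )
                if a < 0:
                    raise ValueError("component amplitudes must be >= 0")

    @property
    def delta_f(self) -> float:
        return 1.0 / (self.n_timepoints * self.tr)

    def snapped(self, freq: float) -> float:
        """Frequency rounded to the nearest FFT bin (if snapping is on)."""
        if not self.snap_to_grid:
            return freq
        return round(freq / self.delta_f) * self.delta_f


def _voxel_components(spec: SyntheticSpec, voxel: int) -> list[Component]:
    comps = spec.components
    per_voxel = bool(comps) and isinstance(comps[0], list)
    return comps[voxel] if per_voxel else comps


def make_voxel(spec: SyntheticSpec, subject: int, voxel: int) -> np.ndarray:
    """One voxel's time series, bit-reproducible from (seed, subject, voxel)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(subject, voxel))
    )
    t = np.arange(spec.n_timepoints) * spec.tr
    gain = spec.mbi_gain[subject]
    s = np.full(spec.n_timepoints, spec.mbi_base * gain)
    for freq, amp, phase in _voxel_components(spec, voxel):
        f = spec.snapped(freq)
        s = s + gain * amp * np.cos(2 * np.pi * f * t + phase)
    if spec.noise_sd > 0:
        sd = spec.noise_sd * gain if spec.noise_gain_scaled else spec.noise_sd
        s = s + rng.normal(0.0, sd, spec.n_timepoints)
    return s


def _ground_truth(spec: SyntheticSpec) -> pd.DataFrame:
    """Analytic per-(subject, voxel) truths for the noiseless signal part.

    ``rms_inband_true`` / ``rms_total_true`` are the RMS of the sinusoidal
    components inside [fl, fh] and of all components (a cosine of amplitude
    A contributes A^2/2 to the mean square); white noise adds noise_sd^2 to
    the expected total mean square on top of these.
    """
    rows = []
    for j in range(spec.n_subjects):
        gain = spec.mbi_gain[j]
        for v in range(spec.n_voxels):
            comps = [(spec.snapped(f), a) for f, a, _ in _voxel_components(spec, v)]
            total = sum(a**2 / 2 for _, a in comps)
            inband = sum(
                a**2 / 2 for f, a in comps if spec.band.fl <= f <= spec.band.fh
            )
            rows.append(
                {
                    "subject": j,
                    "voxel": v,
                    "mbi_true": spec.mbi_base * gain,
                    "rms_inband_true": gain * np.sqrt(inband),
                    "rms_total_true": gain * np.sqrt(total),
                }
            )
    return pd.DataFrame(rows)


def make_dataset(spec: SyntheticSpec) -> tuple[list[BoldSeries], pd.DataFrame]:
    """All subjects' series on a shared toy grid, plus the ground-truth table."""
    shape = spec.grid_shape
    flat = np.arange(spec.n_voxels)  # sorted flat indices, C order
    coords = np.column_stack(np.unravel_index(flat, shape))
    ref = SpatialRef(np.diag([3.0, 3.0, 3.0, 1.0]), shape)
    subjects = []
    for j in range(spec.n_subjects):
        data = np.vstack(
            [make_voxel(spec, j, v) for v in range(spec.n_voxels)]
        )
        subjects.append(
            BoldSeries(
                data=data,
                tr=spec.tr,
                voxel_index=coords,
                spatial_ref=ref,
            )
        )
    return subjects, _ground_truth(spec)


def write_dataset(spec: SyntheticSpec, outdir) -> list:
    """Materialize the dataset as NIfTI fixtures plus a ground-truth CSV."""
    import nibabel as nib
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects, truth = make_dataset(spec)
    shape = spec.grid_shape
    affine = subjects[0].spatial_ref.affine

    mask = np.zeros(shape, dtype=np.uint8)
    i, j, k = subjects[0].voxel_index.T
    mask[i, j, k] = 1
    nib.save(nib.Nifti1Image(mask, affine), str(outdir / "mask.nii.gz"))

    paths = [outdir / "mask.nii.gz", outdir / "ground_truth.csv"]
    for sidx, series in enumerate(subjects):
        vol = np.zeros(shape + (spec.n_timepoints,))
        vol[i, j, k, :] = series.data
        img = nib.Nifti1Image(vol.astype(np.float32), affine)
        img.header.set_zooms((3.0, 3.0, 3.0, spec.tr))
        path = outdir / f"sub-{sidx:03d}_bold.nii.gz"
        nib.save(img, str(path))
        paths.append(path)
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    return paths
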