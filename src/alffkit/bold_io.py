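"""NIfTI I/O for masked BOLD time series and voxelwise metric maps.

A 4D BOLD volume plus a 3D mask are reduced to an ``M voxels x N timepoints``
matrix (:class:`BoldSeries`); per-voxel metrics travel as :class:`VoxelMap`
and can be written back into volume space with the input affine unchanged.
Voxel order is always the sorted flattened index in the array's native (C)
order, so re-reading the same files yields bit-identical matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SpatialRef", "BoldSeries", "VoxelMap", "read_bold", "write_map"]

# raw fractional metrics carry a hard [0, 1] invariant; their normalized
# variants (mean pinned to 1) do not
_FRACTIONAL_NAMES = ("amfALFF", "qmfALFF")
_FALFF_SLACK = 1e-9
_NORM_MEAN_SLACK = 1e-9


@dataclass(frozen=True)
class SpatialRef:
    """Affine + 3D shape of the volume a voxel set was extracted from."""

    affine: np.ndarray  # (4, 4)
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if len(self.shape) != 3:
            raise ValueError(f"shape must be 3D, got {self.shape}")


@dataclass
class BoldSeries:
    """Masked voxel-by-time BOLD matrix with acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (M, N)
        BOLD intensities, one row per retained voxel, in arbitrary scanner
        units. M >= 1, N >= 8.
    tr : float
        Repetition time in seconds (> 0); sets the spectral resolution
        1/(N*TR) and the Nyquist frequency 1/(2*TR).
    voxel_index : ndarray, shape (M, 3)
        Integer (i, j, k) coordinates of each row in the source volume.
    spatial_ref : SpatialRef
        Affine/shape of the source volume, carried through to output maps.
    demeaned : bool
        True once each row's temporal mean has been removed.
    voxel_means : ndarray, shape (M,), optional
        Raw per-voxel temporal means, stored when demeaning so mean BOLD
        intensity (MBI) remains available downstream.
    n_dropped : int
        Count of in-mask voxels discarded at read time for zero temporal
        variance.
    """

    data: np.ndarray
    tr: float
    voxel_index: np.ndarray
    spatial_ref: SpatialRef
    demeaned: bool = False
    voxel_means: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (voxels x timepoints)")
        m, n = self.data.shape
        if m < 1:
            raise ValueError("need at least one voxel")
        if n < 8:
            raise ValueError(f"need at least 8 timepoints, got {n}")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.voxel_index.shape != (m, 3):
            raise ValueError(
                f"voxel_index shape {self.voxel_index.shape} != ({m}, 3)"
            )
        shape = np.asarray(self.spatial_ref.shape)
        if (self.voxel_index < 0).any() or (self.voxel_index >= shape).any():
            raise ValueError("voxel_index coordinates fall outside the volume")
        if self.voxel_means is not None:
            self.voxel_means = np.asarray(self.voxel_means, dtype=np.float64)
            if self.voxel_means.shape != (m,):
                raise ValueError("voxel_means length must equal voxel count")
        if self.demeaned:
            scale = np.sqrt(np.mean(self.data**2, axis=1))
            resid = np.abs(self.data.mean(axis=1))
            if np.any(resid > 1e-8 * np.maximum(scale, 1e-300)):
                raise ValueError("demeaned flag set but row means are not ~0")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def temporal_means(self) -> np.ndarray:
        """Raw per-voxel temporal means (MBI per voxel).

        Uses the means stored at demeaning time if present, otherwise
        computes them from the data; the two are the same arithmetic.
        """
        if self.voxel_means is not None:
            return self.voxel_means
        if self.demeaned:
            raise ValueError("series demeaned without stored voxel means")
        return self.data.mean(axis=1)

    def with_data(self, data: np.ndarray, *, demeaned: bool | None = None) -> "BoldSeries":
        """Copy of this series with new sample values, same geometry."""
        return replace(
            self,
            data=data,
            demeaned=self.demeaned if demeaned is None else demeaned,
        )


@dataclass
class VoxelMap:
    """One scalar metric value per retained voxel."""

    values: np.ndarray
    metric_name: str
    voxel_index: np.ndarray
    spatial_ref: SpatialRef

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1D vector")
        if self.voxel_index.shape != (self.values.size, 3):
            raise ValueError(
                f"voxel_index shape {self.voxel_index.shape} does not match "
                f"{self.values.size} values"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and self.metric_name in _FRACTIONAL_NAMES:
            if finite.min() < -_FALFF_SLACK or finite.max() > 1 + _FALFF_SLACK:
                raise ValueError(
                    f"{self.metric_name} values outside [0, 1]: "
                    f"range [{finite.min()}, {finite.max()}]"
                )
        if finite.size and self.metric_name.endswith(("_norm", "_norm_z")):
            mean = finite.mean()
            if abs(mean - 1.0) > _NORM_MEAN_SLACK:
                raise ValueError(
                    f"normalized map {self.metric_name} has mean {mean}, not 1"
                )

    @property
    def n_voxels(self) -> int:
        return self.values.size


def _read_tr(img: nib.Nifti1Image, tr: float | None) -> float:
    if tr is not None:
        if not tr > 0:
            raise ValueError(f"TR override must be positive, got {tr}")
        return float(tr)
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if header_tr <= 0:
        raise ValueError(
            "TR not recoverable from the NIfTI header (pixdim[4] <= 0); "
            "pass an explicit TR"
        )
    if header_tr == 1.0:
        warnings.warn(
            "header TR is exactly 1.0 s, a common placeholder; pass an "
            "explicit TR if this is not the true repetition time",
            stacklevel=2,
        )
    return header_tr


def read_bold(
    bold_path,
    mask_path,
    tr: float | None = None,
) -> BoldSeries:
    """Read a 4D BOLD volume restricted to a 3D mask.

    Rows are the in-mask voxels with non-zero temporal variance, ordered by
    sorted flattened index (C order) for reproducibility. Zero-variance
    in-mask voxels are dropped with a logged count (every downstream metric
    divides by a spectral or RMS quantity that would vanish for them); the
    count is kept on the returned series as ``n_dropped``.

    Parameters
    ----------
    bold_path, mask_path : path-like
        4D BOLD and 3D mask NIfTI files on an identical spatial grid.
    tr : float, optional
        Repetition time override in seconds; required when the header's
        time step is missing or zero.
    """
    bold_img = nib.load(str(bold_path))
    mask_img = nib.load(str(mask_path))
    bold_shape = tuple(bold_img.shape)
    mask_shape = tuple(mask_img.shape)
    if len(bold_shape) != 4:
        raise ValueError(f"BOLD volume must be 4D, got shape {bold_shape}")
    if len(mask_shape) != 3 or bold_shape[:3] != mask_shape:
        raise ValueError(
            f"spatial grid mismatch: BOLD {bold_shape} vs mask {mask_shape}"
        )
    tr_s = _read_tr(bold_img, tr)

    mask = np.asarray(mask_img.dataobj) > 0
    flat = np.flatnonzero(mask.reshape(-1))  # C order, sorted
    if flat.size == 0:
        raise ValueError("mask selects no voxels")
    coords = np.column_stack(np.unravel_index(flat, mask_shape))

    vol = np.asarray(bold_img.dataobj, dtype=np.float64)
    data = vol.reshape(-1, bold_shape[3])[flat]

    variable = data.var(axis=1) > 0
    n_dropped = int((~variable).sum())
    if n_dropped:
        logger.info(
            "dropped %d in-mask voxel(s) with zero temporal variance", n_dropped
        )
        data = data[variable]
        coords = coords[variable]
    if data.shape[0] == 0:
        raise ValueError("all in-mask voxels have zero temporal variance")

    return BoldSeries(
        data=data,
        tr=tr_s,
        voxel_index=coords,
        spatial_ref=SpatialRef(bold_img.affine, mask_shape),
        demeaned=False,
        n_dropped=n_dropped,
    )


def write_map(
    vmap: VoxelMap,
    path,
    *,
    background: float = np.nan,
    dtype: str = "float32",
) -> None:
    """Write a voxel map back into 3D volume space.

    Out-of-mask voxels are filled with ``background`` (NaN by default, 0
    under the flag). Output is float32 by the usual neuroimaging convention;
    pass ``dtype="float64"`` for a bit-exact round trip. The metric label is
    stored in the header ``descrip`` field and the input affine is carried
    unchanged.
    """
    if dtype not in ("float32", "float64"):
        raise ValueError(f"dtype must be float32 or float64, got {dtype!r}")
    ref = vmap.spatial_ref
    vol = np.full(ref.shape, background, dtype=np.float64)
    i, j, k = vmap.voxel_index.T
    vol[i, j, k] = vmap.values
    img = nib.Nifti1Image(vol.astype(dtype), ref.affine)
    img.header["descrip"] = vmap.metric_name.encode()[:79]
    nib.save(img, str(path))
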