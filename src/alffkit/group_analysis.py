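"""Subject- and voxel-level metric tables and their correlation structure.

Mirrors the standard two-level analysis: at the subject level each metric is
the mask mean of the subject's map and MBI is the mean intensity across
voxels; at the voxel level MBI is averaged across subjects per voxel, the
ALFF columns are across-subject means of per-subject *normalized* maps, and
the fractional columns are across-subject means of the (scale-free) fALFF
maps. Pairwise association is summarized with Pearson r and two-sided
p-values (raw, no multiple-testing correction), optionally within clusters
of mean BOLD intensity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .bold_io import BoldSeries
from .normalize import mbi_subject, mbi_voxel, normalize_map
from .spectral import (
    BandSpec,
    am_alff,
    am_falff,
    amplitude_spectrum,
    band_indices,
    demean,
    qm_alff_freq,
    qm_falff_freq,
)

__all__ = [
    "METRIC_COLUMNS",
    "subject_table",
    "voxel_table",
    "correlation_matrix",
    "cluster_mbi",
    "plot_correlation_matrix",
]

METRIC_COLUMNS = ["MBI", "amALFF", "qmALFF", "amfALFF", "qmfALFF"]
_ID_COLUMNS = ("subject", "voxel", "cluster")


def _subject_maps(series: BoldSeries, band: BandSpec) -> dict:
    dm = demean(series)
    spec = amplitude_spectrum(dm)
    idx = band_indices(band, dm.n_timepoints, dm.tr)
    return {
        "amALFF": am_alff(spec, idx),
        "qmALFF": qm_alff_freq(spec, idx),
        "amfALFF": am_falff(spec, idx),
        "qmfALFF": qm_falff_freq(spec, idx),
    }


def subject_table(
    subjects: list[BoldSeries], band: BandSpec | None = None
) -> pd.DataFrame:
    """One row per subject: MBI and the mask mean of each metric map."""
    band = band or BandSpec()
    _check_support(subjects)
    rows = []
    for j, series in enumerate(subjects):
        maps = _subject_maps(series, band)
        row = {"subject": j, "MBI": mbi_subject(series)}
        row.update({name: float(m.values.mean()) for name, m in maps.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def voxel_table(
    subjects: list[BoldSeries], band: BandSpec | None = None
) -> pd.DataFrame:
    """One row per voxel: across-subject means of per-subject maps.

    The ALFF columns are means of *normalized* maps (each subject's map
    divided by its own mask mean), so single-subject tables have
    normalized-column mean 1 and per-subject gain factors cancel; the
    fractional columns need no normalization.
    """
    band = band or BandSpec()
    _check_support(subjects)
    mbi = mbi_voxel(subjects)
    acc = {name: [] for name in ("amALFF_norm", "qmALFF_norm", "amfALFF", "qmfALFF")}
    for series in subjects:
        maps = _subject_maps(series, band)
        acc["amALFF_norm"].append(normalize_map(maps["amALFF"]).values)
        acc["qmALFF_norm"].append(normalize_map(maps["qmALFF"]).values)
        acc["amfALFF"].append(maps["amfALFF"].values)
        acc["qmfALFF"].append(maps["qmfALFF"].values)
    table = {"voxel": np.arange(mbi.n_voxels), "MBI": mbi.values}
    table.update({name: np.mean(stack, axis=0) for name, stack in acc.items()})
    return pd.DataFrame(table)


def _check_support(subjects: list[BoldSeries]) -> None:
    if not subjects:
        raise ValueError("need at least one subject")
    first = subjects[0]
    for s in subjects[1:]:
        if not np.array_equal(s.voxel_index, first.voxel_index):
            raise ValueError("subjects do not share the same mask support")


def _metric_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _ID_COLUMNS]


def _pairwise(table: pd.DataFrame, cols: list[str]):
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            x, y = table[a].to_numpy(float), table[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"correlation between {a} and {b} undefined "
                    "(constant column)",
                    stacklevel=3,
                )
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


def correlation_matrix(table: pd.DataFrame, *, by_cluster: bool = False):
    """Pairwise Pearson r and two-sided p across the metric columns.

    Returns ``(r, p)`` DataFrames, or a ``{label: (r, p)}`` dict when
    ``by_cluster`` is set and the table carries cluster labels. Constant
    columns yield NaN entries with a warning rather than an error.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation")
    cols = _metric_columns(table)
    if by_cluster:
        if "cluster" not in table.columns:
            raise ValueError("by_cluster requires a 'cluster' column")
        return {
            label: _pairwise(sub, cols)
            for label, sub in table.groupby("cluster", sort=True)
        }
    return _pairwise(table, cols)


def _kmeans_1d(x: np.ndarray, k: int, max_iter: int = 300) -> np.ndarray:
    """Deterministic 1-D Lloyd k-means with quantile seeding.

    Centers start at the (i + 0.5)/k quantiles; assignment ties go to the
    lower-mean cluster. Returns integer labels ordered by cluster mean
    ascending.
    """
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    for _ in range(max_iter):
        labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [x[labels == i].mean() if (labels == i).any() else centers[i]
             for i in range(k)]
        )
        if np.allclose(new, centers, rtol=0, atol=0):
            break
        centers = new
    order = np.argsort(centers, kind="stable")
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    return rank[labels]


def cluster_mbi(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Label rows by 1-D k-means on the MBI column.

    Labels are ordered by cluster mean ascending: ``l``/``m``/``h`` for
    k = 3, otherwise ``c0``..``c{k-1}``. A convenience for exploring
    MBI strata; the clustering itself is not a property of the metrics.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = table["MBI"].to_numpy(float)
    if len(x) < k:
        raise ValueError(f"k={k} exceeds the {len(x)} rows")
    if np.unique(x).size < k:
        raise ValueError(f"k={k} exceeds the number of distinct MBI values")
    labels = _kmeans_1d(x, k)
    names = ["l", "m", "h"] if k == 3 else [f"c{i}" for i in range(k)]
    out = table.copy()
    out["cluster"] = [names[i] for i in labels]
    return out


def plot_correlation_matrix(r: pd.DataFrame, path) -> None:
    """Save the correlation matrix as an annotated heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(r) + 1.5, 1.2 * len(r)))
    im = ax.imshow(r.to_numpy(float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(r.columns)), r.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(r.index)), r.index)
    for i in range(len(r)):
        for j in range(len(r)):
            val = r.iloc[i, j]
            ax.text(
                j, i, "—" if np.isnan(val) else f"{val:.2f}",
                ha="center", va="center", fontsize=9,
            )
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
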