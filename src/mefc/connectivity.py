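"""Seed-based correlation maps and ROI-by-ROI correlation matrices.

The seed analysis extracts the mean time series of a labelled seed region
and Pearson-correlates it with every in-mask voxel.  The ROI analysis
correlates mean time series of every parcellation region of the selected
classes, subcortical block first then cortical (ascending label order
within each), yielding a symmetric unit-diagonal matrix — with the
emulated 16-subcortical + 148-cortical scheme, 164 x 164.

Raw r is carried throughout (no Fisher z by default, matching the analysis
being emulated); thresholding is inclusive (r >= threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BoldSeries, Parcellation

__all__ = [
    "ConnectivityMap",
    "ConnectivityMatrix",
    "seed_map",
    "roi_matrix",
    "threshold_binarize",
]


@dataclass
class ConnectivityMap:
    """Voxelwise Pearson correlation with a seed's mean time series."""

    r_map: np.ndarray
    seed_label: int
    n_timepoints: int
    df_effective: int
    zero_variance_mask: np.ndarray | None = None


@dataclass
class ConnectivityMatrix:
    """Symmetric unit-diagonal ROI x ROI Pearson correlation matrix."""

    r: np.ndarray
    roi_labels: list[int]
    n_timepoints: int

    def __post_init__(self) -> None:
        if self.r.shape != (len(self.roi_labels), len(self.roi_labels)):
            raise ValueError("matrix shape does not match roi_labels")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")


def _masked_series(b: BoldSeries) -> tuple[np.ndarray, tuple]:
    vox = np.argwhere(b.mask)
    idx = tuple(vox.T)
    return b.data[idx].astype(float), idx


def seed_map(b: BoldSeries, p: Parcellation, seed_label: int) -> ConnectivityMap:
    """Correlate the seed-mean time series with every in-mask voxel.

    Zero-variance voxels get r = 0 and are flagged.  The effective df is
    n_timepoints - 2 minus the counted df loss accumulated in the series'
    ledger.
    """
    seed_vox = p.roi_mask(seed_label) & b.mask
    if not seed_vox.any():
        raise ValueError(f"seed label {seed_label} has no in-mask voxels")
    seed_ts = b.data[seed_vox].mean(axis=0)
    if seed_ts.std() == 0:
        raise ValueError(f"seed label {seed_label} has a constant mean series")

    ts, idx = _masked_series(b)
    zc = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(zc, axis=1)
    zero = norms == 0
    norms[zero] = 1.0
    sc = seed_ts - seed_ts.mean()
    r = (zc @ sc) / (norms * np.linalg.norm(sc))
    r[zero] = 0.0
    r = np.clip(r, -1.0, 1.0)

    r_map = np.zeros(b.mask.shape)
    r_map[idx] = r
    flag = np.zeros(b.mask.shape, dtype=bool)
    flag[idx] = zero
    df_eff = b.n_volumes - 2 - b.total_df_loss
    return ConnectivityMap(r_map=r_map, seed_label=int(seed_label),
                           n_timepoints=b.n_volumes, df_effective=df_eff,
                           zero_variance_mask=flag)


def roi_matrix(
    b: BoldSeries,
    p: Parcellation,
    roi_classes: tuple[str, ...] = ("cortical", "subcortical"),
) -> ConnectivityMatrix:
    """ROI-mean Pearson correlation matrix over the selected label classes.

    Ordering: subcortical labels first, then cortical, then seed (if
    selected), ascending label order within each block.
    """
    labels = p.labels_of_class(roi_classes)
    if not labels:
        raise ValueError(f"no labels of classes {roi_classes}")
    means = []
    empty = []
    for lab in labels:
        m = p.roi_mask(lab) & b.mask
        if not m.any():
            row = p.table.loc[p.table["label"] == lab].iloc[0]
            empty.append(f"{lab} ({row['name']})")
            continue
        means.append(b.data[m].mean(axis=0))
    if empty:
        raise ValueError(f"ROIs with no in-mask voxels: {', '.join(empty)}")
    r = np.corrcoef(np.asarray(means))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r=r, roi_labels=labels, n_timepoints=b.n_volumes)


def threshold_binarize(x, r_thr: float):
    """Binarize at r >= r_thr (inclusive).

    For a ConnectivityMap returns a binary 3D array; for a
    ConnectivityMatrix returns a binary matrix with the diagonal forced to 0
    (self-correlations never count as connections).
    """
    if not -1.0 < r_thr <= 1.0:
        raise ValueError(f"r_thr must be in (-1, 1], got {r_thr}")
    if isinstance(x, ConnectivityMap):
        return (x.r_map >= r_thr).astype(np.uint8)
    if isinstance(x, ConnectivityMatrix):
        out = (x.r >= r_thr).astype(np.uint8)
        np.fill_diagonal(out, 0)
        return out
    arr = np.asarray(x)
    out = (arr >= r_thr).astype(np.uint8)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1]:
        np.fill_diagonal(out, 0)
    return out
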