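"""Test-retest reproducibility metrics.

Two statistics compare a subject's two sessions:

* Dice coefficient for binarized maps or matrices,
  DC = 2 * |A and B| / (|A| + |B|), ranging 0-1 with 1 = perfect overlap;
  for symmetric matrices only the strictly-lower-triangle entries enter.
* REP for (non-negative) FCD maps, voxelwise
  REP = 1 - |x1 - x2| / (x1 + x2), ranging 0-1 with 1 for identical values
  (0/0 counts as identical, hence 1); unlike percent change this is robust
  to large outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fcd import FCDMap

__all__ = ["ReproResult", "dice_maps", "dice_matrices", "rep_fcd"]


@dataclass
class ReproResult:
    """Voxelwise REP map and its region summary for one map pair."""

    rep_map: np.ndarray
    region_mean_rep: float
    variant: str
    r_thr: float


def dice_maps(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two binary volumes.

    Both-empty input has no defined overlap fraction: returns NaN (reported
    as missing, deliberately distinct from 0).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    va, vb = int(a.sum()), int(b.sum())
    if va + vb == 0:
        return float("nan")
    overlap = int((a & b).sum())
    return 2.0 * overlap / (va + vb)


def dice_matrices(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient over strictly-lower-triangle entries of two binary
    symmetric matrices (the diagonal and upper triangle are redundant)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("inputs must be square matrices of the same size")
    rows, cols = np.tril_indices(a.shape[0], k=-1)
    return dice_maps(a[rows, cols], b[rows, cols])


def rep_fcd(m1: FCDMap, m2: FCDMap, region_mask: np.ndarray) -> ReproResult:
    """Voxelwise REP between two FCD maps of the same variant, plus its
    mean over ``region_mask`` (typically grey matter)."""
    if m1.variant != m2.variant:
        raise ValueError(f"variant mismatch: {m1.variant} vs {m2.variant}")
    x1 = np.asarray(m1.counts, dtype=float)
    x2 = np.asarray(m2.counts, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"shape mismatch {x1.shape} vs {x2.shape}")
    if np.any(x1 < 0) or np.any(x2 < 0):
        raise ValueError("REP is defined for non-negative FCD values")
    total = x1 + x2
    safe = np.where(total > 0, total, 1.0)
    rep = 1.0 - np.abs(x1 - x2) / safe
    rep[total == 0] = 1.0        # 0/0: two identical values
    region_mask = np.asarray(region_mask).astype(bool)
    if not region_mask.any():
        raise ValueError("empty region mask")
    return ReproResult(rep_map=rep,
                       region_mean_rep=float(rep[region_mask].mean()),
                       variant=m1.variant, r_thr=m1.r_thr)
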