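"""Functional connectivity density (FCD) mapping.

Two degree-like statistics at a fixed Pearson correlation threshold
(default r >= 0.6):

* local FCD — for each voxel, the size of the spatially contiguous cluster
  of voxels all correlated with that voxel above threshold, grown outward
  from the voxel (correlation is always against the index voxel's series,
  never chained);
* global FCD — for each voxel, the count of voxels anywhere in the mask
  correlated with it above threshold.

Conventions (the source tools in this literature differ, so both are
exposed): the local count includes the index voxel itself (minimum 1 inside
the mask); the global count excludes it; spatial contiguity defaults to
26-connectivity (faces, edges and corners).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .types import BoldSeries

__all__ = ["FCDMap", "lfcd", "gfcd", "summarize_fcd", "neighbor_offsets"]


def neighbor_offsets(scheme: int) -> list[tuple[int, int, int]]:
    """Voxel-neighborhood offsets for 6 (faces), 18 (+edges) or 26
    (+corners) connectivity."""
    if scheme not in (6, 18, 26):
        raise ValueError(f"neighbor scheme must be 6, 18 or 26, got {scheme}")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                k = abs(dx) + abs(dy) + abs(dz)
                if k == 0:
                    continue
                if scheme == 6 and k > 1:
                    continue
                if scheme == 18 and k > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


@dataclass
class FCDMap:
    """Voxelwise connection counts with the settings that produced them."""

    counts: np.ndarray
    variant: str                 # "local" or "global"
    r_thr: float
    neighbor_scheme: int | None = None
    self_inclusive: bool | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("local", "global"):
            raise ValueError(f"variant must be local or global, got {self.variant}")
        if np.any(self.counts < 0):
            raise ValueError("FCD counts must be non-negative")


def _standardized(b: BoldSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-mask series standardized to unit norm; zero-variance rows zeroed
    (so their correlation with anything is 0)."""
    vox = np.argwhere(b.mask)
    ts = b.data[tuple(vox.T)].astype(float)
    ts = ts - ts.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(ts, axis=1, keepdims=True)
    zero = norm[:, 0] == 0
    norm[zero] = 1.0
    ts /= norm
    ts[zero] = 0.0
    return ts, vox, zero


def lfcd(
    b: BoldSeries,
    r_thr: float = 0.6,
    neighbor_scheme: int = 26,
    self_inclusive: bool = True,
) -> FCDMap:
    """Local FCD: breadth-first cluster growth from every in-mask voxel,
    admitting a neighbor u iff corr(index, u) >= r_thr."""
    if b.n_volumes < 3:
        raise ValueError("need at least 3 time points")
    if not b.mask.any():
        raise ValueError("empty mask")
    offs = neighbor_offsets(neighbor_scheme)
    ts, vox, _ = _standardized(b)
    shape = b.mask.shape
    row = -np.ones(shape, dtype=np.int64)
    row[tuple(vox.T)] = np.arange(len(vox))

    counts = np.zeros(shape, dtype=np.int32)
    for i, v in enumerate(map(tuple, vox)):
        zi = ts[i]
        visited = {v}
        cluster = 1
        queue = deque([v])
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offs:
                u = (x + dx, y + dy, z + dz)
                if (u in visited or not (0 <= u[0] < shape[0]
                        and 0 <= u[1] < shape[1] and 0 <= u[2] < shape[2])):
                    continue
                j = row[u]
                if j < 0:
                    continue
                visited.add(u)
                if float(zi @ ts[j]) >= r_thr:
                    cluster += 1
                    queue.append(u)
        counts[v] = cluster if self_inclusive else cluster - 1
    return FCDMap(counts=counts, variant="local", r_thr=r_thr,
                  neighbor_scheme=neighbor_scheme, self_inclusive=self_inclusive)


def gfcd(
    b: BoldSeries,
    r_thr: float = 0.6,
    include_self: bool = False,
    chunk: int = 256,
) -> FCDMap:
    """Global FCD: whole-mask suprathreshold correlation count per voxel.

    Computed in row chunks against the full standardized series matrix so
    memory stays O(chunk * n_voxels) rather than the full pairwise matrix.
    """
    if b.n_volumes < 3:
        raise ValueError("need at least 3 time points")
    if not b.mask.any():
        raise ValueError("empty mask")
    ts, vox, zero = _standardized(b)
    n = len(vox)
    counts = np.zeros(n, dtype=np.int64)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        r = ts[lo:hi] @ ts.T
        hits = (r >= r_thr).sum(axis=1)
        # self-correlation is 1 for non-degenerate rows; remove unless wanted
        if not include_self:
            hits -= (np.diagonal(r, offset=lo) >= r_thr)[: hi - lo]
        counts[lo:hi] = hits
    out = np.zeros(b.mask.shape, dtype=np.int32)
    out[tuple(vox.T)] = counts
    return FCDMap(counts=out, variant="global", r_thr=r_thr,
                  self_inclusive=include_self)


def summarize_fcd(m: FCDMap, region_mask: np.ndarray) -> float:
    """Arithmetic mean of FCD counts over a region (e.g. grey matter)."""
    region_mask = region_mask.astype(bool)
    if not region_mask.any():
        raise ValueError("empty region mask")
    return float(m.counts[region_mask].mean())
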