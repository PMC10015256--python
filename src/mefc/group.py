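"""Group-level comparison of two acquisition conditions.

Element-wise paired testing (voxel or matrix-entry wise) of condition B
minus condition A, optionally adjusting for a per-session scan-number
covariate: the differences are regressed on an intercept plus the
mean-centered covariate, and the intercept's t statistic (n - 2 df) tests
the covariate-adjusted mean difference.  Without a covariate this is the
classical paired t-test (n - 1 df).

Multiple comparisons: Benjamini-Hochberg FDR for matrices (strictly-lower-
triangle entries) and a Monte-Carlo cluster-extent threshold for maps.  The
cluster procedure simulates smooth Gaussian null volumes and calibrates the
minimum cluster size whose familywise false-positive probability is alpha;
it is a transparent stand-in for autocorrelation-function-based tools and
is not numerically equivalent to them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupResult",
    "paired_test",
    "fdr_bh",
    "cluster_threshold_mc",
    "apply_cluster_threshold",
]


@dataclass
class GroupResult:
    """Element-wise t/p values and the post-correction significance mask."""

    t_map: np.ndarray
    p_map: np.ndarray
    significant_mask: np.ndarray | None = None
    q_level: float | None = None
    cluster_min_size: int | None = None
    alpha: float | None = None
    df: int | None = None


def paired_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    covariate: np.ndarray | None = None,
) -> GroupResult:
    """Paired comparison of cond_b vs cond_a across sessions.

    ``cond_a``/``cond_b``: (n_sessions, ...) element-wise values aligned by
    session.  Zero-variance nonzero differences are flagged with infinite t
    and p = 0; exactly-zero differences give t = 0, p = 1.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"condition shapes differ: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sessions")
    d = (b - a).reshape(n, -1)

    if covariate is not None:
        c = np.asarray(covariate, dtype=float)
        if c.shape != (n,):
            raise ValueError(f"covariate must have one value per session ({n})")
        x = np.column_stack([np.ones(n), c - c.mean()])
    else:
        x = np.ones((n, 1))
    df = n - x.shape[1]

    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ x.T @ d
    resid = d - x @ beta
    mse = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(np.clip(mse * xtx_inv[0, 0], 0.0, None))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[0] / np.where(se > 0, se, 1.0), 0.0)
    degenerate = (se == 0) & (beta[0] != 0)
    t[degenerate] = np.sign(beta[0][degenerate]) * np.inf
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[degenerate] = 0.0
    p[(se == 0) & (beta[0] == 0)] = 1.0

    shape = a.shape[1:]
    return GroupResult(t_map=t.reshape(shape), p_map=p.reshape(shape), df=df)


def fdr_bh(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection vector at FDR level q.

    For matrix-valued tests, pass only the strictly-lower-triangle p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def cluster_threshold_mc(
    map_shape: tuple[int, int, int],
    mask: np.ndarray,
    smoothness_fwhm_mm: float,
    voxel_p: float = 0.001,
    alpha: float = 0.05,
    n_iter: int = 1000,
    seed: int = 0,
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> int:
    """Monte-Carlo minimum cluster size controlling the familywise
    false-positive cluster probability at ``alpha``.

    Each iteration draws a white Gaussian volume, smooths it to the given
    FWHM, z-standardizes within the mask, thresholds two-sided at
    ``voxel_p`` and records the largest suprathreshold 26-connected in-mask
    cluster.  Returns the ceiling of the (1 - alpha) quantile of those
    maxima (at least 1).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = np.random.default_rng(seed)
    sigma_vox = np.array([
        (smoothness_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))) / v
        for v in voxel_mm])
    z_crit = stats.norm.isf(voxel_p / 2.0)
    structure = np.ones((3, 3, 3), dtype=bool)   # 26-connectivity

    maxima = np.zeros(n_iter)
    for it in range(n_iter):
        vol = rng.standard_normal(map_shape)
        if smoothness_fwhm_mm > 0:
            vol = ndimage.gaussian_filter(vol, sigma_vox)
        inm = vol[mask]
        vol = (vol - inm.mean()) / inm.std()
        supra = (np.abs(vol) >= z_crit) & mask
        if supra.any():
            labels, n_lab = ndimage.label(supra, structure=structure)
            if n_lab:
                sizes = np.bincount(labels.ravel())[1:]
                maxima[it] = sizes.max()
    thr = math.ceil(float(np.quantile(maxima, 1.0 - alpha)))
    return max(1, thr)


def apply_cluster_threshold(
    result: GroupResult,
    mask: np.ndarray,
    voxel_p: float,
    cluster_min_size: int,
    alpha: float | None = None,
) -> GroupResult:
    """Keep only suprathreshold (p < voxel_p) 26-connected clusters of at
    least ``cluster_min_size`` voxels; returns a result with the mask set."""
    mask = np.asarray(mask).astype(bool)
    supra = (result.p_map < voxel_p) & mask
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n_lab = ndimage.label(supra, structure=structure)
    keep = np.zeros_like(supra)
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        if comp.sum() >= cluster_min_size:
            keep |= comp
    return GroupResult(t_map=result.t_map, p_map=result.p_map,
                       significant_mask=keep, cluster_min_size=cluster_min_size,
                       alpha=alpha, df=result.df)
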