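"""T2*/S0 estimation and multi-echo combination.

T2* is estimated voxelwise by an unweighted ordinary-least-squares fit of
log(signal) against echo time ("log-linear fit"): slope = -1/T2*,
intercept = log(S0).  Echoes are then combined with the standard
T2*-weighted scheme, w_i proportional to TE_i * exp(-TE_i / T2*),
normalized to sum to one across echoes, which restores BOLD sensitivity
lost at any single echo time.  A temporal SNR map with optional
sqrt(N_timepoints) scaling (to compare scans of different lengths on a
statistical-efficiency footing) completes the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BoldSeries, MultiEchoSeries

__all__ = ["T2StarFit", "fit_t2star", "combine_echoes", "tsnr",
           "COMBINE_SCHEMES"]

COMBINE_SCHEMES = ("t2star_weighted", "summation", "normalized_t2star")


@dataclass
class T2StarFit:
    """Voxelwise T2* (ms) and S0 maps from the log-linear fit.

    ``valid_mask`` marks voxels where the fit used at least two positive
    samples; elsewhere T2* is set to the upper clamp.
    """

    t2s_map: np.ndarray
    s0_map: np.ndarray
    valid_mask: np.ndarray
    t2s_min: float = 2.0
    t2s_max: float = 300.0


def _loglinear(signal: np.ndarray, te: np.ndarray,
               t2s_min: float, t2s_max: float):
    """OLS of log(signal) on TE, per row, using only positive samples.

    signal: (n_vox, n_echo). Returns (t2s, s0, valid) per row.
    """
    n_vox, n_echo = signal.shape
    pos = signal > 0
    valid = pos.sum(axis=1) >= 2
    logs = np.where(pos, np.log(np.where(pos, signal, 1.0)), 0.0)

    w = pos.astype(float)
    n = w.sum(axis=1)
    n_safe = np.where(n > 0, n, 1.0)
    sx = (w * te).sum(axis=1)
    sy = (w * logs).sum(axis=1)
    sxx = (w * te ** 2).sum(axis=1)
    sxy = (w * te * logs).sum(axis=1)
    denom = n_safe * sxx - sx ** 2
    denom = np.where(np.abs(denom) > 0, denom, 1.0)
    slope = (n_safe * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n_safe

    t2s = np.full(n_vox, t2s_max)
    decaying = valid & (slope < 0)
    t2s[decaying] = np.clip(-1.0 / slope[decaying], t2s_min, t2s_max)
    s0 = np.where(valid, np.exp(intercept), 0.0)
    return t2s, s0, valid


def fit_t2star(me: MultiEchoSeries, use_mean_over_time: bool = True,
               t2s_min: float = 2.0, t2s_max: float = 300.0) -> T2StarFit:
    """Log-linear T2*/S0 fit, either on the temporal mean signal (default)
    or per volume with the per-volume estimates averaged.

    Voxels without two positive samples are marked invalid and assigned the
    upper clamp; zero or non-decaying slopes clamp to ``t2s_max``.
    """
    if me.n_echoes < 2:
        raise ValueError(
            "T2* fit needs >= 2 echoes; for single-echo data use "
            "combine_echoes(..., scheme='summation') as a pass-through")
    te = np.asarray(me.te_ms)
    vox = np.argwhere(me.mask)
    idx = tuple(vox.T)

    if use_mean_over_time:
        sig = np.stack([d[idx].mean(axis=1) for d in me.data], axis=1)
        t2s_v, s0_v, valid_v = _loglinear(sig, te, t2s_min, t2s_max)
    else:
        acc_t2s = np.zeros(len(vox))
        acc_s0 = np.zeros(len(vox))
        acc_n = np.zeros(len(vox))
        any_valid = np.zeros(len(vox), dtype=bool)
        for t in range(me.n_volumes):
            sig = np.stack([d[idx][:, t] for d in me.data], axis=1)
            t2s_t, s0_t, valid_t = _loglinear(sig, te, t2s_min, t2s_max)
            acc_t2s[valid_t] += t2s_t[valid_t]
            acc_s0[valid_t] += s0_t[valid_t]
            acc_n[valid_t] += 1
            any_valid |= valid_t
        n_safe = np.where(acc_n > 0, acc_n, 1.0)
        t2s_v = np.where(any_valid, acc_t2s / n_safe, t2s_max)
        s0_v = np.where(any_valid, acc_s0 / n_safe, 0.0)
        valid_v = any_valid

    t2s = np.full(me.shape, t2s_max)
    s0 = np.zeros(me.shape)
    valid = np.zeros(me.shape, dtype=bool)
    t2s[idx] = t2s_v
    s0[idx] = s0_v
    valid[idx] = valid_v
    return T2StarFit(t2s_map=t2s, s0_map=s0, valid_mask=valid,
                     t2s_min=t2s_min, t2s_max=t2s_max)


def combination_weights(te_ms: np.ndarray, t2s_map: np.ndarray) -> np.ndarray:
    """Normalized T2*-weighted combination weights, shape (..., n_echo):
    w_i = TE_i * exp(-TE_i / T2*), scaled to sum to 1 across echoes."""
    te = np.asarray(te_ms)
    w = te * np.exp(-te / t2s_map[..., None])
    total = w.sum(axis=-1, keepdims=True)
    total = np.where(total > 0, total, 1.0)
    return w / total


def combine_echoes(me: MultiEchoSeries, fit: T2StarFit | None = None,
                   scheme: str = "t2star_weighted") -> BoldSeries:
    """Combine echoes into a single BOLD series.

    * ``t2star_weighted`` — per-voxel weights TE_i * exp(-TE_i/T2*),
      normalized to sum to one;
    * ``summation`` — plain voxelwise sum across echoes;
    * ``normalized_t2star`` — alias of ``t2star_weighted``: under the
      normalization used here (weights already sum to one) dividing the
      weighted sum by the sum of unnormalized weights yields the identical
      series, so the two names map to the same computation.
    """
    if scheme not in COMBINE_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {COMBINE_SCHEMES}")
    if scheme == "summation":
        data = np.sum(me.data, axis=0) if me.n_echoes > 1 else me.data[0].copy()
    else:
        if fit is None:
            raise ValueError("T2*-weighted combination requires a T2StarFit")
        if fit.t2s_map.shape != me.shape:
            raise ValueError(
                f"fit shape {fit.t2s_map.shape} does not match series {me.shape}")
        if me.n_echoes == 1:
            data = me.data[0].copy()
        else:
            w = combination_weights(np.asarray(me.te_ms), fit.t2s_map)
            data = np.zeros(me.data[0].shape)
            for i in range(me.n_echoes):
                data += w[..., i, None] * me.data[i]
    return BoldSeries(data=data, tr_ms=me.tr_ms, mask=me.mask.copy(),
                      affine=me.affine.copy(), df_ledger=[])


def tsnr(b: BoldSeries, scale_by_sqrt_ntp: bool = False) -> np.ndarray:
    """Temporal SNR: voxelwise mean over sample SD (ddof=1) of the series.

    Zero-SD voxels get NaN (excluded from any summary).  With
    ``scale_by_sqrt_ntp`` the map is multiplied by sqrt(N_timepoints) so
    scans of different lengths compare on equal statistical footing.
    """
    if b.n_volumes < 3:
        raise ValueError("tSNR needs >= 3 time points")
    mean = b.data.mean(axis=3)
    sd = b.data.std(axis=3, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.nan)
    out[~b.mask] = np.nan
    if scale_by_sqrt_ntp:
        out = out * np.sqrt(b.n_volumes)
    return out
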