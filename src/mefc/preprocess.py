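"""Standard denoising chain for a combined BOLD series.

Stages (order configurable; the default mirrors a conventional resting-state
pipeline): discard of initial non-equilibrium volumes, Gaussian smoothing,
polynomial detrending folded into a nuisance-regression design (Legendre
basis, so degrees-of-freedom accounting is unified), regression of motion /
tissue / externally supplied component time courses, and an ideal
zero-phase bandpass.  Every stage that removes regressors appends to the
series' degrees-of-freedom ledger; with the 12-motion + WM + CSF +
third-order-detrend configuration the counted loss is 12 + 2 + 3 = 17.

Component-based denoising methods (multi-echo ICA, ICA-AROMA) are out of
scope as algorithms, but their outputs plug in here: any t x m table of
component time courses is accepted as additional nuisance regressors and
counted in the ledger.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy.ndimage import gaussian_filter

from .types import BoldSeries, DfEntry

__all__ = [
    "NuisanceSet",
    "discard_initial",
    "build_design",
    "regress_nuisance",
    "bandpass",
    "smooth_gaussian",
    "motion_with_derivatives",
    "extract_tissue_signals",
    "standard_denoise",
]

FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # approx 2.3548


@dataclass
class NuisanceSet:
    """Nuisance regressors for one scan.

    motion: t x 6 (rigid-body params) or t x 12 (+ temporal derivatives);
    tissue_signals: t x k (typically WM and CSF means);
    components: t x m externally computed component time courses;
    detrend_order: Legendre polynomial detrend order (0 = constant only).
    """

    motion: np.ndarray | None = None
    tissue_signals: np.ndarray | None = None
    components: np.ndarray | None = None
    detrend_order: int = 0

    def __post_init__(self) -> None:
        if self.detrend_order < 0:
            raise ValueError("detrend_order must be >= 0")
        for name in ("motion", "tissue_signals", "components"):
            v = getattr(self, name)
            if v is not None:
                arr = np.asarray(v, dtype=float)
                if arr.ndim == 1:
                    arr = arr[:, None]
                setattr(self, name, arr)
        if self.motion is not None and self.motion.shape[1] not in (6, 12):
            raise ValueError(
                f"motion table must have 6 or 12 columns, got {self.motion.shape[1]}")


def motion_with_derivatives(motion: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Expand a t x 6 motion table to t x 12 by appending backward temporal
    differences (first row 0)."""
    m = np.asarray(motion, dtype=float)
    d = np.vstack([np.zeros((1, m.shape[1])), np.diff(m, axis=0)])
    return np.hstack([m, d])


def extract_tissue_signals(b: BoldSeries, masks: dict) -> np.ndarray:
    """WM and CSF mean time courses from eroded masks (eroding avoids GM
    partial-volume contamination; falls back to the full mask if erosion
    empties it).  Meant to be extracted before smoothing."""
    from scipy.ndimage import binary_erosion

    cols = []
    for key in ("wm", "csf"):
        m = np.asarray(masks[key]).astype(bool)
        er = binary_erosion(m)
        use = er if er.any() else m
        cols.append(b.data[use & b.mask].mean(axis=0))
    return np.column_stack(cols)


def discard_initial(b: BoldSeries, seconds: float = 10.0) -> BoldSeries:
    """Drop the first ceil(seconds / TR) volumes so that at least ``seconds``
    of non-equilibrium data are removed."""
    n_drop = math.ceil(seconds * 1000.0 / b.tr_ms)
    if b.n_volumes - n_drop < 10:
        raise ValueError(
            f"discarding {n_drop} of {b.n_volumes} volumes leaves fewer than 10")
    return b.with_data(b.data[..., n_drop:],
                       DfEntry("discard_initial", 0, counted=False))


def build_design(n: NuisanceSet, t: int) -> tuple[np.ndarray, int]:
    """Nuisance design matrix and its counted df loss.

    Columns: Legendre polynomials of orders 0..detrend_order evaluated over
    the scan, then motion, tissue and component regressors.  The df loss
    counts motion + tissue + components + detrend_order: the constant term
    is excluded, matching the conventional arithmetic 12 + 2 + 3 = 17.
    """
    tau = np.linspace(-1.0, 1.0, t)
    cols = [legendre.legval(tau, [0.0] * k + [1.0]) for k in range(n.detrend_order + 1)]
    design = np.column_stack(cols)
    df_loss = n.detrend_order
    for block in (n.motion, n.tissue_signals, n.components):
        if block is not None and block.size:
            if block.shape[0] != t:
                raise ValueError(
                    f"nuisance table has {block.shape[0]} rows for {t} time points")
            design = np.hstack([design, block])
            df_loss += block.shape[1]
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("nuisance design is rank-deficient; using pseudo-inverse",
                      RuntimeWarning, stacklevel=2)
    return design, df_loss


def regress_nuisance(b: BoldSeries, design: np.ndarray,
                     df_loss: int | None = None) -> BoldSeries:
    """Voxelwise OLS residuals against the design, with each voxel's
    temporal mean restored afterwards."""
    if design.shape[0] != b.n_volumes:
        raise ValueError(
            f"design has {design.shape[0]} rows for {b.n_volumes} volumes")
    if df_loss is None:
        # intercept-like constant column does not count toward the loss
        const = np.all(np.isclose(design, design[0:1, :]), axis=0)
        df_loss = int(design.shape[1] - const.sum())
    vox = np.argwhere(b.mask)
    idx = tuple(vox.T)
    y = b.data[idx].T                                   # (t, n_vox)
    beta = np.linalg.pinv(design) @ y
    resid = y - design @ beta
    resid += b.data[idx].mean(axis=1)                   # restore voxel means
    out = b.data.copy()
    out[idx] = resid.T
    return b.with_data(out, DfEntry("regress_nuisance", df_loss))


def bandpass(b: BoldSeries, f_lo: float = 0.01, f_hi: float = 0.1) -> BoldSeries:
    """Ideal zero-phase bandpass: keep frequency bins strictly inside
    (f_lo, f_hi), restore the voxel mean.  Informational ledger entry only
    (spectral truncation is not regressor removal)."""
    fs = 1000.0 / b.tr_ms
    nyquist = fs / 2.0
    if not 0 <= f_lo < f_hi:
        raise ValueError(f"need 0 <= f_lo < f_hi, got {f_lo}, {f_hi}")
    if f_hi >= nyquist:
        raise ValueError(f"f_hi {f_hi} Hz >= Nyquist {nyquist:.4g} Hz at TR {b.tr_ms} ms")
    t = b.n_volumes
    freqs = np.fft.rfftfreq(t, d=b.tr_ms / 1000.0)
    keep = (freqs > f_lo) & (freqs < f_hi)
    n_removed = int((~keep).sum())

    vox = np.argwhere(b.mask)
    idx = tuple(vox.T)
    y = b.data[idx]
    mean = y.mean(axis=1, keepdims=True)
    spectrum = np.fft.rfft(y, axis=1)
    spectrum[:, ~keep] = 0.0
    filt = np.fft.irfft(spectrum, n=t, axis=1) + mean
    out = b.data.copy()
    out[idx] = filt
    return b.with_data(out, DfEntry("bandpass", n_removed, counted=False))


def smooth_gaussian(b: BoldSeries, fwhm_mm: float = 4.0) -> BoldSeries:
    """Per-volume 3D Gaussian smoothing restricted to the mask.

    sigma per axis = fwhm / (2*sqrt(2*ln 2)) / voxel_size; the kernel is
    renormalized over in-mask support so constants are preserved and
    out-of-mask voxels never leak in.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return b.with_data(b.data.copy())
    voxel_mm = np.sqrt((b.affine[:3, :3] ** 2).sum(axis=0))
    sigma_vox = (fwhm_mm / FWHM_TO_SIGMA) / voxel_mm
    maskf = b.mask.astype(float)
    norm = gaussian_filter(maskf, sigma_vox)
    norm = np.where(norm > 0, norm, 1.0)
    out = np.zeros_like(b.data)
    for t in range(b.n_volumes):
        sm = gaussian_filter(b.data[..., t] * maskf, sigma_vox) / norm
        out[..., t] = np.where(b.mask, sm, 0.0)
    return b.with_data(out)


def standard_denoise(
    b: BoldSeries,
    nuisance: NuisanceSet,
    *,
    discard_seconds: float = 10.0,
    fwhm_mm: float = 4.0,
    f_lo: float = 0.01,
    f_hi: float = 0.1,
    already_discarded: bool = False,
) -> BoldSeries:
    """The standard chain: discard -> smooth -> detrend+regress -> bandpass.

    ``nuisance`` tables must match the post-discard series length.  tSNR, if
    wanted, should be computed before this call (it is defined pre-smoothing).
    """
    if not already_discarded and discard_seconds > 0:
        b = discard_initial(b, discard_seconds)
    b = smooth_gaussian(b, fwhm_mm)
    design, df_loss = build_design(nuisance, b.n_volumes)
    b = regress_nuisance(b, design, df_loss)
    b = bandpass(b, f_lo, f_hi)
    return b
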