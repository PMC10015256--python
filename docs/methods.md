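# Methods

This note documents the models, conventions and numerical choices behind
`mefc`, what the synthetic phantom world does and does not emulate, and
the design decisions taken where the underlying analysis left choices
open.

## Emulated study design

The phantom generator emulates a two-acquisition, two-timepoint
resting-state design: every subject is scanned with a multiband
single-echo protocol (MB: TR 650 ms, TE 30 ms, 554 volumes) and a
multiband multi-echo protocol (MBME: TR 900 ms, TEs 11/30/49 ms,
400 volumes), both 6 minutes at 3 mm isotropic; 29 subjects, of whom the
first 18 return for a repeat session, give 47 sessions. Volume counts
derive from `round(duration / TR)`, which reproduces both printed counts
(554 and 400); `floor` would give 553.

`make_study` is lazy: sessions are descriptors with a `realize()` method.
This keeps the full-scale design instantiable in milliseconds and lets
tests realize only the scans they need. `scale` shortens the scans
(volume counts) without touching the grid; tests run at desk scale
(grids around 12×12×6 to 20×20×10, 100–150 volumes).

## Phantom signal model

Per voxel v, echo TE and volume t:

    S_v(t, TE) = S0_v · exp(−TE · R2*_v(t)) · (1 + d_v(t) + p_v(t)) + ε
    R2*_v(t)   = (1 + A · Σ_k L_vk n_k(t)) / T2*_v

Key parameters (defaults in parentheses):

* **T2\*** — GM uniform 30–60 ms with a short-T2\* "dropout" pocket of
  15–25 ms near the anterior pole (susceptibility emulation); WM
  40–55 ms, CSF 80–150 ms. S0 ≈ 1000 arbitrary units with 5% voxelwise
  jitter.
* **A**, fractional R2\* BOLD amplitude (0.02) — at TE = T2\* this is a
  ~2% peak signal change, a conventional resting-state magnitude. BOLD
  enters via R2\*, so its percent-signal amplitude grows with TE; drift
  and physio act multiplicatively on S0. This split is what makes
  T2\*-weighted combination demonstrably change BOLD sensitivity, the
  same TE-dependence logic that multi-echo denoising methods exploit.
* **n_k(t)** — unit-variance Gaussian latent network signals, temporally
  smoothed (σ = 1 TR) and colored by the eigendecomposition of the
  requested correlation matrix (validated symmetric PSD, unit diagonal).
  Empirical correlations converge to the target as scans lengthen
  (within ±0.1 at 400 volumes).
* **L** — each GM ROI loads 1.0 onto one of k networks (round-robin
  assignment); WM/CSF load nothing.
* **noise_sd** (7.0) — thermal noise giving per-echo GM tSNR ≈ 50–100 at
  the default S0, a conventional 3 T range; the underlying study does not
  characterize its noise levels, so this is a realism choice, not a
  derived value.
* **drift** — per-voxel random quadratic polynomial (fractional amplitude
  0.005); **physio** — sinusoids at 0.25 and 1.0 Hz (fractional amplitude
  0.005 each), aliased naturally by sampling at TR.
* **motion** — smooth low-amplitude random walks (6 columns: mm and
  degrees). Motion is recorded but never applied to the images:
  realignment is out of scope, and the tables exist to exercise nuisance
  regression and df accounting.

**Between-session stability.** `session_stability` s ∈ [0, 1] mixes the
repeat session's network modulation with a fresh draw:
g₂ = s·g₁ + √(1−s²)·g_fresh, where g_fresh uses fresh per-voxel loadings
(Gaussian, variance 1/k, GM only) and fresh latents. At s = 1 the repeat
session's latent signals are identical to timepoint 1 (only noise, drift
phases and physio phases are redrawn); at s = 0 the two sessions have
unrelated correlation structure. Mixing the *loadings*, not merely the
latent time courses, is deliberate: within-session correlation structure
— which is all that Dice/REP can see — only changes if the spatial
pattern changes.

What the phantom does **not** emulate: k-space/reconstruction physics,
multiband unaliasing and g-factor noise amplification, applied head
motion, realistic cardiac/respiratory waveforms, spatial autocorrelation
of thermal noise, and inter-subject anatomical variability beyond
resampled truth maps. A green test therefore establishes algorithmic
correctness and direction-level behavior, not in-vivo effect sizes.

## Echo combination

T2\*/S0 by unweighted OLS of log signal on TE ("log-linear" literally: no
variance weighting). Default fits the temporal mean signal; a per-volume
mode (estimates averaged over volumes) is available since the emulated
analysis does not state which was used. T2\* is clamped to [2, 300] ms
(config-exposed); non-decaying or invalid voxels (< 2 positive samples)
are flagged and assigned the upper clamp.

Combination weights w_i = TE_i·exp(−TE_i/T2\*), normalized to sum to one
— the standard T2\*-weighted scheme, adopted because the source analysis
cites it without printing the formula. `normalized_t2star` is kept as a
documented alias: under this normalization, dividing the weighted sum by
the sum of unnormalized weights yields the identical series. `summation`
is the plain sum.

tSNR is voxelwise mean over sample SD (ddof = 1), computed before
smoothing, with NaN at zero-SD voxels. The time-point adjustment is
√N_TP: the printed text says "multiplied by N_TP", but the HCP reference
it cites uses the square-root scaling, and a bare N_TP would double-count
scan length; treated as a typographically lost radical (flag
`scale_by_sqrt_ntp`).

## Standard denoising

Stage order: discard → (combine) → smooth → detrend+regress → bandpass.

* **Discard**: ceil(10 s / TR) volumes, guaranteeing at least 10 s of
  non-equilibrium data are removed (12 volumes at TR 900 ms, 16 at
  650 ms).
* **Detrending** is folded into the regression design as Legendre
  polynomials of orders 0..3, so df accounting is unified. The df loss
  counts motion + tissue + components + detrend order, excluding the
  constant: 12 + 2 + 3 = 17 for the 12-motion configuration. The source
  text is internally inconsistent (6 motion parameters in one section,
  12 in the df arithmetic); both are supported, 12 (6 + temporal
  derivatives) is the pipeline default because it reproduces the printed
  arithmetic.
* **Tissue regressors**: WM/CSF means from eroded masks, extracted before
  smoothing (unstated in the source; erosion avoids GM partial-volume
  contamination).
* **Component injection**: externally computed component time courses
  (e.g. from multi-echo ICA or motion-component classifiers, whose
  internals are out of scope) enter as additional regressors and are
  counted in the ledger.
* **Bandpass**: ideal zero-phase spectral mask keeping bins strictly
  inside (0.01, 0.1) Hz, mean restored. An ideal mask (not Butterworth)
  makes the attenuation contracts exact and the filter an idempotent
  projection. The ledger entry is informational (bin count), not counted
  df loss.
* **Smoothing**: per-volume Gaussian, σ = FWHM/(2√(2 ln 2))/voxel size,
  kernel renormalized over in-mask support so constants are preserved
  and out-of-mask values never leak in.

Idempotence: regression and bandpass are each projections and therefore
individually idempotent to floating-point precision. The *composition* is
not: bandpassing residuals destroys their orthogonality to broadband
regressors, so a second full pass is not a strict no-op. The tests check
the stage-wise property, which is the one that actually holds.

## Connectivity, FCD, reproducibility

Seed maps correlate the seed-mean series with every in-mask voxel;
zero-variance voxels get r = 0 (kept defined for counting) plus a flag.
Effective df = N_TP − 2 − counted ledger loss. ROI matrices order the
subcortical block first, then cortical, ascending labels. Raw r is used
throughout (no Fisher z by default). Thresholding is inclusive (≥), with
the matrix diagonal excluded.

FCD conventions (the cited implementations differ; all config-exposed):
26-connectivity for spatial contiguity, local count includes the index
voxel (minimum 1 in-mask), global count excludes it, threshold r ≥ 0.6
inclusive. Correlations are computed against the index voxel on the fly
(no N×N matrix); correctness is established by exact equality with
brute-force oracles on randomized volumes, including degenerate masks and
planted correlated triples.

Dice: both-empty input returns NaN (missing), deliberately distinct from
0 — "no overlap" and "nothing to overlap" are different findings. Matrix
Dice uses strictly-lower-triangle entries only. REP: 0/0 := 1 (two equal
values). Note a consequence: on nearly-empty FCD maps the GM-mean REP is
dominated by 0/0 voxels and can *rise* as maps empty out. The
reproducibility-vs-stability monotonicity suite therefore uses phantoms
with BOLD amplitude 0.04 and noise SD 5 so suprathreshold counts are well
populated at every stability level, and uses local FCD (counts ≥ 1 by
convention); this is a property of the REP definition, not of the
implementation.

## Group statistics

Paired comparisons regress per-session differences on an intercept plus
the mean-centered scan-number covariate; the intercept t (n − 2 df) tests
the covariate-adjusted mean difference. Without a covariate this is
exactly the classical paired t-test (n − 1 df) — the two are equal only
then, since the df differ. Zero-variance nonzero differences flag t = ±∞,
p = 0.

FDR is Benjamini–Hochberg step-up (via statsmodels), applied to
strictly-lower-triangle matrix elements; default q = 0.05 (the source
prints both q < 0.01 and q < 0.05 in different places; both supported).

Cluster-extent correction is a transparent Monte Carlo: white Gaussian
volumes smoothed to a target FWHM, z-standardized in-mask, thresholded
two-sided at the voxel p, largest 26-connected cluster recorded per
iteration; the minimum cluster size is the ceiling of the (1 − α)
quantile (at least 1). This deliberately replaces
autocorrelation-function-model tools and is *not* numerically equivalent
to them; published cluster thresholds are not reproduction targets.

## Known limitations

* Gaussian-only noise; no spatial noise correlations, so Monte-Carlo
  cluster thresholds are optimistic relative to real EPI smoothness
  unless the smoothness parameter is estimated externally.
* The phantom's GM partition (farthest-point seeding + BFS) guarantees
  disjoint labels but contiguity only within connected GM components.
* Per-volume T2\* fitting is offered but slow on large grids; the
  temporal-mean fit is the default and the one validated against ground
  truth.
* The repeat-session latent mixing introduces pointwise correlation
  between sessions' time courses; harmless for every analysis here (none
  compares sessions sample-by-sample) but not physical.
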