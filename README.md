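# mefc — multiband multi-echo resting-state fMRI connectivity

`mefc` is a tested, reusable implementation of a multiband multi-echo
(MBME) resting-state fMRI analysis pipeline: voxelwise T2\*-weighted echo
combination, standard nuisance denoising with exact degrees-of-freedom
accounting, seed- and ROI-based functional connectivity, functional
connectivity density (FCD) mapping, test–retest reproducibility metrics,
and paired group statistics. Because raw MBME data of this kind are rarely
deposited, the package ships a first-class synthetic multi-echo BOLD
phantom generator with known ground truth (T2\*/S0 maps, planted network
structure, nuisance signals, controllable between-session stability), so
every stage is verifiable end to end without external data.

It is aimed at fMRI methods researchers who want a transparent, scriptable
alternative to stitched-together shell pipelines for multi-echo
connectivity analyses, and at anyone who needs a controlled phantom world
to validate such analyses.

## The models in brief

**Signal model (phantom).** Per voxel $v$, echo time $TE$ and volume $t$:

$$S_v(t, TE) = S_{0,v}\,e^{-TE \cdot R^*_{2,v}(t)}\,(1 + d_v(t) + p_v(t)) + \varepsilon,
\qquad R^*_{2,v}(t) = \frac{1 + A \sum_k L_{vk}\, n_k(t)}{T^*_{2,v}}$$

with latent network time courses $n_k$ at a requested cross-correlation,
loadings $L$, fractional BOLD amplitude $A$, polynomial drift $d$,
sinusoidal physiological nuisance $p$, and white thermal noise
$\varepsilon$. BOLD enters through $R_2^*$ (TE-dependent), nuisance terms
multiplicatively on $S_0$ — so echo combination genuinely changes BOLD
sensitivity.

**Echo combination.** T2\* and S0 come from an ordinary least-squares fit
of $\log S$ on $TE$ (log-linear fit); echoes are averaged with weights
$w_i \propto TE_i\, e^{-TE_i/T_2^*}$ normalized to sum to one.

**Connectivity.** Pearson correlation of a seed's mean time series with
every voxel, and an ROI×ROI matrix over parcellation regions (with the
emulated 16 subcortical + 148 cortical scheme: 164×164).

**FCD.** At threshold $r \ge 0.6$: local FCD is the size of the spatially
contiguous cluster of voxels all correlated with the index voxel above
threshold; global FCD counts suprathreshold correlations anywhere in the
mask. Both are checked exactly against brute-force oracles.

**Reproducibility.** Dice coefficient
$DC = 2\,|A \cap B| / (|A| + |B|)$ for thresholded maps/matrices and the
voxelwise statistic $REP = 1 - |x_1 - x_2| / (x_1 + x_2)$ for FCD maps.

**Group layer.** Element-wise paired t-tests with an optional scan-number
covariate, Benjamini–Hochberg FDR for matrices, and a Monte-Carlo
cluster-extent threshold for maps.

## Worked example

Two sessions of one phantom subject (MBME-like acquisition, TR 900 ms,
TEs 11/30/49 ms, scaled to 100 volumes), processed end to end:

```python
import numpy as np
from mefc import (make_study, fit_t2star, combine_echoes, tsnr,
                  discard_initial, standard_denoise, NuisanceSet,
                  motion_with_derivatives, extract_tissue_signals,
                  roi_matrix, threshold_binarize, lfcd, rep_fcd,
                  dice_matrices)

study = make_study(n_subjects=1, n_repeat=1, scale=0.25, seed=42,
                   shape=(12, 12, 6), n_rois=8, n_subcortical=2, n_seed=0,
                   n_networks=4, session_stability=0.8, bold_amplitude=0.04,
                   noise_sd=5.0)
gm = study.tissue_masks["gm"]
mats, fmaps = {}, {}
for sess in study.sessions:
    me, motion = sess.realize("MBME")
    fit = fit_t2star(me)
    bold = discard_initial(combine_echoes(me, fit))
    print(f"tp{sess.timepoint}: GM median T2* {np.median(fit.t2s_map[gm]):.1f} ms; "
          f"GM mean tSNR*sqrt(N) "
          f"{np.nanmean(tsnr(bold, scale_by_sqrt_ntp=True)[gm]):.0f}")
    mot = motion_with_derivatives(motion.to_numpy()[me.n_volumes - bold.n_volumes:])
    nuis = NuisanceSet(motion=mot,
                       tissue_signals=extract_tissue_signals(
                           bold, sess.anatomy.tissue_masks),
                       detrend_order=3)
    bold = standard_denoise(bold, nuis, already_discarded=True)
    print(f"     df loss {bold.total_df_loss}")
    mats[sess.timepoint] = roi_matrix(bold, sess.anatomy.parcellation)
    fmaps[sess.timepoint] = lfcd(bold, r_thr=0.6)

dc = dice_matrices(threshold_binarize(mats[1], 0.3),
                   threshold_binarize(mats[2], 0.3))
rep = rep_fcd(fmaps[1], fmaps[2], gm)
print(f"test-retest Dice (r>=0.3): {dc:.3f}")
print(f"GM-mean local-FCD REP: {rep.region_mean_rep:.3f}")
```

Output:

```
tp1: GM median T2* 44.0 ms; GM mean tSNR*sqrt(N) 338
     df loss 17
tp2: GM median T2* 44.0 ms; GM mean tSNR*sqrt(N) 345
     df loss 17
test-retest Dice (r>=0.3): 0.444
GM-mean local-FCD REP: 0.432
```

The T2\* fit recovers the phantom's grey-matter T2\* distribution (truth
drawn from 30–60 ms plus a short-T2\* dropout pocket); the df loss of 17 is
the 12-motion + WM + CSF + third-order-detrend bookkeeping; at session
stability 0.8 the two sessions share most but not all of their network
structure, so Dice and REP sit well between their chance and perfect
values (both reach 1.0 as `session_stability` approaches 1 in the
noiseless limit).

A CLI mirrors the stages: `mefc simulate|combine|preprocess|connectivity|
fcd|repro|group|run` (see `mefc --help`); `mefc run --config cfg.yaml
--out results/` executes the whole pipeline and writes a provenance
manifest (config hash, df ledgers, seeds).

## Acceptance script

`scripts/acceptance.py` regenerates a phantom session, runs the seed-based
connectivity analysis, binarizes the resulting correlation map, and
recomputes the overlap statistic for the perfect-overlap case from
scratch, writing the result as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
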