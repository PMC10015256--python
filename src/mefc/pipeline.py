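"""Pipeline configuration and the end-to-end phantom run.

A :class:`PipelineConfig` captures every tunable of the two emulated
pipelines (acquisition timing, denoising choices, analysis thresholds,
RNG seeds); :func:`run_pipeline` drives a synthetic study through
simulate -> combine -> denoise -> connectivity / FCD -> reproducibility ->
group comparison, writing every product plus a manifest (inputs, config
hash, df ledger, seeds) for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .combine import combine_echoes, fit_t2star, tsnr
from .connectivity import roi_matrix, seed_map, threshold_binarize
from .fcd import gfcd, lfcd
from .group import fdr_bh, paired_test
from .preprocess import (NuisanceSet, discard_initial,
                         extract_tissue_signals, motion_with_derivatives,
                         standard_denoise)
from .repro import dice_maps, dice_matrices, rep_fcd
from .synthetic import SyntheticStudy, make_study
from .types import MB_ACQUISITION, MBME_ACQUISITION

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Structured run configuration; serializable to/from YAML."""

    # study / acquisition block
    n_subjects: int = 4
    n_repeat: int = 2
    scale: float = 0.25
    shape: tuple[int, int, int] = (20, 20, 10)
    n_rois: int = 24
    n_subcortical: int = 4
    n_seed: int = 2
    session_stability: float = 0.8
    bold_amplitude: float = 0.02
    noise_sd: float = 7.0
    discard_seconds: float = 10.0
    # denoising block
    pipeline: str = "standard"          # standard | component_injected
    motion_columns: int = 12            # 6 or 12 (+ temporal derivatives)
    detrend_order: int = 3
    f_lo_hz: float = 0.01
    f_hi_hz: float = 0.1
    fwhm_mm: float = 4.0
    components_dir: str | None = None   # TSVs of injected component courses
    # analysis block
    seed_r_thresholds: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6)
    fcd_r_thr: float = 0.6
    fcd_neighbor_scheme: int = 26
    fdr_q: float = 0.05
    # seeds
    seed: int = 0

    def validate(self) -> None:
        for acq in (MB_ACQUISITION, MBME_ACQUISITION):
            nyquist = 1000.0 / (2.0 * acq.tr_ms)
            if self.f_hi_hz >= nyquist:
                raise ValueError(
                    f"f_hi {self.f_hi_hz} Hz >= Nyquist {nyquist:.4g} Hz "
                    f"at TR {acq.tr_ms} ms")
        if not 0 < self.f_lo_hz < self.f_hi_hz:
            raise ValueError("need 0 < f_lo < f_hi")
        if self.pipeline not in ("standard", "component_injected"):
            raise ValueError(f"unknown pipeline {self.pipeline!r}")
        if self.motion_columns not in (6, 12):
            raise ValueError("motion_columns must be 6 or 12")
        for thr in (*self.seed_r_thresholds, self.fcd_r_thr):
            if not -1.0 < thr <= 1.0:
                raise ValueError(f"correlation threshold {thr} out of range")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.components_dir is not None and not Path(self.components_dir).is_dir():
            raise ValueError(f"components_dir {self.components_dir} does not exist")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("shape", "seed_r_thresholds"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["seed_r_thresholds"] = list(self.seed_r_thresholds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _denoise_session(me, motion, masks, cfg: PipelineConfig,
                     components: np.ndarray | None = None):
    """combine -> discard -> (tSNR) -> standard chain. Returns (bold, tsnr_map)."""
    if me.n_echoes > 1:
        fit = fit_t2star(me)
        bold = combine_echoes(me, fit, scheme="t2star_weighted")
    else:
        bold = combine_echoes(me, scheme="summation")
    bold = discard_initial(bold, cfg.discard_seconds)
    n_drop = me.n_volumes - bold.n_volumes
    tsnr_map = tsnr(bold, scale_by_sqrt_ntp=True)

    mot = np.asarray(motion)[n_drop:]
    if cfg.motion_columns == 12:
        mot = motion_with_derivatives(mot)
    comp = components[n_drop:] if components is not None else None
    nuis = NuisanceSet(motion=mot,
                       tissue_signals=extract_tissue_signals(bold, masks),
                       components=comp, detrend_order=cfg.detrend_order)
    bold = standard_denoise(bold, nuis, fwhm_mm=cfg.fwhm_mm,
                            f_lo=cfg.f_lo_hz, f_hi=cfg.f_hi_hz,
                            already_discarded=True)
    return bold, tsnr_map


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 study: SyntheticStudy | None = None) -> dict:
    """Execute the full phantom pipeline and write a result bundle.

    Generates (or accepts) a synthetic study, processes every session and
    acquisition, computes seed maps, the ROI matrix, local and global FCD,
    per-subject test-retest metrics, and the MBME-vs-MB paired group
    comparison of ROI matrices with a scan-number covariate and BH-FDR.
    Returns the manifest (also written to ``manifest.json``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    if study is None:
        study = make_study(
            config.n_subjects, config.n_repeat, scale=config.scale,
            seed=config.seed, shape=config.shape, n_rois=config.n_rois,
            n_subcortical=config.n_subcortical, n_seed=config.n_seed,
            n_networks=min(6, config.n_rois),
            session_stability=config.session_stability,
            bold_amplitude=config.bold_amplitude, noise_sd=config.noise_sd)
    stages.append("simulate")
    mio.save_parcellation(out, study.parcellation)

    seed_labels = study.parcellation.labels_of_class(("seed",))
    gm = study.tissue_masks["gm"]

    matrices: dict[tuple[str, int, str], np.ndarray] = {}
    fcd_maps: dict[tuple[str, int, str, str], object] = {}
    seed_bin: dict[tuple[str, int, str, int, float], np.ndarray] = {}
    df_ledgers = {}
    tsnr_rows = []
    for sess in study.sessions:
        anat = study.anatomies[sess.subject_id]
        for label in sorted(sess.acquisitions):
            me, motion = sess.realize(label)
            components = _load_components(config, sess, label, me.n_volumes)
            bold, tsnr_map = _denoise_session(
                me, motion, anat.tissue_masks, config, components)
            tag = f"{sess.subject_id}_tp{sess.timepoint}_{label}"
            df_ledgers[tag] = [[e.stage, e.n_removed, e.counted]
                               for e in bold.df_ledger]
            tsnr_rows.append({
                "subject": sess.subject_id, "timepoint": sess.timepoint,
                "acquisition": label,
                "gm_mean_tsnr_sqrtntp": float(np.nanmean(
                    tsnr_map[gm & bold.mask])),
            })
            mat = roi_matrix(bold, anat.parcellation)
            matrices[(sess.subject_id, sess.timepoint, label)] = mat.r
            names = [f"roi{lab}" for lab in mat.roi_labels]
            mio.write_matrix_tsv(out / f"{tag}_roimatrix.tsv", mat.r, names)
            for sl in seed_labels:
                cmap = seed_map(bold, anat.parcellation, sl)
                mio.save_volume(out / f"{tag}_seed{sl}_r.nii.gz",
                                cmap.r_map, bold.affine)
                for thr in config.seed_r_thresholds:
                    seed_bin[(sess.subject_id, sess.timepoint, label, sl, thr)] = \
                        threshold_binarize(cmap, thr)
            for variant, fn in (("local", lfcd), ("global", gfcd)):
                kwargs = ({"neighbor_scheme": config.fcd_neighbor_scheme}
                          if variant == "local" else {})
                fmap = fn(bold, r_thr=config.fcd_r_thr, **kwargs)
                fcd_maps[(sess.subject_id, sess.timepoint, label, variant)] = fmap
                mio.save_volume(out / f"{tag}_{variant[0]}fcd.nii.gz",
                                fmap.counts, bold.affine)
    stages += ["combine", "denoise", "connectivity", "fcd"]
    pd.DataFrame(tsnr_rows).to_csv(out / "tsnr.tsv", sep="\t", index=False)

    # --- test-retest reproducibility over repeat subjects -----------------
    repro_rows = []
    repeat_subjects = sorted({s.subject_id for s in study.sessions
                              if s.timepoint == 2})
    for sid in repeat_subjects:
        for label in ("MB", "MBME"):
            for sl in seed_labels:
                thr = config.seed_r_thresholds[0]
                dc = dice_maps(seed_bin[(sid, 1, label, sl, thr)],
                               seed_bin[(sid, 2, label, sl, thr)])
                repro_rows.append({"subject": sid, "acquisition": label,
                                   "measure": f"seed{sl}", "r_thr": thr,
                                   "value": dc})
            for thr in config.seed_r_thresholds:
                dc = dice_matrices(
                    threshold_binarize(matrices[(sid, 1, label)], thr),
                    threshold_binarize(matrices[(sid, 2, label)], thr))
                repro_rows.append({"subject": sid, "acquisition": label,
                                   "measure": "roimatrix", "r_thr": thr,
                                   "value": dc})
            for variant in ("local", "global"):
                rr = rep_fcd(fcd_maps[(sid, 1, label, variant)],
                             fcd_maps[(sid, 2, label, variant)], gm)
                repro_rows.append({"subject": sid, "acquisition": label,
                                   "measure": f"rep_{variant}_fcd",
                                   "r_thr": config.fcd_r_thr,
                                   "value": rr.region_mean_rep})
    if repro_rows:
        pd.DataFrame(repro_rows).to_csv(out / "reproducibility.tsv",
                                        sep="\t", index=False)
        stages.append("reproducibility")

    # --- group comparison: MBME vs MB ROI matrices ------------------------
    sessions = [(s.subject_id, s.timepoint) for s in study.sessions]
    mb = np.stack([matrices[(sid, tp, "MB")] for sid, tp in sessions])
    mbme = np.stack([matrices[(sid, tp, "MBME")] for sid, tp in sessions])
    scan_number = np.array([tp for _, tp in sessions], dtype=float)
    res = paired_test(mb, mbme, covariate=scan_number)
    rows, cols = np.tril_indices(res.p_map.shape[0], k=-1)
    reject = fdr_bh(res.p_map[rows, cols], q=config.fdr_q)
    frac_higher = float(np.mean(reject & (res.t_map[rows, cols] > 0)))
    frac_lower = float(np.mean(reject & (res.t_map[rows, cols] < 0)))
    group = {
        "n_sessions": len(sessions),
        "fdr_q": config.fdr_q,
        "fraction_mbme_higher": frac_higher,
        "fraction_mbme_lower": frac_lower,
    }
    (out / "group_roimatrix.json").write_text(json.dumps(group, indent=1))
    stages.append("group")

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
        "n_sessions": study.n_sessions,
        "df_ledgers": df_ledgers,
        "group": group,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest


def _load_components(config: PipelineConfig, sess, label: str,
                     n_volumes: int) -> np.ndarray | None:
    if config.pipeline != "component_injected" or config.components_dir is None:
        return None
    path = (Path(config.components_dir)
            / f"{sess.subject_id}_tp{sess.timepoint}_{label}_components.tsv")
    if not path.exists():
        return None
    comp = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    if comp.shape[0] != n_volumes:
        raise ValueError(
            f"component table {path} has {comp.shape[0]} rows for "
            f"{n_volumes} volumes")
    return comp
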