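"""Synthetic multi-echo BOLD phantoms with known ground truth.

The generator emulates a two-acquisition resting-state study design: a
multiband single-echo scan (TR 650 ms, TE 30 ms, 554 volumes) and a
multiband multi-echo scan (TR 900 ms, TEs 11/30/49 ms, 400 volumes),
3 mm isotropic, 29 subjects of whom 18 return for a repeat session
(47 sessions in total).

Signal model, per voxel v, echo time TE and volume t::

    S_v(t, TE) = S0_v * exp(-TE * R2*_v(t)) * (1 + d_v(t) + p_v(t)) + eps
    R2*_v(t)   = (1 + A * g_v(t)) / T2*_v
    g_v(t)     = sum_k  L_vk * n_k(t)

where ``n_k`` are latent network time courses with a requested
cross-correlation matrix, ``L`` are per-voxel network loadings, ``A`` is the
fractional R2* BOLD amplitude, ``d`` a slow polynomial drift, ``p`` a sum of
sinusoidal physiological nuisances (aliased naturally by the TR), and
``eps`` white Gaussian thermal noise.  BOLD enters through R2* so its
percent-signal amplitude grows with TE, whereas drift/physio act
multiplicatively on S0 — echo combination therefore genuinely changes BOLD
sensitivity, as it does for real multi-echo data.

Between-session stability is a single knob ``session_stability`` in [0, 1]:
timepoint-2 network modulations are ``s * g1 + sqrt(1 - s^2) * g_fresh``
with ``g_fresh`` built from fresh per-voxel loadings and fresh latents, so
``s = 1`` reproduces timepoint 1 exactly (up to fresh noise) and ``s = 0``
plants an unrelated correlation structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fcd import neighbor_offsets
from .types import (
    MB_ACQUISITION,
    MBME_ACQUISITION,
    AcquisitionSpec,
    BoldSeries,
    MultiEchoSeries,
    Parcellation,
    default_affine,
)

__all__ = [
    "GroundTruth",
    "PhantomAnatomy",
    "SyntheticStudy",
    "StudySession",
    "make_phantom_anatomy",
    "simulate_session",
    "make_study",
    "make_fcd_testcase",
    "latent_time_courses",
    "default_network_corr",
]

# Sub-stream tags so each stochastic ingredient has its own reproducible
# generator for a given user seed.
_ANAT, _LATENT, _NOISE, _DRIFT, _PHYSIO, _MOTION, _FRESH = range(1, 8)


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(list(key))


@dataclass
class GroundTruth:
    """Per-voxel truth maps and nuisance parameters of one phantom brain."""

    t2s_map: np.ndarray              # ms, > 0 inside the brain mask
    s0_map: np.ndarray               # equilibrium signal, arbitrary units
    network_loadings: np.ndarray     # (x, y, z, k) weights onto latent networks
    session_stability: float = 0.8   # in [0, 1]
    noise_sd: float = 7.0            # thermal noise SD, same units as s0_map
    drift_coeffs: np.ndarray | None = None  # (x, y, z, order) polynomial coeffs
    physio_freqs_hz: tuple[float, ...] = (0.25, 1.0)
    physio_amp: float = 0.005        # fractional amplitude per sinusoid

    def __post_init__(self) -> None:
        if not 0.0 <= self.session_stability <= 1.0:
            raise ValueError("session_stability must be in [0, 1]")
        if not np.all(np.isfinite(self.network_loadings)):
            raise ValueError("network_loadings must be finite")

    @property
    def n_networks(self) -> int:
        return self.network_loadings.shape[-1]


@dataclass
class PhantomAnatomy:
    """Parcellation, tissue masks, and ground truth of one phantom brain."""

    parcellation: Parcellation
    tissue_masks: dict[str, np.ndarray]   # keys: brain, gm, wm, csf
    ground_truth: GroundTruth

    def __iter__(self):
        # allow tuple-style unpacking: parcellation, tissue_masks, truth
        yield self.parcellation
        yield self.tissue_masks
        yield self.ground_truth

    @property
    def brain_mask(self) -> np.ndarray:
        return self.tissue_masks["brain"]


def default_network_corr(k: int, rho: float = 0.3) -> np.ndarray:
    """Exchangeable latent-network correlation: 1 on-diagonal, rho off."""
    c = np.full((k, k), rho, dtype=float)
    np.fill_diagonal(c, 1.0)
    return c


def _partition_gm(gm: np.ndarray, n_rois: int, rng: np.random.Generator) -> np.ndarray:
    """Partition GM voxels into n_rois contiguous labels 1..n_rois.

    Greedy farthest-point seeding followed by multi-source BFS over
    6-connectivity within GM; disconnected leftovers go to the nearest seed.
    """
    coords = np.argwhere(gm)
    n_gm = len(coords)
    if n_rois > n_gm:
        raise ValueError(f"cannot host {n_rois} ROIs in {n_gm} GM voxels")
    # farthest-point sampling for spatially spread ROI seeds
    start = int(rng.integers(n_gm))
    seed_idx = [start]
    d2 = np.sum((coords - coords[start]) ** 2, axis=1).astype(float)
    for _ in range(1, n_rois):
        nxt = int(np.argmax(d2))
        seed_idx.append(nxt)
        d2 = np.minimum(d2, np.sum((coords - coords[nxt]) ** 2, axis=1))

    labels = np.zeros(gm.shape, dtype=np.int32)
    from collections import deque

    queue: deque[tuple[int, int, int]] = deque()
    for lab, si in enumerate(seed_idx, start=1):
        pos = tuple(coords[si])
        labels[pos] = lab
        queue.append(pos)
    offs = neighbor_offsets(6)
    shape = gm.shape
    while queue:
        x, y, z = queue.popleft()
        lab = labels[x, y, z]
        for dx, dy, dz in offs:
            u = (x + dx, y + dy, z + dz)
            if (0 <= u[0] < shape[0] and 0 <= u[1] < shape[1]
                    and 0 <= u[2] < shape[2] and gm[u] and labels[u] == 0):
                labels[u] = lab
                queue.append(u)
    # disconnected GM components: nearest seed by Euclidean distance
    left = np.argwhere(gm & (labels == 0))
    if len(left):
        seeds = coords[seed_idx]
        for pos in left:
            lab = int(np.argmin(np.sum((seeds - pos) ** 2, axis=1))) + 1
            labels[tuple(pos)] = lab
    return labels


def make_phantom_anatomy(
    shape: tuple[int, int, int] = (20, 20, 10),
    n_rois: int = 8,
    seed: int = 0,
    *,
    n_subcortical: int = 0,
    n_seed: int = 0,
    n_networks: int | None = None,
    gm_t2s_range: tuple[float, float] = (30.0, 60.0),
    dropout_t2s_range: tuple[float, float] = (15.0, 25.0),
    session_stability: float = 0.8,
    noise_sd: float = 7.0,
    drift_amp: float = 0.005,
    physio_freqs_hz: tuple[float, ...] = (0.25, 1.0),
    physio_amp: float = 0.005,
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> PhantomAnatomy:
    """Build a brain-like phantom: ellipsoidal brain with CSF core, WM shell
    and a GM rind partitioned into ``n_rois`` contiguous ROIs.

    The first ``n_subcortical`` labels are classed subcortical, the last
    ``n_seed`` labels are classed seed (emulating a separate seed atlas), the
    rest cortical.  GM T2* is drawn uniformly from ``gm_t2s_range`` except in
    a small "dropout" pocket near the anterior pole drawn from
    ``dropout_t2s_range`` (emulating susceptibility-related short T2*).
    Deterministic for a fixed seed.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < m for s, m in zip(shape, (8, 8, 4))):
        raise ValueError(f"shape {shape} too small; need at least (8, 8, 4)")
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    if n_subcortical + n_seed > n_rois:
        raise ValueError("n_subcortical + n_seed exceeds n_rois")
    rng = _rng(_ANAT, seed)

    semi = np.maximum((np.asarray(shape) - 1) / 2.0, 1.0)
    center = (np.asarray(shape) - 1) / 2.0
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    rho = np.sqrt(np.sum(((grid - center) / semi) ** 2, axis=-1))
    brain = rho <= 1.0
    csf = rho < 0.25
    wm = (rho >= 0.25) & (rho < 0.6)
    gm = (rho >= 0.6) & brain

    labels = _partition_gm(gm, n_rois, rng)

    # T2* truth: GM uniform in range, with a short-T2* dropout pocket
    t2s = np.zeros(shape)
    t2s[gm] = rng.uniform(*gm_t2s_range, size=int(gm.sum()))
    t2s[wm] = rng.uniform(40.0, 55.0, size=int(wm.sum()))
    t2s[csf] = rng.uniform(80.0, 150.0, size=int(csf.sum()))
    gm_coords = np.argwhere(gm)
    pole = gm_coords[np.argmax(gm_coords[:, 1])]
    near = np.sum((gm_coords - pole) ** 2, axis=1) <= 2.25
    drop_idx = tuple(gm_coords[near].T)
    t2s[drop_idx] = rng.uniform(*dropout_t2s_range, size=int(near.sum()))

    s0 = np.zeros(shape)
    for msk, base in ((gm, 1000.0), (wm, 950.0), (csf, 1050.0)):
        s0[msk] = base * (1.0 + 0.05 * rng.standard_normal(int(msk.sum())))

    if n_networks is None:
        n_networks = min(n_rois, 4)
    loadings = np.zeros(shape + (n_networks,))
    for lab in range(1, n_rois + 1):
        loadings[labels == lab, (lab - 1) % n_networks] = 1.0

    drift_coeffs = drift_amp * rng.standard_normal(shape + (2,))
    drift_coeffs[~brain] = 0.0

    classes = (["subcortical"] * n_subcortical
               + ["cortical"] * (n_rois - n_subcortical - n_seed)
               + ["seed"] * n_seed)
    table = pd.DataFrame({
        "label": np.arange(1, n_rois + 1),
        "name": [f"{c}_{i + 1:03d}" for i, c in enumerate(classes)],
        "class": classes,
    })
    parc = Parcellation(labels=labels, table=table, affine=default_affine(voxel_mm))
    truth = GroundTruth(
        t2s_map=t2s, s0_map=s0, network_loadings=loadings,
        session_stability=session_stability, noise_sd=noise_sd,
        drift_coeffs=drift_coeffs, physio_freqs_hz=tuple(physio_freqs_hz),
        physio_amp=physio_amp,
    )
    masks = {"brain": brain, "gm": gm, "wm": wm, "csf": csf}
    return PhantomAnatomy(parcellation=parc, tissue_masks=masks, ground_truth=truth)


def latent_time_courses(
    n_networks: int,
    n_volumes: int,
    network_corr: np.ndarray,
    rng: np.random.Generator,
    smooth_sigma_tr: float = 1.0,
) -> np.ndarray:
    """Latent network signals (k, t): temporally smoothed unit-variance
    Gaussian processes colored to the requested correlation matrix.

    Raises ValueError if ``network_corr`` is not symmetric PSD with unit
    diagonal.
    """
    from scipy.ndimage import gaussian_filter1d

    c = np.asarray(network_corr, dtype=float)
    if c.shape != (n_networks, n_networks):
        raise ValueError(f"network_corr must be {n_networks}x{n_networks}")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("network_corr must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise ValueError("network_corr must have unit diagonal")
    w, v = np.linalg.eigh(c)
    if w.min() < -1e-10:
        raise ValueError(f"network_corr not positive semi-definite (min eig {w.min():.3g})")
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    white = rng.standard_normal((n_networks, n_volumes))
    if smooth_sigma_tr > 0:
        white = gaussian_filter1d(white, smooth_sigma_tr, axis=1, mode="wrap")
    white -= white.mean(axis=1, keepdims=True)
    sd = white.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    white /= sd
    return factor @ white


def _motion_table(n_volumes: int, rng: np.random.Generator) -> pd.DataFrame:
    """Smooth low-amplitude random-walk rigid-body motion parameters."""
    from scipy.ndimage import gaussian_filter1d

    steps = rng.standard_normal((n_volumes, 6))
    walk = np.cumsum(steps, axis=0)
    walk = gaussian_filter1d(walk, 3.0, axis=0)
    walk -= walk[0]
    walk[:, :3] *= 0.02   # mm
    walk[:, 3:] *= 0.01   # deg
    return pd.DataFrame(
        walk,
        columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
    )


def simulate_session(
    anatomy: PhantomAnatomy,
    acq: AcquisitionSpec,
    network_corr: np.ndarray | None = None,
    bold_amplitude: float = 0.02,
    seed: int = 0,
    *,
    noise_sd: float | None = None,
    include_drift: bool = True,
    include_physio: bool = True,
    latent_signals: np.ndarray | None = None,
    modulation: np.ndarray | None = None,
) -> tuple[MultiEchoSeries, pd.DataFrame]:
    """Simulate one scan of a phantom: one 4D array per echo plus a motion
    table (motion is recorded but never applied to the images).

    ``latent_signals`` (k, t) or ``modulation`` (n_brain_voxels, t) override
    the internally drawn network dynamics; the latter is how the study
    generator implements between-session stability.
    """
    truth = anatomy.ground_truth
    brain = anatomy.brain_mask
    vox = np.argwhere(brain)
    idx = tuple(vox.T)
    n_vox = len(vox)
    t = acq.n_volumes
    k = truth.n_networks

    if modulation is None:
        if latent_signals is None:
            if network_corr is None:
                network_corr = default_network_corr(k)
            latent_signals = latent_time_courses(
                k, t, network_corr, _rng(_LATENT, seed))
        if latent_signals.shape != (k, t):
            raise ValueError(f"latent_signals must be ({k}, {t})")
        loadings = truth.network_loadings[idx]            # (n_vox, k)
        modulation = loadings @ latent_signals            # (n_vox, t)
    elif modulation.shape != (n_vox, t):
        raise ValueError(f"modulation must be ({n_vox}, {t})")

    t2s = truth.t2s_map[idx]
    s0 = truth.s0_map[idx]
    r2s = (1.0 + bold_amplitude * modulation) / t2s[:, None]   # (n_vox, t) 1/ms

    mult = np.ones((n_vox, t))
    tau = np.linspace(-1.0, 1.0, t)
    if include_drift and truth.drift_coeffs is not None:
        coeffs = truth.drift_coeffs[idx]                       # (n_vox, order)
        for j in range(coeffs.shape[1]):
            mult += coeffs[:, j:j + 1] * tau[None, :] ** (j + 1)
    if include_physio and truth.physio_amp > 0 and truth.physio_freqs_hz:
        t_sec = np.arange(t) * acq.tr_ms / 1000.0
        physio_rng = _rng(_PHYSIO, seed)
        for f in truth.physio_freqs_hz:
            phase = physio_rng.uniform(0, 2 * np.pi, size=n_vox)
            mult += truth.physio_amp * np.sin(
                2 * np.pi * f * t_sec[None, :] + phase[:, None])

    sd = truth.noise_sd if noise_sd is None else noise_sd
    noise_rng = _rng(_NOISE, seed)
    echo_arrays = []
    for te in acq.te_ms:
        sig = s0[:, None] * np.exp(-te * r2s) * mult
        if sd > 0:
            sig = sig + sd * noise_rng.standard_normal((n_vox, t))
        vol = np.zeros(brain.shape + (t,))
        vol[idx] = sig
        echo_arrays.append(vol)

    me = MultiEchoSeries(
        data=echo_arrays, te_ms=acq.te_ms, tr_ms=acq.tr_ms,
        mask=brain.copy(), affine=anatomy.parcellation.affine.copy(),
    )
    motion = _motion_table(t, _rng(_MOTION, seed))
    return me, motion


@dataclass
class StudySession:
    """One imaging session (subject x timepoint) carrying both acquisitions.

    4D data are realized on demand via :meth:`realize` to keep a full-scale
    study (47 sessions x 2 acquisitions) tractable in memory.
    """

    subject_id: str
    subject_index: int
    timepoint: int                      # 1 or 2
    acquisitions: dict[str, AcquisitionSpec]
    anatomy: PhantomAnatomy
    study_seed: int
    network_corr: np.ndarray
    bold_amplitude: dict[str, float]

    def _modulation(self, label: str, timepoint: int) -> np.ndarray:
        acq = self.acquisitions[label]
        truth = self.anatomy.ground_truth
        k = truth.n_networks
        idx = tuple(np.argwhere(self.anatomy.brain_mask).T)
        lab_tag = sorted(self.acquisitions).index(label)
        lat1 = latent_time_courses(
            k, acq.n_volumes, self.network_corr,
            _rng(_LATENT, self.study_seed, self.subject_index, 1, lab_tag))
        g1 = truth.network_loadings[idx] @ lat1
        if timepoint == 1:
            return g1
        s = truth.session_stability
        fresh_rng = _rng(_FRESH, self.study_seed, self.subject_index, 2, lab_tag)
        lat2 = latent_time_courses(k, acq.n_volumes, self.network_corr, fresh_rng)
        w = fresh_rng.normal(0.0, 1.0 / math.sqrt(k),
                             size=truth.network_loadings[idx].shape)
        w[truth.network_loadings[idx].sum(axis=1) == 0] = 0.0  # GM only
        g_fresh = w @ lat2
        return s * g1 + math.sqrt(1.0 - s * s) * g_fresh

    def realize(self, label: str) -> tuple[MultiEchoSeries, pd.DataFrame]:
        """Simulate this session's scan for acquisition ``label``."""
        acq = self.acquisitions[label]
        lab_tag = sorted(self.acquisitions).index(label)
        session_seed_key = (self.study_seed, self.subject_index,
                            self.timepoint, lab_tag)
        g = self._modulation(label, self.timepoint)
        me, _ = simulate_session(
            self.anatomy, acq,
            bold_amplitude=self.bold_amplitude[label],
            seed=int(_rng(*session_seed_key).integers(2 ** 31)),
            modulation=g,
        )
        motion = _motion_table(
            acq.n_volumes, _rng(_MOTION, *session_seed_key))
        return me, motion


@dataclass
class SyntheticStudy:
    """A collection of phantom sessions emulating the two-acquisition,
    two-timepoint study design."""

    sessions: list[StudySession]
    anatomies: dict[str, PhantomAnatomy]
    parcellation: Parcellation
    tissue_masks: dict[str, np.ndarray]

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    def subject_sessions(self, subject_id: str) -> list[StudySession]:
        return [s for s in self.sessions if s.subject_id == subject_id]


def make_study(
    n_subjects: int = 29,
    n_repeat: int = 18,
    scale: float = 1.0,
    seed: int = 0,
    *,
    shape: tuple[int, int, int] = (20, 20, 10),
    n_rois: int = 174,
    n_subcortical: int = 16,
    n_seed: int = 10,
    n_networks: int = 6,
    session_stability: float = 0.8,
    network_corr: np.ndarray | None = None,
    bold_amplitude: float | dict[str, float] = 0.02,
    noise_sd: float = 7.0,
) -> SyntheticStudy:
    """Build the emulated study: ``n_subjects`` subjects each scanned with an
    MB-like and an MBME-like acquisition, of whom the first ``n_repeat``
    return for a second session (n_subjects + n_repeat sessions total).

    ``scale`` multiplies volume counts (not the grid) so tests can run on
    shorter scans; repeat sessions reuse the subject's anatomy with network
    structure redrawn at ``session_stability``.
    """
    if n_repeat > n_subjects:
        raise ValueError("n_repeat cannot exceed n_subjects")
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")

    def scaled(acq: AcquisitionSpec) -> AcquisitionSpec:
        n = max(10, int(round(acq.n_volumes * scale)))
        return AcquisitionSpec(acq.tr_ms, acq.te_ms, n, acq.voxel_mm,
                               acq.duration_s)

    acqs = {"MB": scaled(MB_ACQUISITION), "MBME": scaled(MBME_ACQUISITION)}
    if not isinstance(bold_amplitude, dict):
        bold_amplitude = {lab: float(bold_amplitude) for lab in acqs}
    if network_corr is None:
        network_corr = default_network_corr(n_networks)

    anatomies: dict[str, PhantomAnatomy] = {}
    sessions: list[StudySession] = []
    for i in range(n_subjects):
        sid = f"sub-{i + 1:02d}"
        anatomies[sid] = make_phantom_anatomy(
            shape, n_rois, seed=int(_rng(_ANAT, seed, i).integers(2 ** 31)),
            n_subcortical=n_subcortical, n_seed=n_seed, n_networks=n_networks,
            session_stability=session_stability, noise_sd=noise_sd,
        )
        tps = [1, 2] if i < n_repeat else [1]
        for tp in tps:
            sessions.append(StudySession(
                subject_id=sid, subject_index=i, timepoint=tp,
                acquisitions=acqs, anatomy=anatomies[sid],
                study_seed=seed, network_corr=network_corr,
                bold_amplitude=bold_amplitude,
            ))
    first = anatomies[f"sub-01"]
    return SyntheticStudy(
        sessions=sessions, anatomies=anatomies,
        parcellation=first.parcellation, tissue_masks=first.tissue_masks,
    )


def make_fcd_testcase(
    shape: tuple[int, int, int],
    blocks: list[list[tuple[int, int, int]]],
    n_volumes: int = 200,
    seed: int = 0,
    *,
    r_thr: float = 0.6,
    neighbor_scheme: int = 26,
    jitter: float = 1e-3,
    max_tries: int = 20,
) -> tuple[BoldSeries, np.ndarray, np.ndarray]:
    """Oracle fixture for FCD: planted blocks of voxels sharing one time
    series (plus negligible jitter) in a sea of independent noise.

    Returns the series and the expected local / global FCD count maps,
    computed from the construction: a block voxel's local count is the size
    of its block's connected component under ``neighbor_scheme`` (self
    included) and its global count is the block size minus one; background
    voxels count 1 (local) and 0 (global).  The realized correlations are
    validated against ``r_thr`` and the noise redrawn if, by chance, a
    spurious pair crosses the threshold.
    """
    shape = tuple(int(s) for s in shape)
    seen: set[tuple[int, int, int]] = set()
    for b, block in enumerate(blocks):
        for v in block:
            v = tuple(int(c) for c in v)
            if v in seen:
                raise ValueError(f"blocks overlap at voxel {v}")
            if not all(0 <= c < s for c, s in zip(v, shape)):
                raise ValueError(f"voxel {v} outside shape {shape}")
            seen.add(v)

    mask = np.ones(shape, dtype=bool)
    all_vox = np.argwhere(mask)
    n_vox = len(all_vox)
    block_of = {tuple(v): b for b, block in enumerate(blocks)
                for v in [tuple(int(c) for c in w) for w in block]}

    for attempt in range(max_tries):
        rng = _rng(_NOISE, seed, attempt)
        series = rng.standard_normal((n_vox, n_volumes))
        shared = rng.standard_normal((len(blocks), n_volumes))
        for i, v in enumerate(map(tuple, all_vox)):
            if v in block_of:
                series[i] = shared[block_of[v]] + jitter * series[i]
        z = series - series.mean(axis=1, keepdims=True)
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        r = z @ z.T
        np.fill_diagonal(r, 0.0)
        ok = True
        for i, v in enumerate(map(tuple, all_vox)):
            for j in range(i + 1, n_vox):
                u = tuple(all_vox[j])
                same = v in block_of and block_of.get(u) == block_of[v]
                if same and r[i, j] < r_thr:
                    ok = False
                elif not same and r[i, j] >= r_thr:
                    ok = False
                if not ok:
                    break
            if not ok:
                break
        if ok:
            break
    else:
        raise RuntimeError("could not realize testcase satisfying threshold")

    data = np.zeros(shape + (n_volumes,))
    data[tuple(all_vox.T)] = series
    bold = BoldSeries(data=data, tr_ms=900.0, mask=mask,
                      affine=default_affine())

    expected_lfcd = np.ones(shape, dtype=np.int32)
    expected_gfcd = np.zeros(shape, dtype=np.int32)
    offs = neighbor_offsets(neighbor_scheme)
    for block in blocks:
        bset = {tuple(int(c) for c in v) for v in block}
        comp_of: dict[tuple[int, int, int], int] = {}
        comps: list[set[tuple[int, int, int]]] = []
        for v in bset:
            if v in comp_of:
                continue
            comp = {v}
            stack = [v]
            while stack:
                x, y, z3 = stack.pop()
                for dx, dy, dz in offs:
                    u = (x + dx, y + dy, z3 + dz)
                    if u in bset and u not in comp:
                        comp.add(u)
                        stack.append(u)
            ci = len(comps)
            comps.append(comp)
            for u in comp:
                comp_of[u] = ci
        for v in bset:
            expected_lfcd[v] = len(comps[comp_of[v]])
            expected_gfcd[v] = len(bset) - 1
    return bold, expected_lfcd, expected_gfcd
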