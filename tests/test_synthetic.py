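"""Phantom generator: anatomy construction, signal model, study design."""

import numpy as np
import pytest

from mefc.synthetic import (default_network_corr, make_fcd_testcase,
                            make_phantom_anatomy, make_study,
                            simulate_session)
from mefc.types import AcquisitionSpec


class TestPhantomAnatomy:
    def test_labels_partition_gm(self):
        anat = make_phantom_anatomy((20, 20, 10), 8, seed=1)
        labels = anat.parcellation.labels
        assert set(np.unique(labels)) == set(range(9))
        gm = anat.tissue_masks["gm"]
        assert np.array_equal(labels > 0, gm)
        # tissue classes are disjoint and cover the brain
        masks = anat.tissue_masks
        total = masks["gm"].astype(int) + masks["wm"] + masks["csf"]
        assert total.max() == 1
        assert np.array_equal(total > 0, masks["brain"])

    def test_seeded_determinism(self):
        a = make_phantom_anatomy((20, 20, 10), 8, seed=1)
        b = make_phantom_anatomy((20, 20, 10), 8, seed=1)
        assert np.array_equal(a.parcellation.labels, b.parcellation.labels)
        assert np.array_equal(a.ground_truth.t2s_map, b.ground_truth.t2s_map)
        assert np.array_equal(a.ground_truth.s0_map, b.ground_truth.s0_map)

    def test_gm_t2star_within_configured_range(self):
        anat = make_phantom_anatomy((20, 20, 10), 8, seed=1)
        gm_vals = anat.ground_truth.t2s_map[anat.tissue_masks["gm"]]
        assert gm_vals.min() >= 15.0 and gm_vals.max() <= 60.0
        # the dropout pocket actually exists
        assert (gm_vals < 25.0).any()

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_phantom_anatomy((6, 6, 3), 4, seed=0)

    def test_too_many_rois_rejected(self):
        with pytest.raises(ValueError, match="ROIs"):
            make_phantom_anatomy((8, 8, 4), 5000, seed=0)

    def test_roi_class_ordering(self):
        anat = make_phantom_anatomy((20, 20, 10), 10, seed=2,
                                    n_subcortical=3, n_seed=2)
        table = anat.parcellation.table
        assert list(table["class"]) == (["subcortical"] * 3
                                        + ["cortical"] * 5 + ["seed"] * 2)
        assert anat.parcellation.labels_of_class(("cortical", "subcortical")) \
            == [1, 2, 3, 4, 5, 6, 7, 8]


class TestSimulateSession:
    def test_one_array_per_echo(self, small_anatomy, short_mbme_acq):
        me, motion = simulate_session(small_anatomy, short_mbme_acq, seed=1)
        assert me.n_echoes == 3
        assert len({d.shape for d in me.data}) == 1
        assert me.n_volumes == 120
        assert motion.shape == (120, 6)
        assert list(motion.columns[:3]) == ["trans_x", "trans_y", "trans_z"]

    def test_noiseless_monoexponential_echo_ratio(self, small_anatomy,
                                                  noiseless_mbme):
        me, _ = noiseless_mbme
        idx = small_anatomy.brain_mask
        ratio = me.data[1][idx].mean(axis=1) / me.data[0][idx].mean(axis=1)
        expected = np.exp(-(30.0 - 11.0)
                          / small_anatomy.ground_truth.t2s_map[idx])
        np.testing.assert_allclose(ratio, expected, atol=1e-6)

    def test_log_signal_linear_in_te(self, small_anatomy, noiseless_mbme):
        # slope of log mean signal vs TE is -1/T2* at every brain voxel
        me, _ = noiseless_mbme
        idx = small_anatomy.brain_mask
        te = np.array(me.te_ms)
        logs = np.log(np.stack([d[idx].mean(axis=1) for d in me.data], axis=1))
        slope = np.polyfit(te, logs.T, 1)[0]
        np.testing.assert_allclose(
            slope, -1.0 / small_anatomy.ground_truth.t2s_map[idx], atol=1e-6)

    def test_planted_network_correlation(self):
        anat = make_phantom_anatomy((12, 12, 6), 2, seed=1, n_networks=2)
        corr = np.array([[1.0, 0.7], [0.7, 1.0]])
        me, _ = simulate_session(
            anat, AcquisitionSpec(900.0, (30.0,), 400), network_corr=corr,
            bold_amplitude=0.02, seed=3, noise_sd=0.0,
            include_drift=False, include_physio=False)
        labels = anat.parcellation.labels
        ts1 = me.data[0][labels == 1].mean(axis=0)
        ts2 = me.data[0][labels == 2].mean(axis=0)
        assert abs(np.corrcoef(ts1, ts2)[0, 1] - 0.7) < 0.1

    def test_non_psd_network_corr_rejected(self, small_anatomy, short_mbme_acq):
        bad = np.array([[1.0, 0.9, -0.9, 0.0],
                        [0.9, 1.0, 0.9, 0.0],
                        [-0.9, 0.9, 1.0, 0.0],
                        [0.0, 0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_session(small_anatomy, short_mbme_acq,
                             network_corr=bad, seed=0)

    def test_session_determinism(self, small_anatomy, short_mbme_acq):
        a, ma = simulate_session(small_anatomy, short_mbme_acq, seed=9)
        b, mb = simulate_session(small_anatomy, short_mbme_acq, seed=9)
        for da, db in zip(a.data, b.data):
            assert np.array_equal(da, db)
        assert ma.equals(mb)


class TestMakeStudy:
    def test_study_design_session_count(self):
        study = make_study(29, 18, scale=0.1, seed=0, shape=(12, 12, 6),
                           n_rois=8, n_subcortical=2, n_seed=0, n_networks=4)
        assert study.n_sessions == 47
        tp1 = [s for s in study.sessions if s.timepoint == 1]
        tp2 = [s for s in study.sessions if s.timepoint == 2]
        assert len(tp1) == 29 and len(tp2) == 18
        for s in study.sessions:
            assert set(s.acquisitions) == {"MB", "MBME"}

    def test_no_repeats(self):
        study = make_study(3, 0, scale=0.1, seed=0, shape=(12, 12, 6),
                           n_rois=4, n_subcortical=0, n_seed=0, n_networks=2)
        assert study.n_sessions == 3
        assert all(s.timepoint == 1 for s in study.sessions)

    def test_repeat_exceeding_subjects_rejected(self):
        with pytest.raises(ValueError, match="n_repeat"):
            make_study(2, 3, scale=0.1)

    def test_acquisition_labels_match_design(self):
        study = make_study(1, 0, scale=1.0, seed=0, shape=(12, 12, 6),
                           n_rois=4, n_subcortical=0, n_seed=0, n_networks=2)
        acqs = study.sessions[0].acquisitions
        assert acqs["MB"].tr_ms == 650.0 and acqs["MB"].te_ms == (30.0,)
        assert acqs["MB"].n_volumes == 554
        assert acqs["MBME"].tr_ms == 900.0
        assert acqs["MBME"].te_ms == (11.0, 30.0, 49.0)
        assert acqs["MBME"].n_volumes == 400

    def test_full_stability_reproduces_timepoint_one(self):
        """At session_stability 1 with nuisance off, the repeat session's
        latent signals (hence noiseless images) equal timepoint 1's."""
        study = make_study(1, 1, scale=0.1, seed=4, shape=(12, 12, 6),
                           n_rois=4, n_subcortical=0, n_seed=0, n_networks=2,
                           session_stability=1.0)
        s1, s2 = study.sessions
        g1 = s1._modulation("MBME", 1)
        g2 = s2._modulation("MBME", 2)
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_low_stability_changes_modulation(self):
        study = make_study(1, 1, scale=0.1, seed=4, shape=(12, 12, 6),
                           n_rois=4, n_subcortical=0, n_seed=0, n_networks=2,
                           session_stability=0.2)
        s1, s2 = study.sessions
        g1 = s1._modulation("MBME", 1)
        g2 = s2._modulation("MBME", 2)
        assert not np.allclose(g1, g2, atol=1e-3)


class TestFcdTestcase:
    BLOCK = [(1, 1, 0), (1, 2, 0), (2, 1, 0), (2, 2, 0)]

    def test_contiguous_block_expectations(self):
        bold, lfcd_exp, gfcd_exp = make_fcd_testcase(
            (6, 6, 1), [self.BLOCK], n_volumes=200, seed=0)
        for v in self.BLOCK:
            assert lfcd_exp[v] == 4        # block joins itself, self included
            assert gfcd_exp[v] == 3        # 4 correlated voxels minus self
        assert lfcd_exp[0, 0, 0] == 1      # background: itself only
        assert gfcd_exp[0, 0, 0] == 0

    def test_split_block_uses_connected_components(self):
        # two far-apart voxels sharing a series: global sees both, local
        # only the component containing the index voxel
        blocks = [[(0, 0, 0), (5, 5, 0)]]
        bold, lfcd_exp, gfcd_exp = make_fcd_testcase(
            (6, 6, 1), blocks, n_volumes=200, seed=1)
        assert lfcd_exp[0, 0, 0] == 1 and lfcd_exp[5, 5, 0] == 1
        assert gfcd_exp[0, 0, 0] == 1 and gfcd_exp[5, 5, 0] == 1

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_fcd_testcase((6, 6, 1), [self.BLOCK, [(2, 2, 0)]],
                              n_volumes=50, seed=0)

    def test_realized_correlations_respect_threshold(self):
        bold, _, _ = make_fcd_testcase((6, 6, 1), [self.BLOCK],
                                       n_volumes=200, seed=0)
        flat = bold.data.reshape(-1, bold.n_volumes)
        r = np.corrcoef(flat)
        in_block = np.zeros(36, dtype=bool)
        for v in self.BLOCK:
            in_block[v[0] * 6 + v[1]] = True
        within = r[np.ix_(in_block, in_block)]
        assert within.min() >= 0.6
        cross = r[np.ix_(in_block, ~in_block)]
        assert cross.max() < 0.6


def test_default_network_corr_is_valid():
    c = default_network_corr(5, rho=0.3)
    assert np.allclose(np.diag(c), 1.0)
    assert np.linalg.eigvalsh(c).min() > 0
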