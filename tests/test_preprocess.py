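"""Standard denoising chain: discard, design/df accounting, regression,
bandpass, smoothing."""

import numpy as np
import pytest

from mefc.preprocess import (NuisanceSet, bandpass, build_design,
                             discard_initial, motion_with_derivatives,
                             regress_nuisance, smooth_gaussian,
                             standard_denoise)
from mefc.types import BoldSeries, default_affine

from conftest import random_bold


class TestDiscardInitial:
    @pytest.mark.parametrize("tr_ms,n_in,n_drop", [
        (900.0, 400, 12),    # ceil(10 / 0.9)
        (650.0, 554, 16),    # ceil(10 / 0.65)
        (1000.0, 100, 10),   # exact division
    ])
    def test_drop_counts(self, tr_ms, n_in, n_drop):
        b = random_bold((2, 2, 1), n_in, seed=0, tr_ms=tr_ms)
        out = discard_initial(b)
        assert out.n_volumes == n_in - n_drop
        np.testing.assert_array_equal(out.data, b.data[..., n_drop:])

    def test_too_short_series_rejected(self):
        b = random_bold((2, 2, 1), 15, seed=0, tr_ms=900.0)
        with pytest.raises(ValueError, match="fewer than 10"):
            discard_initial(b)


class TestBuildDesign:
    def test_df_loss_twelve_motion_configuration(self):
        # 12 motion + WM + CSF + 3rd-order detrend = 17
        rng = np.random.default_rng(0)
        n = NuisanceSet(motion=rng.normal(size=(100, 12)),
                        tissue_signals=rng.normal(size=(100, 2)),
                        detrend_order=3)
        design, df_loss = build_design(n, 100)
        assert df_loss == 17
        assert design.shape == (100, 4 + 12 + 2)

    def test_df_loss_six_motion(self):
        rng = np.random.default_rng(0)
        n = NuisanceSet(motion=rng.normal(size=(50, 6)),
                        tissue_signals=rng.normal(size=(50, 2)),
                        detrend_order=3)
        assert build_design(n, 50)[1] == 11

    def test_empty_set_costs_nothing(self):
        design, df_loss = build_design(NuisanceSet(detrend_order=0), 30)
        assert df_loss == 0
        assert design.shape == (30, 1)   # constant only

    def test_components_counted(self):
        comp = np.random.default_rng(0).normal(size=(40, 5))
        n = NuisanceSet(components=comp, detrend_order=0)
        assert build_design(n, 40)[1] == 5

    def test_rank_deficient_design_warns(self):
        m = np.zeros((30, 6))
        m[:, 0] = np.linspace(0, 1, 30)
        m[:, 1] = m[:, 0]   # duplicate column
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            build_design(NuisanceSet(motion=m, detrend_order=0), 30)

    def test_motion_derivative_expansion(self):
        m = np.arange(12, dtype=float).reshape(2, 6)
        out = motion_with_derivatives(m)
        assert out.shape == (2, 12)
        np.testing.assert_array_equal(out[0, 6:], 0.0)
        np.testing.assert_array_equal(out[1, 6:], 6.0)


class TestRegressNuisance:
    def test_self_regression_removes_everything(self):
        b = random_bold((2, 2, 1), 50, seed=3)
        own = b.data[0, 0, 0]
        n = NuisanceSet(components=own[:, None], detrend_order=0)
        design, df = build_design(n, 50)
        out = regress_nuisance(b, design, df)
        assert out.data[0, 0, 0].std() == pytest.approx(0.0, abs=1e-10)
        assert out.data[0, 0, 0].mean() == pytest.approx(own.mean(), abs=1e-10)

    def test_orthogonal_regressor_leaves_series(self):
        t = 64
        b = random_bold((1, 1, 1), t, seed=0)
        sig = np.sin(2 * np.pi * np.arange(t) / 8)
        b.data[0, 0, 0] = sig
        reg = np.cos(2 * np.pi * np.arange(t) / 8)   # orthogonal to sig
        design, df = build_design(
            NuisanceSet(components=reg[:, None], detrend_order=0), t)
        out = regress_nuisance(b, design, df)
        np.testing.assert_allclose(out.data[0, 0, 0], sig, atol=1e-10)

    def test_cubic_drift_removed_by_third_order_detrend(self):
        t = 100
        tau = np.linspace(-1, 1, t)
        b = random_bold((2, 2, 1), t, seed=1)
        b.data += 5.0 * tau ** 3
        design, df = build_design(NuisanceSet(detrend_order=3), t)
        out = regress_nuisance(b, design, df)
        for v in out.data.reshape(-1, t):
            resid = v - v.mean()
            c = resid @ tau ** 3 / (np.linalg.norm(resid)
                                    * np.linalg.norm(tau ** 3))
            assert abs(c) < 1e-8

    def test_ledger_accumulates(self):
        b = random_bold((2, 2, 1), 50, seed=0)
        design, df = build_design(
            NuisanceSet(motion=np.random.default_rng(0).normal(size=(50, 6)),
                        detrend_order=2), 50)
        out = regress_nuisance(b, design, df)
        assert out.total_df_loss == 8
        assert out.df_ledger[-1].stage == "regress_nuisance"


class TestBandpass:
    def _tone(self, freq_hz, n=388, tr_ms=900.0):
        t = np.arange(n) * tr_ms / 1000.0
        sig = np.sin(2 * np.pi * freq_hz * t)
        b = random_bold((1, 1, 1), n, seed=0, tr_ms=tr_ms)
        b.data[0, 0, 0] = sig
        return b, sig

    def test_stopband_tone_attenuated(self):
        b, sig = self._tone(0.2)
        out = bandpass(b).data[0, 0, 0]
        assert np.var(out) < 0.01 * np.var(sig)

    def test_passband_tone_retained(self):
        b, sig = self._tone(0.05)
        out = bandpass(b).data[0, 0, 0]
        assert np.var(out) > 0.99 * np.var(sig)

    def test_constant_series_preserved(self):
        b = random_bold((1, 1, 1), 100, seed=0)
        b.data[0, 0, 0] = 42.0
        out = bandpass(b)
        np.testing.assert_allclose(out.data[0, 0, 0], 42.0, atol=1e-10)

    def test_above_nyquist_rejected(self):
        b = random_bold((1, 1, 1), 100, seed=0, tr_ms=900.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(b, 0.01, 0.6)

    def test_ledger_entry_is_informational(self):
        b = random_bold((1, 1, 1), 100, seed=0)
        out = bandpass(b)
        assert out.df_ledger[-1].stage == "bandpass"
        assert not out.df_ledger[-1].counted
        assert out.total_df_loss == 0


class TestSmoothGaussian:
    def test_zero_fwhm_is_identity(self):
        b = random_bold((4, 4, 2), 5, seed=0)
        np.testing.assert_array_equal(smooth_gaussian(b, 0.0).data, b.data)

    def test_sigma_from_fwhm(self):
        from mefc.preprocess import FWHM_TO_SIGMA
        # 4 mm FWHM on 3 mm voxels: 4 / (2*sqrt(2 ln 2)) / 3 = 0.5662 voxels
        assert 4.0 / FWHM_TO_SIGMA / 3.0 == pytest.approx(0.5662, abs=1e-4)

    def test_uniform_in_mask_unchanged(self):
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[2:6, 2:6, 1:3] = True
        b = random_bold((8, 8, 4), 3, seed=0, mask=mask)
        b.data[mask] = 5.0
        out = smooth_gaussian(b, 4.0)
        np.testing.assert_allclose(out.data[mask], 5.0, atol=1e-10)
        assert np.all(out.data[~mask] == 0.0)

    def test_out_of_mask_never_leaks_in(self):
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[2:6, 2:6, 1:3] = True
        b1 = random_bold((8, 8, 4), 3, seed=0, mask=mask)
        b2 = BoldSeries(b1.data.copy(), b1.tr_ms, mask, b1.affine)
        b2.data[~mask] += 100.0   # junk outside the mask
        s1 = smooth_gaussian(b1, 6.0)
        s2 = smooth_gaussian(b2, 6.0)
        np.testing.assert_allclose(s1.data[mask], s2.data[mask], atol=1e-10)


class TestStandardChain:
    def test_full_chain_reports_df_loss_17(self):
        t = 160
        b = random_bold((6, 6, 3), t, seed=2, tr_ms=900.0)
        rng = np.random.default_rng(5)
        n_after = t - 12
        nuis = NuisanceSet(motion=rng.normal(size=(n_after, 12)),
                           tissue_signals=rng.normal(size=(n_after, 2)),
                           detrend_order=3)
        out = standard_denoise(b, nuis)
        assert out.total_df_loss == 17

    def test_regression_is_idempotent(self):
        # OLS residualization is a projection: a second pass is a no-op
        t = 80
        b = random_bold((3, 3, 2), t, seed=7)
        design, df = build_design(
            NuisanceSet(motion=np.random.default_rng(1).normal(size=(t, 6)),
                        detrend_order=3), t)
        r1 = regress_nuisance(b, design, df)
        r2 = regress_nuisance(r1, design, df)
        num = np.linalg.norm(r2.data - r1.data)
        assert num / np.linalg.norm(r1.data) < 1e-6

    def test_bandpass_is_idempotent(self):
        # the spectral mask is a projection; the mean is preserved
        b = random_bold((3, 3, 2), 120, seed=8)
        b1 = bandpass(b)
        b2 = bandpass(b1)
        np.testing.assert_allclose(b2.data, b1.data, atol=1e-8)
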