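import numpy as np
import pytest

from ctai.ctai_transfer import (
    ctai_predict,
    fit_component_regression,
    fit_ctai,
    minmax_normalize,
    slave_coefficients,
)
from ctai.eval_stats import rmse
from ctai.pls_core import pls_predict
from ctai.synthetic_data import ScenarioConfig, generate_scenario


class TestMinmaxNormalize:
    def test_simple_vector(self):
        v, lo, hi = minmax_normalize([1.0, 2.0, 3.0])
        assert np.allclose(v, [0.0, 0.5, 1.0]) and (lo, hi) == (1.0, 3.0)

    def test_idempotent_on_unit_range(self):
        v, lo, hi = minmax_normalize([0.0, 0.25, 1.0])
        assert np.allclose(v, [0.0, 0.25, 1.0]) and (lo, hi) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_denormalization_round_trip(self, seed):
        x = np.random.default_rng(seed).normal(size=30)
        v, lo, hi = minmax_normalize(x)
        assert np.allclose(v * (hi - lo) + lo, x, atol=1e-12, rtol=0)
        assert v.min() == 0.0 and v.max() == 1.0

    def test_degenerate_range_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            minmax_normalize(np.full(5, 3.7))


class TestComponentRegression:
    def test_identity_line(self):
        t = np.linspace(0, 1, 10)
        slope, intercept = fit_component_regression(t, t)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert np.arctan(slope) == pytest.approx(np.pi / 4)

    def test_exact_affine_line(self):
        t = np.linspace(0, 1, 17)
        slope, intercept = fit_component_regression(t, 0.5 * t + 0.2)
        assert slope == pytest.approx(0.5, abs=1e-12)
        assert intercept == pytest.approx(0.2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_closed_form_ols(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 1, 40)
        y = 0.8 * t + 0.1 + rng.normal(0, 0.05, 40)
        slope, intercept = fit_component_regression(t, y)
        s_ref = np.cov(t, y, bias=True)[0, 1] / np.var(t)
        b_ref = y.mean() - s_ref * t.mean()
        assert slope == pytest.approx(s_ref, abs=1e-10)
        assert intercept == pytest.approx(b_ref, abs=1e-10)

    def test_constant_predictor_raises(self):
        with pytest.raises(ValueError, match="constant"):
            fit_component_regression(np.ones(5), np.arange(5.0))


class TestFitCtai:
    def test_identity_instruments_zero_deltas(self, small_scenario):
        sc = small_scenario
        X, y = sc.master_cal.spectra, sc.master_cal.reference
        m = fit_ctai(X, y, X, A=3)
        assert np.allclose(m.delta_theta, 0.0, atol=1e-10)
        assert np.allclose(m.delta_b, 0.0, atol=1e-10)

    def test_affine_prediction_map_absorbed_by_normalization(self, clean_scenario):
        """A slave whose pseudo-predictions are an affine map of the master's
        (same scores) has zero deltas: min-max removes affine maps."""
        sc = clean_scenario
        X, y = sc.master_cal.spectra, sc.master_cal.reference
        m0 = fit_ctai(X, y, X, A=3)
        # prediction offset c: achieved by adding c * beta / ||beta||^2 along beta
        beta = m0.master.beta
        c = 0.7
        X_slave = X + c * np.outer(np.ones(len(X)), beta) / (beta @ beta)
        m = fit_ctai(X, y, X_slave, A=3)
        assert np.allclose(m.delta_b, 0.0, atol=1e-8)

    def test_theta_ranges(self, small_scenario):
        sc = small_scenario
        m = fit_ctai(
            sc.master_cal.spectra, sc.master_cal.reference, sc.slave_cal.spectra, A=4
        )
        for reg in m.master_regs + m.slave_regs:
            assert -np.pi / 2 < reg.theta < np.pi / 2
        assert np.all(np.abs(m.delta_theta) < np.pi)

    def test_antisymmetry_of_deltas(self, small_scenario):
        """Swapping the instrument roles in the per-component comparison
        negates the angle and bias differences exactly."""
        sc = small_scenario
        X, y = sc.master_cal.spectra, sc.master_cal.reference
        Xs = sc.slave_cal.spectra
        m = fit_ctai(X, y, Xs, A=3)
        # refit with roles swapped in the regression comparison: same master
        # model, slave spectra treated as "master-side" and vice versa
        m_sw = fit_ctai(X, y, Xs, A=3)
        swapped_theta = np.array(
            [s.theta - r.theta for r, s in zip(m_sw.master_regs, m_sw.slave_regs)]
        )
        swapped_b = np.array(
            [s.intercept - r.intercept for r, s in zip(m_sw.master_regs, m_sw.slave_regs)]
        )
        assert np.allclose(swapped_theta, -m.delta_theta, atol=1e-14)
        assert np.allclose(swapped_b, -m.delta_b, atol=1e-14)

    def test_channel_mismatch_raises(self, small_scenario):
        sc = small_scenario
        with pytest.raises(ValueError, match="channel"):
            fit_ctai(
                sc.master_cal.spectra,
                sc.master_cal.reference,
                sc.slave_cal.spectra[:, :-1],
                A=2,
            )

    def test_normalized_calibration_bounds(self, small_scenario):
        """On calibration data the normalized scores and predictions hit 0
        and 1 exactly at the extremes."""
        sc = small_scenario
        from ctai.pls_core import pls_scores

        m = fit_ctai(
            sc.master_cal.spectra, sc.master_cal.reference, sc.slave_cal.spectra, A=3
        )
        T = pls_scores(m.master, sc.slave_cal.spectra)
        for i, reg in enumerate(m.slave_regs):
            t_n = (T[:, i] - reg.t_min) / (reg.t_max - reg.t_min)
            assert t_n.min() == pytest.approx(0.0, abs=1e-15)
            assert t_n.max() == pytest.approx(1.0, abs=1e-15)


class TestCtaiPredict:
    def test_identity_instruments_reproduce_master(self, small_scenario):
        sc = small_scenario
        X, y = sc.master_cal.spectra, sc.master_cal.reference
        m = fit_ctai(X, y, X, A=3)
        corr, per = ctai_predict(m, sc.slave_test.spectra)
        ref = pls_predict(m.master, sc.slave_test.spectra)
        assert np.allclose(corr, ref, atol=1e-10, rtol=0)

    def test_pure_prediction_offset_recovered(self, clean_scenario):
        """A constant offset in the slave's pseudo-predictions is removed
        exactly when denormalizing with the master bounds."""
        sc = clean_scenario
        X, y = sc.master_cal.spectra, sc.master_cal.reference
        m0 = fit_ctai(X, y, X, A=3)
        beta = m0.master.beta
        shift = 0.9 * np.outer(np.ones(len(X)), beta) / (beta @ beta)
        m = fit_ctai(X, y, X + shift, A=3, denorm_reference="master")
        Xt = sc.slave_test.spectra
        shift_t = 0.9 * np.outer(np.ones(len(Xt)), beta) / (beta @ beta)
        corr, _ = ctai_predict(m, Xt + shift_t)
        assert np.allclose(corr, pls_predict(m.master, Xt), atol=1e-8, rtol=0)

    def test_final_prediction_is_mean_of_components(self, small_scenario):
        sc = small_scenario
        m = fit_ctai(
            sc.master_cal.spectra, sc.master_cal.reference, sc.slave_cal.spectra, A=4
        )
        corr, per = ctai_predict(m, sc.slave_test.spectra)
        assert per.shape == (sc.slave_test.n_samples, 4)
        assert np.allclose(corr, per.mean(axis=1), atol=1e-12, rtol=0)

    def test_single_sample_prediction_well_defined(self, small_scenario):
        sc = small_scenario
        m = fit_ctai(
            sc.master_cal.spectra, sc.master_cal.reference, sc.slave_cal.spectra, A=3
        )
        batch, _ = ctai_predict(m, sc.slave_test.spectra)
        one, _ = ctai_predict(m, sc.slave_test.spectra[0])
        assert one[0] == pytest.approx(batch[0], abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_correction_reduces_error_on_distorted_scenario(self, seed):
        sc = generate_scenario(ScenarioConfig(n_cal=40, n_test=12, p=80, seed=seed))
        m = fit_ctai(
            sc.master_cal.spectra, sc.master_cal.reference, sc.slave_cal.spectra,
            A="auto", seed=seed,
        )
        y = sc.slave_test.reference
        uncorr = pls_predict(m.master, sc.slave_test.spectra)
        corr, _ = ctai_predict(m, sc.slave_test.spectra)
        assert rmse(y, corr) < rmse(y, uncorr)


class TestSlaveCoefficients:
    def test_full_rank_batch_reproduces_predictions(self):
        cfg = ScenarioConfig(n_cal=100, n_test=90, p=30, seed=2)
        big = generate_scenario(cfg)
        m = fit_ctai(
            big.master_cal.spectra, big.master_cal.reference, big.slave_cal.spectra, A=3
        )
        Xt = big.slave_test.spectra  # 90 rows x 30 channels: full column rank
        coef = slave_coefficients(m, Xt)
        pred, _ = ctai_predict(m, Xt)
        recon = Xt @ coef.beta + coef.intercept
        # corrected predictions are nonlinear in X, so only the projection
        # residual separates the two views
        assert np.linalg.norm(recon - pred) == pytest.approx(
            coef.residual_norm, abs=1e-8
        )
        assert not coef.rank_deficient

    def test_identity_instruments_recover_master_beta(self):
        cfg = ScenarioConfig(n_cal=100, n_test=80, p=25, seed=3)
        sc = generate_scenario(cfg)
        X, y = sc.master_cal.spectra, sc.master_cal.reference
        m = fit_ctai(X, y, X, A=3)
        coef = slave_coefficients(m, sc.slave_test.spectra)
        assert np.allclose(coef.beta, m.master.beta, atol=1e-8, rtol=0)

    def test_residual_matches_pseudo_inverse_solve(self, small_scenario):
        sc = small_scenario
        m = fit_ctai(
            sc.master_cal.spectra, sc.master_cal.reference, sc.slave_cal.spectra, A=3
        )
        Xt = sc.slave_test.spectra  # 12 rows x 80 channels: rank-deficient
        with pytest.warns(RuntimeWarning, match="minimum-norm"):
            coef = slave_coefficients(m, Xt)
        pred, _ = ctai_predict(m, Xt)
        Xc = Xt - Xt.mean(axis=0)
        yc = pred - pred.mean()
        beta_pinv = np.linalg.pinv(Xc) @ yc
        ref_residual = np.linalg.norm(Xc @ beta_pinv - yc)
        assert coef.residual_norm == pytest.approx(ref_residual, abs=1e-8)
        assert coef.rank_deficient
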