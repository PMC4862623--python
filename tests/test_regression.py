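"""Delay embedding, ridge solver, NMSE, and the nested block CV."""

import numpy as np
import pytest

import eegfp.bands as bd
from eegfp.dataset import N_DELAYS, SessionDataset
from eegfp.regression import (CVConfig, EFPModel, EFPRegression,
                              build_design_matrix, evaluate_prediction,
                              fit_individual_efp, inner_cv_select, nmse,
                              ridge_fit)


def _dataset(values, bold=None, offset=0):
    scheme = bd.BandScheme.uniform()
    if bold is None:
        bold = np.random.default_rng(0).standard_normal(
            values.shape[1] - offset)
    return SessionDataset.from_arrays(values, bold, scheme,
                                      bold_offset=offset,
                                      normalize_bands=False)


class TestDesignMatrix:
    def test_row_and_column_counts(self):
        rng = np.random.default_rng(0)
        ds = _dataset(rng.standard_normal((10, 400)))
        X, y, t = build_design_matrix(ds)
        assert X.shape == (353, 480)  # 400 - 47 valid rows
        assert y.shape == (353,)
        assert t[0] == 47 and t[-1] == 399

    def test_constant_bands_give_constant_rows(self):
        vals = np.full((10, 100), 2.5)
        bold = np.random.default_rng(1).standard_normal(100)
        ds = _dataset(vals, bold)
        X, _, _ = build_design_matrix(ds)
        assert np.allclose(X, 2.5)

    def test_one_hot_embedding_identity(self):
        vals = np.zeros((10, 60))
        vals[0, 47] = 1.0
        ds = _dataset(vals, np.random.default_rng(2).standard_normal(60))
        X, _, _ = build_design_matrix(ds)
        # row 0 = time 47; band 0, delay 0 -> column 0
        assert X[0, 0] == 1.0
        assert np.count_nonzero(X[0]) == 1
        # at time 48 the spike sits one delay step back
        assert X[1, 1] == 1.0

    def test_too_short_session_rejected(self):
        with pytest.raises(ValueError):
            build_design_matrix(_dataset(np.ones((10, 30)),
                                         np.random.default_rng(3).standard_normal(30)))


class TestRidgeFit:
    def test_interpolates_at_zero_penalty(self):
        X = np.eye(2)
        y = np.array([1.0, 0.0])
        w, b = ridge_fit(X, y, 0.0)
        assert np.allclose(X @ w + b, y)

    def test_infinite_shrinkage_limit(self, rng):
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        w, b = ridge_fit(X, y, 1e12)
        assert np.linalg.norm(w) < 1e-6
        assert b == pytest.approx(y.mean(), abs=1e-6)

    def test_matches_normal_equation_oracle(self, rng):
        X = rng.standard_normal((50, 8))
        y = rng.standard_normal(50)
        w, _ = ridge_fit(X, y, 0.7)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w_ref = np.linalg.solve(Xc.T @ Xc + 0.7 * np.eye(8), Xc.T @ yc)
        assert np.allclose(w, w_ref, atol=1e-8)

    def test_matches_sklearn_ridge(self, rng):
        from sklearn.linear_model import Ridge

        X = rng.standard_normal((60, 12))
        y = rng.standard_normal(60)
        w, b = ridge_fit(X, y, 2.5)
        sk = Ridge(alpha=2.5).fit(X, y)
        assert np.allclose(w, sk.coef_, atol=1e-8)
        assert b == pytest.approx(sk.intercept_, abs=1e-8)

    def test_norm_monotone_in_lambda(self, rng):
        X = rng.standard_normal((30, 10))
        y = rng.standard_normal(30)
        norms = [np.linalg.norm(ridge_fit(X, y, lam)[0])
                 for lam in np.logspace(-3, 3, 13)]
        assert all(a >= b - 1e-12 for a, b in zip(norms[:-1], norms[1:]))

    def test_rank_deficient_warns_at_zero_lambda(self, rng):
        X = np.tile(rng.standard_normal((20, 1)), (1, 3))
        y = rng.standard_normal(20)
        with pytest.warns(UserWarning, match="rank-deficient"):
            ridge_fit(X, y, 0.0)


class TestNMSE:
    def test_perfect_prediction_is_zero(self, rng):
        y = rng.standard_normal(30)
        assert nmse(y, y) == 0.0

    def test_mean_prediction_is_one(self, rng):
        y = rng.standard_normal(30)
        assert nmse(y, np.full_like(y, y.mean())) == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        y = rng.standard_normal(25)
        p = rng.standard_normal(25)
        assert nmse(y, p) == pytest.approx(np.mean((y - p) ** 2) / y.var())

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            nmse(np.ones(5), np.zeros(5))


class TestInnerCV:
    def _linear_problem(self, noise_sd, n=400, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 6))
        w = rng.standard_normal(6) * 0.5
        y = X @ w + rng.normal(0, noise_sd, n)
        return X, y

    def test_noiseless_target_selects_minimal_lambda(self):
        X, y = self._linear_problem(0.0)
        cfg = CVConfig(n_inner_splits=10, lambda_grid=np.logspace(-3, 3, 7),
                       seed=1)
        lam, _ = inner_cv_select(X, y, cfg)
        assert lam == cfg.lambda_grid[0]

    def test_pure_noise_selects_maximal_lambda(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((300, 6))
        y = rng.standard_normal(300)
        cfg = CVConfig(n_inner_splits=20, lambda_grid=np.logspace(-2, 6, 7),
                       seed=3)
        lam, _ = inner_cv_select(X, y, cfg)
        assert lam >= cfg.lambda_grid[-2]

    def test_seeded_determinism(self):
        X, y = self._linear_problem(0.5, seed=4)
        cfg = CVConfig(n_inner_splits=8, seed=9)
        lam1, t1 = inner_cv_select(X, y, cfg)
        lam2, t2 = inner_cv_select(X, y, cfg)
        assert lam1 == lam2
        assert t1.equals(t2)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            CVConfig(lambda_grid=np.array([]))


class TestFitAndEvaluate:
    def test_parameter_recovery_single_session(self, short_study, fast_cv):
        _, sessions, truths = short_study
        model = fit_individual_efp(sessions[0], fast_cv)
        r = np.corrcoef(model.coeffs.ravel(), truths[0].coeffs.ravel())[0, 1]
        assert r >= 0.8

    def test_refit_is_deterministic(self, short_study, fast_cv):
        _, sessions, _ = short_study
        a = fit_individual_efp(sessions[0], fast_cv)
        b = fit_individual_efp(sessions[0], fast_cv)
        assert np.array_equal(a.coeffs, b.coeffs)
        assert a.lam == b.lam

    def test_single_active_band_energy_concentrates(self, fast_cv):
        """A target driven by one band's history puts most fitted
        coefficient energy in that band's row."""
        from eegfp.simulate import GroundTruth, SimSpec, band_envelopes, simulate_bold

        spec = SimSpec(n_sessions=1, n_positive=1, duration_s=300.0, seed=21,
                       snr=10.0)
        env = bd.zscore(band_envelopes(spec, 0), axis=1)
        coeffs = np.zeros((10, N_DELAYS))
        coeffs[6] = np.exp(-((np.arange(N_DELAYS) / 4 - 6) ** 2) / 4)
        bold = simulate_bold(env, GroundTruth(coeffs, spec.band_scheme), spec)
        ds = SessionDataset.from_arrays(env, bold, spec.band_scheme,
                                        bold_offset=N_DELAYS - 1,
                                        normalize_bands=False)
        model = fit_individual_efp(ds, fast_cv)
        energy = np.sum(model.coeffs**2, axis=1)
        assert energy[6] / energy.sum() >= 0.7

    def test_noiseless_self_prediction(self, noiseless_study, fast_cv):
        _, sessions, _ = noiseless_study
        model = fit_individual_efp(sessions[0], fast_cv)
        assert evaluate_prediction(model, sessions[0]) > 0.99

    def test_zero_model_scores_zero_with_warning(self, short_study):
        _, sessions, _ = short_study
        zero = EFPModel(np.zeros((10, N_DELAYS)), 0.0,
                        sessions[0].band_scheme, 1.0)
        with pytest.warns(UserWarning, match="constant prediction"):
            assert evaluate_prediction(zero, sessions[0]) == 0.0

    def test_sign_flip_negates_correlation(self, short_study, fast_cv):
        _, sessions, _ = short_study
        model = fit_individual_efp(sessions[0], fast_cv)
        r = evaluate_prediction(model, sessions[0])
        flipped = EFPModel(-model.coeffs, -model.intercept,
                           model.band_scheme, model.lam)
        assert evaluate_prediction(flipped, sessions[0]) == pytest.approx(-r)


class TestModelResultsAPI:
    def test_fit_summary_and_frames(self, short_study, fast_cv):
        _, sessions, _ = short_study
        res = EFPRegression(sessions[0]).fit(fast_cv)
        assert res.coeffs.shape == (10, N_DELAYS)
        frame = res.coeff_frame()
        assert frame.shape == (10, N_DELAYS)
        text = res.summary()
        assert "lambda" in text and "NMSE" in text
        assert res.evaluate(sessions[1]) <= 1.0
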