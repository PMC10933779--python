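import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmribench import change_models as cm
from dmribench import diffusion_model as dm


def _linear_gaussian_set(n, k, rng, hetero=False):
    """Synthetic generator g = a + B y + noise; returns truth and TrainingSet."""
    y = rng.normal(size=(n, k))
    a = rng.normal(size=k)
    b = rng.normal(size=(k, k)) * 0.5
    c = rng.normal(size=(k, k)) * 0.3
    cov = c @ c.T + 0.2 * np.eye(k)
    noise = rng.multivariate_normal(np.zeros(k), cov, size=n)
    g = a + y @ b.T + noise
    pattern = cm.ChangePattern.single("s_iso", dm.STANDARD_PARAM_NAMES)
    return a, b, cov, cm.TrainingSet(y=y, g=g, pattern=pattern)


class TestDesignsAndCovarianceMap:
    def test_design_column_counts(self):
        y = np.zeros((1, 5))
        assert cm.polynomial_design(y, 1).shape == (1, 6)
        assert cm.polynomial_design(y, 2).shape == (1, 21)
        row = cm.polynomial_design(np.zeros(5), 2)[0]
        assert row[0] == 1.0 and np.allclose(row[1:], 0.0)

    def test_design_rejects_bad_degree(self):
        with pytest.raises(ValueError):
            cm.polynomial_design(np.zeros((1, 5)), 3)

    def test_quadratic_design_contains_cross_terms(self):
        y = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        row = cm.polynomial_design(y, 2)[0]
        assert 1.0 * 2.0 in row[6:]  # y_0*y_1 cross term present

    def test_zero_theta_gives_identity(self):
        assert np.allclose(cm.covariance_from_vector(np.zeros(3)), np.eye(2))

    def test_diagonal_example(self):
        theta = np.array([np.log(2.0), 0.0, np.log(3.0)])
        assert np.allclose(cm.covariance_from_vector(theta),
                           np.diag([4.0, 9.0]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=6))
    def test_any_theta_yields_spd(self, vals):
        sigma = cm.covariance_from_vector(np.array(vals))  # d = 3
        assert sigma.shape == (3, 3)
        assert np.linalg.eigvalsh(sigma).min() > 0

    def test_bad_theta_length_rejected(self):
        with pytest.raises(ValueError):
            cm.covariance_from_vector(np.zeros(5))


class TestChangePattern:
    def test_single_parameter_pattern(self):
        p = cm.ChangePattern.single("s_ex", dm.STANDARD_PARAM_NAMES)
        assert p.vector[2] == 1.0 and np.sum(p.vector != 0) == 1

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValueError):
            cm.ChangePattern("x", np.array([1.0, 1.0, 0, 0, 0, 0, 0, 0]),
                             dm.STANDARD_PARAM_NAMES)

    def test_default_pattern_set_covers_all_parameters(self):
        pats = cm.single_parameter_patterns(dm.StandardModel())
        assert [p.name for p in pats] == list(dm.STANDARD_PARAM_NAMES)


class TestDirectionalDerivative:
    def test_fraction_pattern_unit_b0_derivative(self, protocol):
        # adding ds_iso raises the b=0 signal one-for-one
        model = dm.StandardModel()
        params = {"s_iso": 0.5, "s_in": 0.5, "s_ex": 0.0, "d_iso": 3.0,
                  "d_in_a": 1.7, "d_ex_a": 1.7, "tau": 0.5, "odi": 0.3}
        pat = cm.ChangePattern.single("s_iso", model.param_names)
        y, g, keep = cm.directional_derivative(model, params, pat, protocol)
        assert keep.size == 1
        assert g[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_absent_parameter_zero_derivative(self, protocol):
        # d_iso does not enter the signal when s_iso = 0
        model = dm.StandardModel()
        params = {"s_iso": 0.0, "s_in": 0.6, "s_ex": 0.4, "d_iso": 3.0,
                  "d_in_a": 1.7, "d_ex_a": 1.7, "tau": 0.5, "odi": 0.3}
        pat = cm.ChangePattern.single("d_iso", model.param_names)
        _, g, _ = cm.directional_derivative(model, params, pat, protocol)
        assert np.max(np.abs(g)) < 1e-8

    def test_first_order_consistency(self, protocol):
        # central differences at two step sizes agree to O(t^2)
        model = dm.StandardModel()
        params = {"s_iso": 0.2, "s_in": 0.5, "s_ex": 0.3, "d_iso": 3.0,
                  "d_in_a": 1.7, "d_ex_a": 1.5, "tau": 0.4, "odi": 0.3}
        pat = cm.ChangePattern.single("odi", model.param_names)
        _, g1, _ = cm.directional_derivative(model, params, pat, protocol,
                                             rel_step=1e-3)
        _, g2, _ = cm.directional_derivative(model, params, pat, protocol,
                                             rel_step=1e-4)
        assert np.max(np.abs(g1 - g2)) < 1e-3 * (1 + np.max(np.abs(g2)))

    def test_boundary_step_shrinking(self, protocol):
        # baseline at the edge of the odi range still yields a finite sample
        model = dm.StandardModel()
        params = {"s_iso": 0.2, "s_in": 0.5, "s_ex": 0.3, "d_iso": 3.0,
                  "d_in_a": 1.7, "d_ex_a": 1.5, "tau": 0.4,
                  "odi": dm.ODI_MAX - 1e-6}
        pat = cm.ChangePattern.single("odi", model.param_names)
        y, g, keep = cm.directional_derivative(model, params, pat, protocol)
        assert keep.size == 1 and np.all(np.isfinite(g))


class TestTraining:
    def test_linear_gaussian_recovery(self, rng):
        # quick sanity recovery; the formal 3-SE check runs at larger n in the
        # acceptance suite
        n, k = 6000, 2
        a, b, cov, ts = _linear_gaussian_set(n, k, rng)
        m = cm.train_change_model(ts, mean_degree=1, cov_degree=1,
                                  standardize=False, trim_iqr=None,
                                  ridge_per_sample=0.0)
        assert np.allclose(m.w_mu[0], a, atol=0.06)
        assert np.allclose(m.w_mu[1:].T, b, atol=0.06)
        _, sigma = m.predict(np.zeros(k))
        assert np.allclose(sigma, cov, atol=0.08)

    def test_mle_equals_ols_under_homoscedastic_noise(self, rng):
        # with constant covariance the mean MLE reduces to least squares
        n, k = 4000, 2
        y = rng.normal(size=(n, k))
        g = 0.3 + y @ rng.normal(size=(k, k)).T + rng.normal(size=(n, k)) * 0.4
        pat = cm.ChangePattern.single("s_in", dm.STANDARD_PARAM_NAMES)
        ts = cm.TrainingSet(y=y, g=g, pattern=pat)
        m = cm.train_change_model(ts, mean_degree=2, cov_degree=1,
                                  standardize=False, trim_iqr=None,
                                  ridge_per_sample=0.0)
        F = cm.polynomial_design(y, 2)
        w_ols, *_ = np.linalg.lstsq(F, g, rcond=None)
        assert np.max(np.abs(m.w_mu - w_ols)) < 1e-3

    def test_scalar_case_matches_closed_form(self, rng):
        # 1-D homoscedastic case: MLE mean = OLS line, variance = mean square
        # residual (computed in closed form, independently of the optimiser)
        n = 3000
        y = rng.normal(size=(n, 1))
        g = 1.5 - 2.0 * y + rng.normal(size=(n, 1)) * 0.7
        pat = cm.ChangePattern.single("tau", dm.STANDARD_PARAM_NAMES)
        m = cm.train_change_model(cm.TrainingSet(y=y, g=g, pattern=pat),
                                  mean_degree=1, cov_degree=1,
                                  standardize=False, trim_iqr=None,
                                  ridge_per_sample=0.0)
        F = np.column_stack([np.ones(n), y])
        w = np.linalg.lstsq(F, g, rcond=None)[0]
        var = np.mean((g - F @ w) ** 2)
        assert np.allclose(m.w_mu, w, atol=2e-3)
        _, sigma = m.predict(np.array([0.0]))
        assert sigma[0, 0] == pytest.approx(var, rel=0.05)

    def test_nll_non_increasing_across_stages(self, protocol):
        model = dm.ConstrainedModel()
        pat = cm.ChangePattern.single("s_in", model.param_names)
        ts = cm.build_training_set(model, pat, protocol, n=2500, seed=0)
        m = cm.train_change_model(ts)
        nlls = m.metadata["stage_nll"]
        assert nlls[0] >= nlls[1] >= nlls[2]

    def test_training_is_seed_reproducible(self, protocol):
        model = dm.ConstrainedModel()
        pat = cm.ChangePattern.single("odi", model.param_names)
        t1 = cm.build_training_set(model, pat, protocol, n=2500, seed=11)
        t2 = cm.build_training_set(model, pat, protocol, n=2500, seed=11)
        assert np.array_equal(t1.y, t2.y) and np.array_equal(t1.g, t2.g)
        m1 = cm.train_change_model(t1)
        m2 = cm.train_change_model(t2)
        assert np.array_equal(m1.w_mu, m2.w_mu)
        assert np.array_equal(m1.w_sigma, m2.w_sigma)

    def test_insufficient_samples_rejected(self, rng):
        pat = cm.ChangePattern.single("s_iso", dm.STANDARD_PARAM_NAMES)
        ts = cm.TrainingSet(y=rng.normal(size=(100, 5)),
                            g=rng.normal(size=(100, 5)), pattern=pat)
        with pytest.raises(ValueError):
            cm.train_change_model(ts)

    def test_inactive_pattern_predicts_zero_mean(self, protocol):
        # d_iso cannot move the summaries on the s_iso = 0 prior subspace
        model = dm.StandardModel(dm.PriorSpec(s_iso_delta_weight=1.0))
        pat = cm.ChangePattern.single("d_iso", model.param_names)
        ts = cm.build_training_set(model, pat, protocol, n=2500, seed=1)
        m = cm.train_change_model(ts)
        mu, _ = m.predict(ts.y[:50])
        assert np.max(np.abs(mu)) < 1e-4


class TestPrediction:
    def test_predicted_covariance_spd_and_deterministic(self, rng):
        _, _, _, ts = _linear_gaussian_set(3000, 2, rng)
        m = cm.train_change_model(ts, mean_degree=1)
        y = rng.normal(size=(40, 2))
        mu1, s1 = m.predict(y)
        mu2, s2 = m.predict(y.copy())
        assert np.array_equal(mu1, mu2) and np.array_equal(s1, s2)
        assert np.all(np.linalg.eigvalsh(s1)[:, 0] > 0)

    def test_dimension_mismatch_rejected(self, rng):
        _, _, _, ts = _linear_gaussian_set(3000, 2, rng)
        m = cm.train_change_model(ts, mean_degree=1)
        with pytest.raises(ValueError):
            m.predict(np.zeros(5))

    def test_mean_matches_binned_empirical_derivative(self, rng):
        # within a narrow y-bin the predicted mean tracks the empirical mean
        n, k = 20000, 1
        y = rng.uniform(-2, 2, size=(n, k))
        g = 0.3 + 0.8 * y - 0.4 * y**2 + rng.normal(size=(n, k)) * 0.3
        pat = cm.ChangePattern.single("s_ex", dm.STANDARD_PARAM_NAMES)
        m = cm.train_change_model(cm.TrainingSet(y=y, g=g, pattern=pat),
                                  mean_degree=2, trim_iqr=None)
        sel = np.abs(y[:, 0] - 0.5) < 0.05
        emp = g[sel].mean()
        se = g[sel].std() / np.sqrt(sel.sum())
        mu, _ = m.predict(np.array([0.5]))
        assert abs(mu[0] - emp) < 3 * se


class TestSerialisation:
    def _toy_models(self, rng):
        _, _, _, ts = _linear_gaussian_set(3000, 2, rng)
        ts.protocol_hash = "cafe0123deadbeef"
        return [cm.train_change_model(ts, mean_degree=1)]

    def test_round_trip_bitwise(self, tmp_path, rng):
        models = self._toy_models(rng)
        path = tmp_path / "models.json"
        cm.save_models(models, path)
        loaded = cm.load_models(path)
        y = rng.normal(size=(10, 2))
        mu0, s0 = models[0].predict(y)
        mu1, s1 = loaded[0].predict(y)
        assert np.array_equal(mu0, mu1) and np.array_equal(s0, s1)

    def test_tampered_archive_rejected(self, tmp_path, rng):
        import json
        path = tmp_path / "models.json"
        cm.save_models(self._toy_models(rng), path)
        doc = json.loads(path.read_text())
        doc["models"][0]["w_mu"][0][0] += 1.0
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="checksum"):
            cm.load_models(path)

    def test_protocol_hash_mismatch_rejected(self, tmp_path, rng):
        path = tmp_path / "models.json"
        cm.save_models(self._toy_models(rng), path)
        with pytest.raises(ValueError, match="protocol"):
            cm.load_models(path, expected_protocol_hash="0000000000000000")

    def test_missing_file_clear_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            cm.load_models(tmp_path / "absent.json")
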