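import numpy as np
import pytest

from bidomainuq import gp
from bidomainuq.synthetic import SurrogateSpec, make_surrogate


@pytest.fixture(scope="module")
def nonlinear_model():
    rng = np.random.default_rng(4)
    x = rng.random((120, 3))
    y = np.sin(2 * np.pi * x[:, 0]) + 0.5 * x[:, 1] ** 2 + 0.2 * x[:, 2]
    model, report = gp.fit(x, y, seed=4)
    return model, report


class TestFit:
    def test_linear_response_absorbed_by_mean(self):
        rng = np.random.default_rng(0)
        x = rng.random((60, 4))
        y = 1.5 + x @ np.array([2.0, -1.0, 0.5, 0.0])
        model, report = gp.fit(x, y, seed=0)
        xs = rng.random((30, 4))
        pred = model.predict(xs)
        truth = 1.5 + xs @ np.array([2.0, -1.0, 0.5, 0.0])
        assert np.max(np.abs(pred - truth)) < 1e-6
        assert report.passed

    def test_interpolates_training_points(self, nonlinear_model):
        model, _ = nonlinear_model
        pred = model.predict(model.x)
        assert np.max(np.abs(pred - model.y)) < 1e-4

    def test_heldout_accuracy_on_smooth_surrogate(self):
        surrogate = make_surrogate(
            SurrogateSpec(linear=(1.0, 0.5, 0.0, 0.0, 0.2, 0.0, 0.0, 0.3),
                          sine=(0.5, 0.0, 0.4), sine_phase=(0.0, 0.0, 1.0))
        )
        rng = np.random.default_rng(1)
        x = rng.random((240, 8))
        y = surrogate(x)
        model, _ = gp.fit(x, y, seed=1)
        x_new = rng.random((200, 8))
        rmse = np.sqrt(np.mean((model.predict(x_new) - surrogate(x_new)) ** 2))
        assert rmse < 0.05 * (y.max() - y.min())

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            gp.fit(np.random.rand(10, 2), np.random.rand(10))


class TestMahalanobis:
    def test_near_zero_when_emulator_interpolates_test_data(self):
        rng = np.random.default_rng(2)
        x = rng.random((60, 2))
        y = np.sin(2 * np.pi * x[:, 0]) - x[:, 1]
        model = gp.fit_gp(x, y, seed=2)
        # validating at training points: residuals vanish, D far below ref
        rep = gp.mahalanobis_validate(model, x[:10], y[:10])
        assert rep.mahalanobis < 0.05 * rep.reference_mean

    def test_reference_mean_matches_test_size(self):
        # 216/24 split: the reference distribution is centred near m = 24
        rng = np.random.default_rng(3)
        x = rng.random((240, 8))
        y = np.sin(2 * np.pi * x[:, 0]) + x[:, 1]
        model, report = gp.fit(x, y, train_fraction=0.9, seed=3)
        assert report.n_train == 216 and report.n_test == 24
        assert report.reference_mean == pytest.approx(24.0, abs=0.5)

    def test_calibration_under_the_predictive_distribution(self, nonlinear_model):
        """Residuals drawn from the predictive law keep D near its reference."""
        model, _ = nonlinear_model
        rng = np.random.default_rng(7)
        xt = rng.random((12, 3))
        mean, cov = model.predict(xt, full_cov=True)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(xt)))
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            yt = mean + chol @ rng.standard_normal(len(xt))
            rep = gp.mahalanobis_validate(model, xt, yt)
            hits += abs(rep.mahalanobis - rep.reference_mean) <= 3 * rep.reference_std
        assert hits >= 0.95 * n_rep


class TestMainEffects:
    def test_constant_output_gives_flat_curve(self):
        rng = np.random.default_rng(5)
        x = rng.random((40, 2))
        y = np.full(40, 3.0) + 1e-9 * x[:, 0]
        model = gp.fit_gp(x, y, seed=5)
        curve = gp.main_effect(model, 0)
        assert np.max(np.abs(curve.values)) < 1e-6

    def test_additive_term_recovered(self):
        rng = np.random.default_rng(6)
        x = rng.random((120, 3))
        y = np.sin(2 * np.pi * x[:, 0]) + 2.0 * x[:, 1]
        model = gp.fit_gp(x, y, seed=6)
        curve = gp.main_effect(model, 0)
        expected = np.sin(2 * np.pi * curve.grid)
        expected -= np.sin(2 * np.pi * 0.5) * np.exp(-0.5 * (2 * np.pi) ** 2 * 0.04)
        inner = (curve.grid > 0.05) & (curve.grid < 0.95)
        assert np.max(np.abs(curve.values[inner] - expected[inner])) < 0.05

    def test_product_interaction_conditional_mean(self):
        # for f = x1 x2 with x2 ~ N(0.5, v): E[f | x1] = 0.5 x1
        rng = np.random.default_rng(8)
        x = rng.random((150, 2))
        y = x[:, 0] * x[:, 1]
        model = gp.fit_gp(x, y, seed=8)
        curve = gp.main_effect(model, 0)
        absolute = curve.values + curve.emulator_mean
        inner = (curve.grid > 0.1) & (curve.grid < 0.9)
        assert np.max(np.abs(absolute[inner] - 0.5 * curve.grid[inner])) < 0.02


class TestSensitivityIndices:
    def test_single_active_input(self):
        rng = np.random.default_rng(9)
        x = rng.random((80, 3))
        model = gp.fit_gp(x, x[:, 0].copy(), seed=9)
        rep = gp.sensitivity_indices(model)
        assert rep.indices[0] == pytest.approx(1.0, abs=0.02)
        assert np.all(rep.indices[1:] < 0.02)

    def test_variance_ratio_three_to_one(self):
        rng = np.random.default_rng(10)
        x = rng.random((100, 2))
        model = gp.fit_gp(x, 3 * x[:, 0] + x[:, 1], seed=10)
        rep = gp.sensitivity_indices(model)
        assert rep.indices[0] == pytest.approx(0.9, abs=0.02)
        assert rep.indices[1] == pytest.approx(0.1, abs=0.02)

    def test_surrogate_index_recovery_at_design_scale(self):
        """Indices of a known additive+interaction surrogate recovered +-0.05."""
        spec = SurrogateSpec(
            linear=(2.0, 1.0, 0.0, 0.5, 0.0, 0.0, 0.0, 0.0),
            sine=(0.0, 0.0, 0.6), sine_phase=(0.0, 0.0, 0.5),
            interactions=((0, 1, 1.0),),
        )
        surrogate = make_surrogate(spec)
        rng = np.random.default_rng(11)
        x = rng.random((216, 8))
        model = gp.fit_gp(x, surrogate(x), seed=11)
        rep = gp.sensitivity_indices(model)
        np.testing.assert_allclose(rep.indices, surrogate.indices, atol=0.05)

    def test_indices_invariant_to_output_rescaling(self):
        rng = np.random.default_rng(12)
        x = rng.random((80, 2))
        y = np.sin(2 * np.pi * x[:, 0]) + x[:, 1]
        a = gp.sensitivity_indices(gp.fit_gp(x, y, seed=12))
        b = gp.sensitivity_indices(gp.fit_gp(x, 100.0 * y - 7.0, seed=12))
        np.testing.assert_allclose(a.indices, b.indices, atol=0.02)

    def test_plugin_variant_bounds_indices(self, nonlinear_model):
        model, _ = nonlinear_model
        rep = gp.sensitivity_indices(model, include_emulator_uncertainty=False)
        assert np.all(rep.indices >= 0) and np.all(rep.indices <= 1.0 + 1e-9)
        assert rep.total <= 1.05
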