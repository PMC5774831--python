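"""The polynomial-kernel Gaussian process: kernel, training, prediction."""

import numpy as np
import pytest

import woundspeed as ws
from woundspeed.gp import kernel_eval


class TestKernel:
    @pytest.mark.parametrize(
        "t,tp,C,sk,expected",
        [
            (2.0, 3.0, 0.0, 0.0, 36.0),  # homogeneous quadratic (t t')^2
            (5.0, 0.0, 2.0, 1.5, 2.0 + 1.5**4),  # t'=0: C + sigma_k^4
            (1.0, 1.0, 1.0, 1.0, 5.0),  # 1 + (1+1)^2
        ],
    )
    def test_direct_values(self, t, tp, C, sk, expected):
        assert kernel_eval(t, tp, C, sk) == pytest.approx(expected)

    def test_symmetry_and_psd(self):
        t = np.linspace(0, 1, 7)
        K = kernel_eval(t, t, 0.7, 0.3)
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-9

    def test_negative_constant_rejected(self):
        with pytest.raises(ValueError):
            kernel_eval(1.0, 1.0, -1.0, 0.0)


class TestFit:
    def test_exact_quadratic_reproduced(self):
        t = np.linspace(1, 16, 8)
        y = 3.0 + 2.0 * t - 0.5 * t**2
        fit = ws.fit_gp(t, y, np.zeros_like(y), seed=0)
        grid = np.linspace(1, 16, 200)
        mean, _ = ws.predict(fit, grid)
        truth = 3.0 + 2.0 * grid - 0.5 * grid**2
        assert np.max(np.abs(mean - truth) / np.maximum(np.abs(truth), 1.0)) < 1e-3

    def test_constant_series_recovered_exactly(self):
        t = np.array([1.0, 2.0, 5.0, 9.0])
        fit = ws.fit_gp(t, np.full(4, 42.0), seed=0)
        mean, std = ws.predict(fit, np.linspace(1, 9, 30))
        np.testing.assert_allclose(mean, 42.0, rtol=1e-9)
        assert std.max() < 1e-3  # degenerate scale: prior collapses to c

    def test_training_point_interpolation(self):
        # noise-free data inside the kernel's function space (a quadratic)
        # is reproduced at the training points to within the jitter floor
        t = np.arange(1.0, 9.0)
        y = 100 - 5 * t + 0.8 * t**2
        fit = ws.fit_gp(t, y, np.zeros_like(y), seed=0)
        mean, _ = ws.predict(fit, t)
        np.testing.assert_allclose(mean, y, rtol=1e-6)

    def test_optimum_beats_all_restarts(self):
        rng = np.random.default_rng(3)
        t = np.arange(1.0, 13.0)
        y = 3000 - 200 * t + 4 * t**2 + rng.normal(0, 30, t.size)
        fit = ws.fit_gp(t, y, np.full(t.size, 900.0), seed=5)
        assert fit.log_marginal_likelihood >= fit.restart_lmls.max() - 1e-8

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ws.fit_gp(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_negative_noise_rejected(self):
        t = np.arange(3.0)
        with pytest.raises(ValueError, match="noise"):
            ws.fit_gp(t, t, np.array([1.0, -1.0, 1.0]))

    def test_serialization_roundtrip(self, tmp_path):
        import json

        t = np.arange(1.0, 7.0)
        fit = ws.fit_gp(t, t**2, seed=0)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["C"] == pytest.approx(fit.C)
        assert payload["n_train"] == 6


class TestPredictUncertainty:
    def test_posterior_std_nonnegative_and_small_at_clean_points(self):
        t = np.arange(1.0, 9.0)
        fit = ws.fit_gp(t, 10 + t**2, np.zeros_like(t), seed=0)
        _, std = ws.predict(fit, t)
        assert (std >= 0).all()
        assert std.max() < 1e-2 * fit.y_scale

    def test_extrapolation_variance_grows(self):
        rng = np.random.default_rng(1)
        t = np.arange(1.0, 9.0)
        y = 50 - 2 * t + rng.normal(0, 1, t.size)
        fit = ws.fit_gp(t, y, np.full(t.size, 1.0), seed=0)
        _, std = ws.predict(fit, np.array([5.0, 30.0]))
        assert std[1] > std[0]

    def test_noisier_point_never_sharper(self):
        t = np.arange(1.0, 9.0)
        y = 100 - 3 * t
        base = np.full(t.size, 1.0)
        noisier = base.copy()
        noisier[4] = 25.0
        f1 = ws.fit_gp(t, y, base, seed=0)
        f2 = ws.fit_gp(t, y, noisier, seed=0)
        # compare at fixed hyperparameters to isolate the noise effect
        f2.C, f2.sigma_k, f2._chol, f2._alpha = f1.C, f1.sigma_k, None, None
        _, s1 = ws.predict(f1, t[[4]])
        _, s2 = ws.predict(f2, t[[4]])
        assert s2[0] >= s1[0]

    def test_imputation_calibration(self):
        """A held-out interior point falls within 2 predictive SD (posterior
        function SD plus known measurement noise) in >= 90% of seeded trials."""
        hits = 0
        n_trials = 50
        for s in range(n_trials):
            rng = np.random.default_rng(s)
            t = np.arange(1.0, 17.0)
            sd = 300.0
            y = 30000 - 3000 * t + 50 * t**2 + rng.normal(0, sd, t.size)
            hold = 8
            keep = np.ones(t.size, bool)
            keep[hold] = False
            fit = ws.fit_gp(t[keep], y[keep], np.full(keep.sum(), sd**2), seed=s)
            mean, fstd = ws.predict(fit, t[[hold]])
            total = np.hypot(fstd[0], sd)
            hits += abs(mean[0] - y[hold]) <= 2 * total
        assert hits >= 0.9 * n_trials


class TestAgainstReferenceGP:
    def test_matches_sklearn_at_fixed_hyperparameters(self):
        """Independent cross-check: at the same kernel and noise, the
        posterior and log marginal likelihood agree with scikit-learn's GP
        regression using ConstantKernel + DotProduct**2."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import ConstantKernel, DotProduct

        rng = np.random.default_rng(7)
        tn = np.linspace(0, 1, 9)
        yn = 0.3 - 1.2 * tn + 0.9 * tn**2 + rng.normal(0, 0.05, tn.size)
        noise = np.full(tn.size, 0.05**2)
        C, sk = 0.8, 0.6

        fit = ws.GPFit(
            t_train=tn, y_train=yn, noise_var=noise, C=C, sigma_k=sk,
            t_offset=0.0, t_scale=1.0, y_mean=0.0, y_scale=1.0,
            log_marginal_likelihood=np.nan, jitter=0.0,
        )
        grid = np.linspace(-0.2, 1.2, 40)
        mean, std = ws.predict(fit, grid)

        kern = ConstantKernel(C, "fixed") + DotProduct(sigma_0=sk, sigma_0_bounds="fixed") ** 2
        ref = GaussianProcessRegressor(kernel=kern, alpha=noise, optimizer=None)
        ref.fit(tn[:, None], yn)
        ref_mean, ref_std = ref.predict(grid[:, None], return_std=True)

        np.testing.assert_allclose(mean, ref_mean, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(std, ref_std, rtol=1e-6, atol=1e-8)

        from woundspeed.gp import _neg_lml

        mine = -_neg_lml(np.log([C, sk**2]), tn, yn, noise)
        theirs = ref.log_marginal_likelihood_value_
        # same expression up to the tiny jitter my ladder adds
        assert mine == pytest.approx(theirs, abs=1e-3)
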