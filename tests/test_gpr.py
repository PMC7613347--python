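"""ARD-kernel Gaussian process regression."""

import numpy as np
import pytest

from prosailgpr import gpr
from prosailgpr.gpr import _nll_and_grad


class TestKernel:
    def test_self_similarity_is_nu(self, rng):
        x = rng.random((1, 4))
        K = gpr.ard_kernel(x, x, 2.5, np.ones(4))
        assert K[0, 0] == pytest.approx(2.5, rel=1e-12)

    def test_decay_with_distance(self):
        x0 = np.zeros((1, 3))
        far = np.full((1, 3), 50.0)
        K = gpr.ard_kernel(x0, far, 1.0, np.ones(3))
        assert K[0, 0] < 1e-12

    def test_closed_form_1d(self):
        K = gpr.ard_kernel(np.array([[0.0]]), np.array([[1.0]]), 1.0, np.array([1.0]))
        assert K[0, 0] == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_symmetry_and_psd(self, rng):
        X = rng.random((40, 6))
        K = gpr.ard_kernel(X, X, 1.3, rng.uniform(0.5, 2.0, 6))
        assert np.max(np.abs(K - K.T)) < 1e-12
        w = np.linalg.eigvalsh(K + 1e-10 * np.eye(40))
        assert w.min() > -1e-10

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gpr.ard_kernel(np.zeros((1, 3)), np.zeros((1, 4)), 1.0, np.ones(3))


class TestTwoPointPosterior:
    """Hand-computed 2x2 linear algebra against fit/predict."""

    def setup_method(self):
        self.X = np.array([[0.0], [1.0]])
        self.y = np.array([1.0, 3.0])
        self.nu, self.sn, self.sb = 2.0, 0.5, 1.0
        self.model = gpr.fit(
            self.X, self.y, optimize_hyperparameters=False,
            init=dict(nu=self.nu, sigma_n=self.sn, sigma_b=self.sb),
        )

    def hand(self, xq):
        Xs = self.model.X_train
        xqs = self.model.standardize(np.array([[xq]]))[0, 0]
        K = self.nu * np.exp(-0.5 * (Xs - Xs.T) ** 2 / self.sb**2)
        Ky = K + (self.sn**2 + 1e-10 * self.nu) * np.eye(2)
        ks = self.nu * np.exp(-0.5 * (Xs[:, 0] - xqs) ** 2 / self.sb**2)
        yc = self.y - self.y.mean()
        mean = ks @ np.linalg.solve(Ky, yc) + self.y.mean()
        var = self.nu + self.sn**2 - ks @ np.linalg.solve(Ky, ks)
        return mean, var

    @pytest.mark.parametrize("xq", [0.5, -0.3, 2.0])
    def test_mean_and_variance(self, xq):
        p = gpr.predict(self.model, np.array([xq]))
        mean, var = self.hand(xq)
        assert p.mean == pytest.approx(mean, abs=1e-10)
        assert p.variance == pytest.approx(var, abs=1e-10)


def test_constant_targets_return_constant(rng):
    X = rng.random((20, 3))
    y = np.full(20, 4.2)
    m = gpr.fit(X, y, optimize_hyperparameters=False,
                init=dict(nu=1.0, sigma_n=0.1, sigma_b=1.0))
    p = gpr.predict(m, rng.random((5, 3)))
    assert np.allclose(p.mean, 4.2, atol=1e-9)


def test_noiseless_interpolation(rng):
    X = rng.uniform(0, 1, (40, 3))
    y = np.sin(3 * X.sum(axis=1))
    m = gpr.fit(X, y, optimize_hyperparameters=False,
                init=dict(nu=1.0, sigma_n=0.0, sigma_b=1.0))
    resid = np.abs(gpr.predict(m, X).mean - y)
    assert resid.max() < 1e-6


def test_prior_reversion_far_from_data(rng):
    X = rng.random((30, 4))
    y = rng.random(30)
    m = gpr.fit(X, y, optimize_hyperparameters=False,
                init=dict(nu=1.5, sigma_n=0.2, sigma_b=0.5))
    p = gpr.predict(m, np.full(4, 100.0))
    assert p.mean == pytest.approx(m.bias, abs=1e-8)
    assert p.variance == pytest.approx(1.5 + 0.2**2, abs=1e-8)


def test_predictive_variance_nonnegative(rng):
    X = rng.uniform(0, 1, (150, 5))
    y = np.sin(4 * X[:, 0]) + rng.normal(0, 0.05, 150)
    m = gpr.fit(X, y, restarts=1, seed=0, maxiter=30)
    q = rng.uniform(-1, 2, (10_000, 5))
    p = gpr.predict(m, q)
    assert np.all(p.variance >= 0)


def test_marginal_likelihood_improves_from_start(rng):
    X = rng.uniform(0, 1, (80, 3))
    y = np.sin(5 * X[:, 0]) + 0.3 * X[:, 1] + rng.normal(0, 0.1, 80)
    m = gpr.fit(X, y, restarts=1, seed=0)
    Xs, yc = m.X_train, y - y.mean()
    theta0 = np.log(np.concatenate([[yc.var()], [0.1 * yc.std()], np.full(3, np.sqrt(3))]))
    nll0, _ = _nll_and_grad(theta0, Xs, yc)
    assert m.log_evidence >= -nll0 - 1e-9


def test_gradient_matches_finite_differences(rng):
    X = rng.uniform(0, 1, (25, 2))
    y = np.sin(3 * X[:, 0]) + rng.normal(0, 0.1, 25)
    theta = np.log(np.array([1.2, 0.3, 0.8, 1.5]))
    f0, g = _nll_and_grad(theta, X, y)
    for i in range(theta.size):
        d = np.zeros_like(theta)
        d[i] = 1e-6
        fp, _ = _nll_and_grad(theta + d, X, y)
        fm, _ = _nll_and_grad(theta - d, X, y)
        assert g[i] == pytest.approx((fp - fm) / 2e-6, rel=1e-4, abs=1e-7)


def test_hyperparameter_recovery_on_gp_draw():
    """Data drawn from a known ARD-SE GP with length-scales (1, 10):
    the fitted length-scale ratio recovers the factor-10 anisotropy
    within a factor of 2."""
    rng = np.random.default_rng(7)
    X = rng.uniform(0, 5, (200, 2))
    sb_true = np.array([1.0, 10.0])
    K = gpr.ard_kernel(X, X, 1.0, sb_true) + 1e-8 * np.eye(200)
    y = np.linalg.cholesky(K) @ rng.normal(size=200)
    m = gpr.fit(X, y, restarts=3, seed=1)
    # compare in the original units: sigma_b is reported in standardized
    # units, so rescale by the per-band standard deviation
    sb_orig = m.sigma_b * m.x_scale
    ratio = sb_orig[1] / sb_orig[0]
    assert 5.0 < ratio < 20.0


class TestBandRelevance:
    def test_sorted_by_sigma(self):
        m = _dummy_model(sigma_b=np.array([5.0, 1.0, 3.0]),
                         names=("B2", "B5", "B8"))
        assert [n for n, _ in gpr.band_relevance(m)] == ["B5", "B8", "B2"]

    def test_ties_preserve_band_order(self):
        m = _dummy_model(sigma_b=np.ones(3), names=("B2", "B5", "B8"))
        assert [n for n, _ in gpr.band_relevance(m)] == ["B2", "B5", "B8"]

    def test_informative_band_ranked_first(self, rng):
        X = rng.uniform(0, 1, (150, 4))
        y = np.sin(6 * X[:, 1])  # only band 1 matters
        m = gpr.fit(X, y, restarts=2, seed=0, band_names=("a", "b", "c", "d"))
        assert gpr.band_relevance(m)[0][0] == "b"


def _dummy_model(sigma_b, names):
    B = sigma_b.size
    return gpr.GPRModel(
        X_train=np.zeros((2, B)), weights=np.zeros(2), bias=0.0, nu=1.0,
        sigma_b=sigma_b, sigma_n=0.1, x_mean=np.zeros(B), x_scale=np.ones(B),
        band_names=names,
    )


class TestCrossValidation:
    def test_perfect_predictor(self):
        y = np.linspace(0, 5, 60)
        X = y[:, None]
        rep, folds = gpr.cross_validate(
            X, y, k=5, seed=0, optimize_hyperparameters=False,
            init=dict(nu=4.0, sigma_n=1e-4, sigma_b=1.0),
        )
        assert rep.r2 > 0.999
        assert rep.rmse < 0.05
        assert len(folds) == 5

    def test_leave_one_out_partition(self, rng):
        X = rng.random((10, 2))
        y = rng.random(10)
        rep, folds = gpr.cross_validate(
            X, y, k=10, seed=0, optimize_hyperparameters=False,
            init=dict(nu=1.0, sigma_n=0.1, sigma_b=1.0),
        )
        assert rep.n == 10
        assert len(folds) == 0  # single-sample folds carry no fold report

    def test_too_many_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            gpr.cross_validate(rng.random((5, 2)), rng.random(5), k=6)


class TestSerialization:
    def test_roundtrip_predictions(self, tmp_path, rng):
        X = rng.uniform(0, 1, (50, 4))
        y = np.sin(3 * X[:, 0]) + rng.normal(0, 0.05, 50)
        m = gpr.fit(X, y, restarts=1, seed=0, maxiter=30,
                    band_names=("B2", "B3", "B4", "B5"))
        m.save(tmp_path / "model")
        back = gpr.GPRModel.load(tmp_path / "model")
        q = rng.uniform(0, 1, (20, 4))
        a, b = gpr.predict(m, q), gpr.predict(back, q)
        assert np.array_equal(a.mean, b.mean)
        assert np.allclose(a.variance, b.variance, atol=1e-12)
        assert back.band_names == m.band_names


class TestErrors:
    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            gpr.fit(np.zeros((1, 3)), np.zeros(1))

    def test_nonfinite_targets(self, rng):
        with pytest.raises(ValueError):
            gpr.fit(rng.random((5, 2)), np.array([1, 2, np.nan, 4, 5.0]))

    def test_query_length_mismatch(self, rng):
        m = gpr.fit(rng.random((10, 3)), rng.random(10),
                    optimize_hyperparameters=False,
                    init=dict(nu=1.0, sigma_n=0.1, sigma_b=1.0))
        with pytest.raises(ValueError):
            gpr.predict(m, np.zeros(4))


def test_metrics_r2_conventions():
    rep = gpr.regression_metrics(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]))
    assert rep.r2 == pytest.approx(1.0) and rep.rmse == 0.0
    assert rep.slope == pytest.approx(1.0) and rep.intercept == pytest.approx(0.0)
    # constant offset: perfect correlation, nonzero error
    rep = gpr.regression_metrics(np.array([2.0, 3, 4, 5]), np.array([1.0, 2, 3, 4]))
    assert rep.r2 == pytest.approx(1.0) and rep.rmse == pytest.approx(1.0)
    assert rep.r2_identity < rep.r2
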