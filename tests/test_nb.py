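"""Unit tests for the NB location-scale engine.

The fitter is checked against closed-form likelihood values, a brute-force
lattice-search oracle on tiny designs, and known invariances of the model.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

from sdvar import nb


class TestLoglik:
    def test_closed_form_value(self):
        # single zero count: loglik = (1/sigma) * ln(1/(1 + sigma*mu))
        assert nb.nb_loglik([0], [1500.0], [0.1]) == pytest.approx(10 * np.log(1 / 151), rel=1e-12)

    def test_poisson_limit(self):
        # sigma below the floor follows the Poisson branch: log P(0 | mu=1) = -1
        assert nb.nb_loglik([0], [1.0], [0.0]) == pytest.approx(-1.0, rel=1e-12)
        # and the NB value converges to it as sigma -> 0
        assert nb.nb_loglik([3], [2.5], [1e-7]) == pytest.approx(
            stats.poisson.logpmf(3, 2.5), rel=1e-5
        )

    def test_pmf_normalizes(self):
        ys = np.arange(0, 10_000)
        ll = (
            stats.nbinom.logpmf(ys, 1 / 0.3, (1 / 0.3) / (1 / 0.3 + 5.0))
        )
        ours = np.array([nb.nb_loglik([y], [5.0], [0.3]) for y in range(200)])
        assert np.allclose(ours, ll[:200], rtol=1e-10)
        total = sum(np.exp(nb.nb_loglik([y], [5.0], [0.3])) for y in range(200))
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize(
        "y,mu,sigma",
        [([-1], [1.0], [0.1]), ([1], [np.inf], [0.1]), ([1], [1.0], [np.nan])],
    )
    def test_invalid_inputs_raise(self, y, mu, sigma):
        with pytest.raises(ValueError):
            nb.nb_loglik(y, mu, sigma)


from tests._oracles import lattice_oracle as _lattice_oracle


class TestFit:
    def test_intercept_only_mean_is_sample_mean(self, rng):
        y = rng.negative_binomial(10, 0.4, size=500).astype(float)
        d = nb.NBDesign(y, np.ones((500, 1)), np.ones((500, 1)))
        f = nb.fit(d)
        assert f.converged
        assert np.exp(f.beta_mu[0]) == pytest.approx(y.mean(), rel=1e-6)

    def test_loglik_at_mle_beats_truth(self, rng):
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        bm, bs = np.array([5.0, 0.2]), np.array([-2.0, 0.4])
        mu, sig = np.exp(X @ bm), np.exp(X @ bs)
        y = rng.negative_binomial(1 / sig, 1 / (1 + sig * mu)).astype(float)
        f = nb.fit(nb.NBDesign(y, X, X))
        assert f.converged
        ll_truth = nb.nb_loglik(y, mu, sig)
        assert f.loglik >= ll_truth - 1e-6

    def test_never_beaten_by_lattice_search_tiny_designs(self, rng):
        # brute-force oracle on n <= 12 with one covariate
        for trial in range(5):
            n = int(rng.integers(8, 13))
            x = rng.normal(size=n)
            X = np.column_stack([np.ones(n), x])
            mu, sig = np.exp(3.0 + 0.5 * x), np.full(n, 0.3)
            y = rng.negative_binomial(1 / sig, 1 / (1 + sig * mu)).astype(float)
            y = np.maximum(y, np.array([1.0] + [0.0] * (n - 1)))  # avoid all-zero
            f = nb.fit(nb.NBDesign(y, X, X))
            center = np.concatenate([f.beta_mu, f.beta_sigma])
            best = _lattice_oracle(y, X, X, np.zeros(n), center)
            assert f.loglik >= best - 1e-3

    def test_offset_shift_invariance(self, rng):
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        mu = np.exp(4.0 + 0.3 * X[:, 1])
        y = rng.negative_binomial(5, 5 / (5 + mu)).astype(float)
        f0 = nb.fit(nb.NBDesign(y, X, X, offset=np.zeros(n)))
        f1 = nb.fit(nb.NBDesign(y, X, X, offset=np.full(n, 2.0)))
        assert f1.loglik == pytest.approx(f0.loglik, abs=1e-5)
        assert f1.beta_mu[0] == pytest.approx(f0.beta_mu[0] - 2.0, abs=1e-4)

    def test_nesting_monotonicity(self, rng):
        n = 150
        grp = (np.arange(n) < n // 2).astype(float)
        X = np.column_stack([np.ones(n), grp])
        X1 = np.ones((n, 1))
        y = rng.negative_binomial(8, 0.2, size=n).astype(float)
        ll_full = nb.fit(nb.NBDesign(y, X, X)).loglik
        ll_m2 = nb.fit(nb.NBDesign(y, X, X1)).loglik
        ll_m3 = nb.fit(nb.NBDesign(y, X1, X)).loglik
        assert ll_full >= ll_m2 - 1e-6
        assert ll_full >= ll_m3 - 1e-6

    def test_rank_deficient_design_raises(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            nb.NBDesign(np.ones(10), X, np.ones((10, 1)))

    def test_parameter_recovery_with_se(self, rng):
        # estimates within 3 standard errors (from observed information) of truth
        n = 10_000
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        bm, bs = np.array([6.0, 0.25]), np.array([-2.3, 0.5])
        mu, sig = np.exp(X @ bm), np.exp(X @ bs)
        y = rng.negative_binomial(1 / sig, 1 / (1 + sig * mu)).astype(float)
        f = nb.fit(nb.NBDesign(y, X, X))
        assert f.converged
        from sdvar.nb import _grad_hess, _predictors

        b = np.concatenate([f.beta_mu, f.beta_sigma])
        _, H = _grad_hess(y, *_predictors(b, X, X, np.zeros(n)), X, X)
        se = np.sqrt(np.diag(np.linalg.inv(-H)))
        assert np.all(np.abs(b - np.concatenate([bm, bs])) < 3 * se)


class TestLRT:
    def test_identical_fits_give_p_one(self):
        f = nb.NBFit(np.zeros(1), np.zeros(1), -10.0, True, 3)
        assert nb.lrt(f, f, 1) == pytest.approx(1.0)

    def test_chi2_quantile(self):
        full = nb.NBFit(np.zeros(1), np.zeros(1), -10.0, True, 3)
        red = nb.NBFit(np.zeros(1), np.zeros(1), -10.0 - 3.841 / 2, True, 3)
        assert nb.lrt(full, red, 1) == pytest.approx(0.0500, abs=1e-4)

    def test_reversed_nesting_raises(self):
        full = nb.NBFit(np.zeros(1), np.zeros(1), -20.0, True, 3)
        red = nb.NBFit(np.zeros(1), np.zeros(1), -10.0, True, 3)
        with pytest.raises(ValueError):
            nb.lrt(full, red, 1)
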