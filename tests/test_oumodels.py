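import warnings

import numpy as np
import pytest

from ouregimes import read_newick
from ouregimes.oumodels import (MODEL_NAMES, OUModelSpec, OUParams, OUFit,
                                branch_transition, simulate_traits,
                                ou_likelihood, fit_ou, fit_all_models,
                                aic_weights, theta_standard_errors, OUError,
                                _mean_cov, _single_regime_painting)
from ouregimes.tree import RegimePainting
from conftest import random_painted_tree


def _params_for(spec, R, rng=None):
    """Random but well-conditioned parameters respecting the sharing map."""
    rng = rng or np.random.default_rng(0)
    theta = rng.normal(1.0, 1.0, R if spec.theta_per_regime else 1) \
        if spec.has_alpha else None
    alpha = rng.uniform(0.5, 4.0, R if spec.alpha_per_regime else 1) \
        if spec.has_alpha else np.zeros(1)
    sigma2 = rng.uniform(0.1, 1.0, R if spec.sigma_per_regime else 1)
    root = float(theta[0]) if theta is not None else float(rng.normal())
    return OUParams(theta, alpha, sigma2, root)


class TestBranchTransition:
    def test_fixed_point_at_optimum(self):
        for t in (0.0, 0.5, 10.0):
            mean, _ = branch_transition(2.0, 2.0, 1.5, 0.3, t)
            assert mean == pytest.approx(2.0)

    def test_stationary_limit(self):
        mean, var = branch_transition(5.0, 2.0, 1.5, 0.3, 1e4)
        assert mean == pytest.approx(2.0, abs=1e-10)
        assert var == pytest.approx(0.3 / (2 * 1.5), abs=1e-10)

    def test_closed_form_variance(self):
        _, var = branch_transition(0.0, 0.0, 1.0, 2.0, np.log(2.0))
        assert var == pytest.approx(0.75, abs=1e-12)

    def test_brownian_limit_series_safe(self):
        mean, var = branch_transition(1.3, 9.9, 1e-10, 0.4, 0.7)
        assert mean == pytest.approx(1.3, abs=1e-8)
        assert var == pytest.approx(0.4 * 0.7, rel=1e-6)

    def test_negative_time_errors(self):
        with pytest.raises(OUError):
            branch_transition(0.0, 0.0, 1.0, 1.0, -0.1)


class TestSimulation:
    def test_vanishing_noise_tracks_attraction_path(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        painting = RegimePainting(np.zeros(t.n_nodes, dtype=int), ("LS",), 0)
        p = OUParams(np.array([2.0]), np.array([3.0]), np.array([1e-18]), 2.0)
        traits = simulate_traits(t, painting, OUModelSpec("OU1"), p, seed=0)
        assert all(abs(v - 2.0) < 1e-6 for v in traits.values())

    def test_bm_star_tree_moments(self):
        t = read_newick("(A:1,B:1);")
        painting = RegimePainting(np.zeros(t.n_nodes, dtype=int), ("LS",), 0)
        spec = OUModelSpec("BM1")
        p = OUParams(None, np.zeros(1), np.array([0.5]), 0.0)
        n = 100_000
        draws = np.array([
            list(simulate_traits(t, painting, spec, p, seed=s).values())
            for s in range(n)])
        var = draws.var(axis=0)
        cov = np.cov(draws.T)[0, 1]
        se_var = 0.5 * np.sqrt(2.0 / n)
        assert np.all(np.abs(var - 0.5) < 3 * se_var)
        assert abs(cov) < 3 * 0.5 / np.sqrt(n)

    def test_multi_regime_moments_match_analytic(self):
        rng = np.random.default_rng(5)
        tree, painting = random_painted_tree(rng, 4)
        spec = OUModelSpec("OUM")
        p = _params_for(spec, 3, rng)
        mean, C = _mean_cov(tree, painting, spec, p)
        n = 40_000
        draws = np.array([
            list(simulate_traits(tree, painting, spec, p, seed=s).values())
            for s in range(n)])
        emp_mean = draws.mean(axis=0)
        emp_cov = np.cov(draws.T)
        sd = np.sqrt(np.diag(C))
        # 4 s.e. bound: 14 simultaneous statistics, so a per-comparison
        # 3 s.e. band would fail by chance alone too often
        assert np.all(np.abs(emp_mean - mean) < 4 * sd / np.sqrt(n))
        # covariance entries: s.e. ~ sqrt((C_ii C_jj + C_ij^2)/n)
        se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / n)
        assert np.all(np.abs(emp_cov - C) < 4 * se)

    def test_reproducible_under_seed(self, painted_tree_200):
        tree, _, painting = painted_tree_200
        spec = OUModelSpec("OUMA")
        p = _params_for(spec, 3)
        a = simulate_traits(tree, painting, spec, p, seed=42)
        b = simulate_traits(tree, painting, spec, p, seed=42)
        assert a == b


class TestLikelihood:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_mvn_equals_belief_propagation(self, name):
        rng = np.random.default_rng(17)
        spec = OUModelSpec(name)
        for _ in range(10):
            tree, painting = random_painted_tree(
                rng, int(rng.integers(4, 17)))
            p = _params_for(spec, 3, rng)
            traits = simulate_traits(tree, painting, spec, p,
                                     seed=int(rng.integers(2**31)))
            l1 = ou_likelihood(tree, painting, spec, p, traits, method="mvn")
            l2 = ou_likelihood(tree, painting, spec, p, traits, method="bp")
            assert l1 == pytest.approx(l2, abs=1e-8)

    def test_bm_limit_of_ou(self):
        rng = np.random.default_rng(3)
        tree, painting = random_painted_tree(rng, 8)
        traits = {lab: float(rng.normal()) for lab in tree.tip_labels}
        mu, s2 = 0.3, 0.7
        l_bm = ou_likelihood(tree, painting, OUModelSpec("BM1"),
                             OUParams(None, np.zeros(1), np.array([s2]), mu),
                             traits)
        l_ou = ou_likelihood(tree, painting, OUModelSpec("OU1"),
                             OUParams(np.array([mu]), np.array([1e-9]),
                                      np.array([s2]), mu), traits)
        assert l_ou == pytest.approx(l_bm, abs=1e-5)

    def test_two_tip_star_closed_form(self):
        t = read_newick("(A:1,B:1);")
        painting = RegimePainting(np.zeros(t.n_nodes, dtype=int), ("x",), 0)
        th, a, s2 = 1.0, 2.0, 0.5
        p = OUParams(np.array([th]), np.array([a]), np.array([s2]), th)
        traits = {"A": 1.4, "B": 0.8}
        v = s2 * (1 - np.exp(-2 * a)) / (2 * a)
        expected = sum(
            -0.5 * (np.log(2 * np.pi * v) + (y - th) ** 2 / v)
            for y in traits.values())
        got = ou_likelihood(t, painting, OUModelSpec("OU1"), p, traits)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        tree, painting = random_painted_tree(rng, 10)
        spec = OUModelSpec("OUM")
        p = _params_for(spec, 3, rng)
        traits = simulate_traits(tree, painting, spec, p, seed=1)
        l0 = ou_likelihood(tree, painting, spec, p, traits)
        c = 3.7
        p2 = OUParams(p.theta + c, p.alpha, p.sigma2, p.root_value + c)
        traits2 = {k: v + c for k, v in traits.items()}
        assert ou_likelihood(tree, painting, spec, p2, traits2) == \
            pytest.approx(l0, abs=1e-9)


class TestFitting:
    def test_bm1_matches_closed_form(self, painted_tree_200):
        tree, _, painting = painted_tree_200
        rng = np.random.default_rng(2)
        spec = OUModelSpec("BM1")
        p = OUParams(None, np.zeros(1), np.array([0.3]), 1.0)
        traits = simulate_traits(tree, painting, spec, p, seed=6)
        fit = fit_ou(tree, painting, "BM1", traits, seed=0)
        # closed form: GLS mean and sigma2 = r' C^-1 r / n
        d = tree.depths()
        M = tree.mrca_matrix()
        C = d[M]
        y = np.array([traits[lab] for lab in tree.tip_labels])
        Ci = np.linalg.inv(C)
        one = np.ones_like(y)
        mu = float(one @ Ci @ y / (one @ Ci @ one))
        r = y - mu
        s2 = float(r @ Ci @ r / y.size)
        assert fit.theta is None
        assert fit.root_value == pytest.approx(mu, abs=1e-8)
        assert fit.sigma2[0] == pytest.approx(s2, rel=1e-6)
        assert fit.n_params == 2

    def test_oum_recovery_and_se(self, painted_tree_200):
        tree, _, painting = painted_tree_200
        theta = np.log10([597.0, 210.0, 51.09])
        p = OUParams(theta, np.array([3.0]), np.array([0.05]), theta[0])
        traits = simulate_traits(tree, painting, OUModelSpec("OUM"), p, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_ou(tree, painting, "OUM", traits, n_starts=4, seed=0)
        se = theta_standard_errors(tree, painting, fit, traits)
        assert se is not None and np.all(se > 0) and np.all(np.isfinite(se))
        # estimates should sit within a few standard errors of truth (the
        # rarest regime covers only a handful of tips, so se does the scaling)
        assert np.all(np.abs(fit.theta - theta) < 4 * np.maximum(se, 0.02))
        assert fit.theta[0] > fit.theta[1] > fit.theta[2]

    def test_model_nesting_loglik_order(self, painted_tree_200):
        tree, _, painting = painted_tree_200
        theta = np.log10([597.0, 210.0, 51.09])
        p = OUParams(theta, np.array([3.0]), np.array([0.05]), theta[0])
        traits = simulate_traits(tree, painting, OUModelSpec("OUM"), p, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = {n: fit_ou(tree, painting, n, traits, n_starts=3, seed=1)
                    for n in ("OU1", "OUM", "OUMA", "OUMVA")}
        tol = 1e-4
        assert fits["OUMVA"].lnL >= fits["OUMA"].lnL - tol
        assert fits["OUMA"].lnL >= fits["OUM"].lnL - tol
        assert fits["OUM"].lnL >= fits["OU1"].lnL - tol

    def test_param_counts_all_models(self, painted_tree_200):
        expected = {"BM1": 2, "BMS": 4, "OU1": 3, "OUM": 5, "OUMV": 7,
                    "OUMA": 7, "OUMVA": 9}
        for name, p in expected.items():
            assert OUModelSpec(name).n_params(3) == p
            assert OUModelSpec(name, root="free").n_params(3) == p + 1

    def test_degenerate_trait_variance_errors(self, painted_tree_200):
        tree, _, painting = painted_tree_200
        traits = {lab: 1.0 for lab in tree.tip_labels}
        with pytest.raises(OUError, match="variance"):
            fit_ou(tree, painting, "OUM", traits)


class TestAICWeights:
    def _fit_like(self, aic, n=100, p=2):
        lnL = p - aic / 2.0
        return OUFit(OUModelSpec("OU1"), ("all",), np.array([0.0]),
                     np.array([1.0]), np.array([1.0]), 0.0, lnL, p, n,
                     True, [], _data_key=(n, 0.0, 1.0))

    def test_closed_form_pair(self):
        fits = [self._fit_like(10.0), self._fit_like(12.0)]
        w = aic_weights(fits, criterion="AIC")
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_aics_equal_weights(self):
        fits = [self._fit_like(5.0) for _ in range(4)]
        w = aic_weights(fits, criterion="AIC")
        assert np.allclose(w, 0.25, atol=1e-12)

    def test_mismatched_data_rejected(self):
        a = self._fit_like(10.0)
        b = self._fit_like(10.0)
        b._data_key = (50, 1.0, 2.0)
        with pytest.raises(OUError, match="different data"):
            aic_weights([a, b])

    def test_aicc_at_least_aic(self, painted_tree_200):
        tree, _, painting = painted_tree_200
        p = OUParams(np.array([1.0, 2.0, 0.5]), np.array([2.0]),
                     np.array([0.3]), 1.0)
        traits = simulate_traits(tree, painting, OUModelSpec("OUM"), p, seed=3)
        fit = fit_ou(tree, painting, "OUM", traits, n_starts=2, seed=0)
        assert fit.aicc >= fit.aic
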