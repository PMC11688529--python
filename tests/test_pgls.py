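import warnings

import numpy as np
import pytest

from ouregimes import read_newick
from ouregimes.pgls import (error_covariance, fit_pgls, select_error_model,
                            PGLSError, _profile_lnl)
from ouregimes.oumodels import OUModelSpec, OUParams, fit_ou, simulate_traits
from ouregimes.tree import RegimePainting
from ouregimes.synth import simulate_yule_tree, simulate_regime_history


def _star_tree(n, depth=1.0):
    inner = ",".join(f"s{i}:{depth}" for i in range(n))
    return read_newick(f"({inner});")


class TestErrorCovariance:
    def test_bm_is_shared_path_length(self, three_tip_tree):
        V = error_covariance(three_tip_tree, "BM")
        labs = three_tip_tree.tip_labels
        i, j, k = labs.index("A"), labs.index("B"), labs.index("C")
        assert V[i, j] == pytest.approx(1.0)
        assert V[i, k] == pytest.approx(0.0)
        assert V[i, i] == pytest.approx(2.0)

    def test_ou_fixed_root_bm_limit(self, three_tip_tree):
        V_ou = error_covariance(three_tip_tree, "OUfixedRoot", alpha=1e-9)
        V_bm = error_covariance(three_tip_tree, "BM")
        assert np.allclose(V_ou, V_bm, atol=1e-6)

    def test_root_divergence_uncorrelated(self, three_tip_tree):
        V = error_covariance(three_tip_tree, "OUfixedRoot", alpha=1.0)
        labs = three_tip_tree.tip_labels
        i, k = labs.index("A"), labs.index("C")
        assert V[i, k] == pytest.approx(0.0, abs=1e-15)

    def test_three_tip_closed_form(self, three_tip_tree):
        V = error_covariance(three_tip_tree, "OUfixedRoot", alpha=1.0)
        labs = three_tip_tree.tip_labels
        i, j = labs.index("A"), labs.index("B")
        assert V[i, j] == pytest.approx(
            np.exp(-2.0) * (1 - np.exp(-2.0)) / 2.0, abs=1e-12)

    def test_random_root_stationary_diagonal(self, three_tip_tree):
        V = error_covariance(three_tip_tree, "OUrandomRoot", alpha=2.0)
        assert np.allclose(np.diag(V), 1.0 / 4.0)

    def test_invalid_alpha_errors(self, three_tip_tree):
        with pytest.raises(PGLSError):
            error_covariance(three_tip_tree, "OUfixedRoot", alpha=0.0)


class TestFit:
    def test_star_tree_equals_ols(self):
        t = _star_tree(30)
        rng = np.random.default_rng(0)
        states = {lab: ("LS", "CC", "CS")[i % 3]
                  for i, lab in enumerate(t.tip_labels)}
        traits = {lab: {"LS": 2.8, "CC": 2.4, "CS": 2.1}[states[lab]]
                  + rng.normal(0, 0.2) for lab in t.tip_labels}
        fit = fit_pgls(t, traits, states, error_model="BM")
        y = np.array([traits[s] for s in t.tip_labels])
        X = np.ones((30, 3))
        X[:, 1] = [states[s] == "CC" for s in t.tip_labels]
        X[:, 2] = [states[s] == "CS" for s in t.tip_labels]
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, beta_ols, atol=1e-10)
        assert fit.terms[0] == "COX_LS (intercept)"

    def test_reference_level_is_ls_group_mean(self):
        t = _star_tree(12)
        states = {lab: ("LS", "CC")[i % 2]
                  for i, lab in enumerate(t.tip_labels)}
        rng = np.random.default_rng(2)
        traits = {lab: (3.0 if states[lab] == "LS" else 2.0)
                  + rng.normal(0, 0.05) for lab in t.tip_labels}
        fit = fit_pgls(t, traits, states, error_model="BM")
        mean_ls = np.mean([traits[s] for s in t.tip_labels
                           if states[s] == "LS"])
        mean_cc = np.mean([traits[s] for s in t.tip_labels
                           if states[s] == "CC"])
        assert fit.beta[0] == pytest.approx(mean_ls, abs=1e-9)
        assert fit.beta[1] == pytest.approx(mean_cc - mean_ls, abs=1e-9)

    def test_single_level_refused(self):
        t = _star_tree(10)
        states = {lab: "LS" for lab in t.tip_labels}
        traits = {lab: float(i) for i, lab in enumerate(t.tip_labels)}
        with pytest.raises(PGLSError, match="level"):
            fit_pgls(t, traits, states)

    def test_adjusted_r2_conventions(self):
        t = _star_tree(20)
        rng = np.random.default_rng(4)
        states = {lab: ("LS", "CC")[i % 2]
                  for i, lab in enumerate(t.tip_labels)}
        traits = {lab: (2.5 if states[lab] == "LS" else 2.0)
                  + rng.normal(0, 0.3) for lab in t.tip_labels}
        fit = fit_pgls(t, traits, states, error_model="BM")
        n, k = fit.n, len(fit.beta)
        assert fit.r2_adj == pytest.approx(
            1 - (1 - fit.r2) * (n - 1) / (n - k))
        assert fit.r2_adj_alt == pytest.approx(
            1 - (1 - fit.r2) * (n - 1) / (n - k - 1))
        assert fit.r2_adj_alt <= fit.r2_adj <= fit.r2 <= 1.0

    def test_pvalues_in_unit_interval_and_df(self):
        t = simulate_yule_tree(40, seed=1)
        rng = np.random.default_rng(7)
        states = {lab: ("LS", "CC", "CS")[int(rng.integers(3))]
                  for lab in t.tip_labels}
        traits = {lab: float(rng.normal(2.5, 0.3)) for lab in t.tip_labels}
        fit = fit_pgls(t, traits, states, error_model="OUfixedRoot")
        assert np.all((fit.pvals >= 0) & (fit.pvals <= 1))
        assert fit.n_params == 3 + 2


class TestEquivalenceWithOU1:
    def test_intercept_only_pgls_matches_ou1_trait_model(self):
        """The OUfixedRoot residual kernel with an intercept-only design is
        exactly the single-optimum, tied-root OU trait model, so the two
        maximised log-likelihoods must coincide."""
        tree = simulate_yule_tree(40, seed=5)
        painting = RegimePainting(np.zeros(tree.n_nodes, dtype=int),
                                  ("all",), 0)
        p = OUParams(np.array([2.0]), np.array([1.5]), np.array([0.3]), 2.0)
        traits = simulate_traits(tree, painting, OUModelSpec("OU1"), p, seed=2)
        fit = fit_ou(tree, painting, "OU1", traits, seed=0)
        y = np.array([traits[lab] for lab in tree.tip_labels])
        X = np.ones((y.size, 1))

        def pgls_lnl(alpha):
            V0 = error_covariance(tree, "OUfixedRoot", alpha=alpha)
            return _profile_lnl(y, X, V0)[0]

        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda la: -pgls_lnl(np.exp(la)),
                              bounds=(np.log(1e-6), np.log(50.0)),
                              method="bounded")
        assert -res.fun == pytest.approx(fit.lnL, abs=1e-6)


class TestErrorModelSelection:
    def test_weights_sum_to_one_and_ranking_shift_invariant(self):
        tree = simulate_yule_tree(60, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, painting = simulate_regime_history(tree, 0.6, seed=3)
        states = {tree.labels[t]: painting.label_of(t) for t in tree.tips}
        rng = np.random.default_rng(13)
        traits = {lab: float(rng.normal(2.5, 0.4)) for lab in tree.tip_labels}
        fits, notes = select_error_model(tree, traits, states)
        w = [f.aic_weight for f in fits]
        assert sum(w) == pytest.approx(1.0, abs=1e-12)
        # each model's AIC is invariant to a unit shift of the trait
        # (rank order can flip only between numerically tied models)
        shifted = {k: v + 5.0 for k, v in traits.items()}
        fits2, _ = select_error_model(tree, shifted, states)
        a1 = {f.error_model: f.aic for f in fits}
        a2 = {f.error_model: f.aic for f in fits2}
        for m in a1:
            assert a2[m] == pytest.approx(a1[m], abs=1e-4)

    def test_duplicate_candidates_share_weight(self):
        t = _star_tree(12)
        states = {lab: ("LS", "CC")[i % 2]
                  for i, lab in enumerate(t.tip_labels)}
        rng = np.random.default_rng(3)
        traits = {lab: float(rng.normal()) for lab in t.tip_labels}
        fits, _ = select_error_model(t, traits, states,
                                     candidates=("BM", "BM"))
        assert fits[0].aic_weight == pytest.approx(0.5, abs=1e-12)

    def test_bm_truth_usually_ranked_first(self):
        """Residuals simulated under BM: the BM error structure should win
        the AIC comparison in a clear majority of replicates."""
        tree = simulate_yule_tree(120, seed=21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, painting = simulate_regime_history(tree, 0.5, seed=4)
        states = {tree.labels[t]: painting.label_of(t) for t in tree.tips}
        spec = OUModelSpec("BM1")
        wins = 0
        n_rep = 30
        for r in range(n_rep):
            p = OUParams(None, np.zeros(1), np.array([0.4]), 2.5)
            traits = simulate_traits(tree, painting, spec, p, seed=100 + r)
            fits, _ = select_error_model(tree, traits, states)
            wins += fits[0].error_model == "BM"
        assert wins / n_rep > 0.6
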