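import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from spinetrait.pgls import (
    ChainSettings,
    RegressionData,
    RegressionParams,
    RegressionPosterior,
    bm_ancestral_continuous,
    fit_mcmc,
    fit_ml,
    gls_loglik,
    phylo_ttest_summary,
)
from spinetrait.synthetic_data import SimulationSpec, simulate_bm_regression, simulate_yule, sub_rng
from spinetrait.treeio import read_tree, vcv_matrix

from conftest import random_tree


def _data(y, z, taxa):
    X = np.column_stack([np.ones(len(y)), np.asarray(z, float)])
    return RegressionData(np.asarray(y, float), X, list(taxa))


class TestGlsLoglik:
    def test_two_standard_normals(self):
        data = _data([0.0, 0.0], [0, 1], ["A", "B"])
        ll = gls_loglik(data, np.eye(2), RegressionParams(0.0, 0.0, 1.0))
        assert ll == pytest.approx(-math.log(2 * math.pi), abs=1e-12)

    def test_matches_dense_mvn_oracle(self, three_taxon_tree):
        rng = np.random.default_rng(1)
        C = vcv_matrix(three_taxon_tree)
        for _ in range(10):
            y = rng.normal(size=3)
            b1, b2, s2 = rng.normal(), rng.normal(), rng.uniform(0.2, 3)
            data = _data(y, [0, 1, 0], C.taxa)
            mean = data.X @ [b1, b2]
            oracle = stats.multivariate_normal.logpdf(y, mean, s2 * C.matrix)
            assert gls_loglik(data, C, RegressionParams(b1, b2, s2)) == pytest.approx(
                oracle, abs=1e-10
            )

    def test_translation_invariance(self, three_taxon_tree):
        C = vcv_matrix(three_taxon_tree)
        y = np.array([1.0, 2.0, 3.0])
        data1 = _data(y, [0, 1, 0], C.taxa)
        data2 = _data(y + 5.0, [0, 1, 0], C.taxa)
        p1 = RegressionParams(0.5, 1.0, 0.8)
        p2 = RegressionParams(5.5, 1.0, 0.8)
        assert gls_loglik(data1, C, p1) == pytest.approx(
            gls_loglik(data2, C, p2), abs=1e-12
        )

    def test_predictor_without_contrast_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            _data([1.0, 2.0], [1, 1], ["A", "B"])


class TestFitMl:
    def test_star_tree_reduces_to_ols(self):
        # equal tip depths, no shared history -> GLS == OLS
        tree = read_tree("(A:1,B:1,C:1,D:1,E:1,F:1);")
        rng = np.random.default_rng(2)
        y = rng.normal(size=6)
        z = np.array([0, 0, 0, 1, 1, 1.0])
        params, _, _ = fit_ml(_data(y, z, tree.tip_labels), tree)
        X = np.column_stack([np.ones(6), z])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert params.beta1 == pytest.approx(beta_ols[0], abs=1e-8)
        assert params.beta2 == pytest.approx(beta_ols[1], abs=1e-8)

    def test_zero_residual_flagged_degenerate(self):
        tree = read_tree("(A:1,B:1,C:1,D:1);")
        z = np.array([0, 0, 1, 1.0])
        y = 2.0 + 0.5 * z  # exactly X beta
        params, _, _ = fit_ml(_data(y, z, tree.tip_labels), tree)
        from spinetrait.pgls import DEGENERATE_SIGMA2

        assert params.sigma2 == DEGENERATE_SIGMA2
        assert params.beta1 == pytest.approx(2.0, abs=1e-8)
        assert params.beta2 == pytest.approx(0.5, abs=1e-8)

    def test_too_few_taxa_rejected(self):
        tree = read_tree("(A:1,B:1);")
        from spinetrait.pgls import FitError

        with pytest.raises(FitError):
            fit_ml(_data([1.0, 2.0], [0, 1], tree.tip_labels), tree)

    def test_ml_beats_grid_of_alternatives(self):
        rng = np.random.default_rng(3)
        tree = random_tree(rng, 12)
        spec = SimulationSpec(n_tips=12, lam=0.7, kappa=1.0, delta=1.0, seed=9)
        y, z = simulate_bm_regression(tree, spec, rng)
        data = _data(y, z, tree.tip_labels)
        _, tp, ll = fit_ml(data, tree, {"lambda"})
        from spinetrait.transforms import TransformParams, transform_covariance

        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            C = transform_covariance(tree, TransformParams(lam=lam))
            beta, s2, ll_alt, _ = _profile(C.matrix, data)
            assert ll >= ll_alt - 1e-8

    def test_slope_recovery_on_simulated_data(self):
        """Mean ML slope over replicates sits near the generating value."""
        est = []
        for rep in range(20):
            tree = simulate_yule(200, seed=sub_rng(100 + rep, "tree"))
            spec = SimulationSpec(n_tips=200, lam=0.88, kappa=1.0, seed=100 + rep)
            y, z = simulate_bm_regression(tree, spec)
            params, _, _ = fit_ml(_data(y, z, tree.tip_labels), tree, {"lambda"})
            est.append(params.beta2)
        assert abs(np.mean(est) - 0.88) < 0.15


def _profile(C, data):
    from spinetrait.pgls import _profile_ll

    return _profile_ll(C, data.X, data.y)


class TestFitMcmc:
    def test_same_seed_identical_samples(self):
        tree = simulate_yule(15, seed=5)
        spec = SimulationSpec(n_tips=15, seed=5)
        y, z = simulate_bm_regression(tree, spec)
        data = _data(y, z, tree.tip_labels)
        s = ChainSettings(2000, 500, 5)
        a = fit_mcmc(data, tree, {"lambda"}, s, seed=11)
        b = fit_mcmc(data, tree, {"lambda"}, s, seed=11)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        assert a.samples.to_csv() == b.samples.to_csv()

    def test_sample_count_matches_settings(self):
        tree = simulate_yule(10, seed=6)
        spec = SimulationSpec(n_tips=10, seed=6)
        y, z = simulate_bm_regression(tree, spec)
        post = fit_mcmc(
            _data(y, z, tree.tip_labels), tree, set(),
            ChainSettings(3000, 1000, 7), seed=2,
        )
        assert len(post) == (3000 - 1000) // 7
        assert np.all(np.isfinite(post.samples["loglik"]))

    def test_flat_likelihood_recovers_prior(self):
        """With sigma^2 pinned huge and constant y the likelihood is flat in
        beta2, so its posterior must reproduce the N(0, 10) prior."""
        tree = simulate_yule(20, seed=1)
        z = np.zeros(20)
        z[:5] = 1
        data = _data(np.zeros(20), z, tree.tip_labels)
        post = fit_mcmc(
            data, tree, set(), ChainSettings(45_000, 5_000, 10), seed=3,
            fixed={"sigma2": 1e8},
        )
        ks = stats.kstest(post.samples["beta2"], stats.norm(0, 10).cdf)
        assert ks.statistic < 0.05

    def test_posterior_means_approach_ml_at_large_n(self):
        tree = simulate_yule(200, seed=21)
        spec = SimulationSpec(n_tips=200, lam=0.88, kappa=1.0, seed=21)
        y, z = simulate_bm_regression(tree, spec)
        data = _data(y, z, tree.tip_labels)
        params_ml, tp_ml, _ = fit_ml(data, tree, {"lambda"})
        post = fit_mcmc(data, tree, {"lambda"}, ChainSettings(20_000, 4_000, 8), seed=22)
        s = post.samples
        assert s["beta2"].mean() == pytest.approx(params_ml.beta2, abs=0.15)
        assert s["beta1"].mean() == pytest.approx(params_ml.beta1, abs=0.2)
        assert s["lambda"].mean() == pytest.approx(tp_ml.lam, abs=0.1)


class TestSummary:
    def _post(self, beta2_values):
        n = len(beta2_values)
        df = pd.DataFrame(
            {
                "beta1": np.zeros(n),
                "beta2": beta2_values,
                "sigma2": np.ones(n),
                "lambda": np.ones(n),
                "delta": np.ones(n),
                "kappa": np.ones(n),
                "loglik": np.zeros(n),
            }
        )
        return RegressionPosterior(df, ChainSettings(10, 0, 1), 0, frozenset(), {})

    def test_all_positive_slope_samples(self):
        s = phylo_ttest_summary(self._post([1.0, 2.0, 3.0]))
        assert s["prop_beta2_gt0"] == 1.0
        assert s["two_sided_tail"] == 0.0

    def test_balanced_slope_samples(self):
        s = phylo_ttest_summary(self._post([-1.0, 1.0]))
        assert s["prop_beta2_gt0"] == 0.5
        assert s["two_sided_tail"] == 1.0

    def test_empty_posterior_rejected(self):
        with pytest.raises(ValueError):
            phylo_ttest_summary(self._post([]))


class TestBmAncestral:
    def test_two_tips_equal_branches_root_is_mean(self):
        tree = read_tree("(A:1,B:1);")
        out = bm_ancestral_continuous(tree, {"A": 2.0, "B": 6.0})
        assert out.loc[out.node == tree.root, "estimate"].iloc[0] == pytest.approx(4.0)

    def test_star_tree_root_is_arithmetic_mean(self):
        tree = read_tree("(A:1,B:1,C:1,D:1);")
        y = np.array([1.0, 2.0, 3.0, 10.0])
        out = bm_ancestral_continuous(tree, y)
        assert out["estimate"].iloc[0] == pytest.approx(y.mean())

    def test_matches_numeric_joint_ml_oracle(self):
        """Internal-node estimates equal the joint maximizer of the BM
        likelihood over internal values, found by direct optimization of the
        sum of squared contrasts weighted by branch lengths."""
        rng = np.random.default_rng(4)
        tree = random_tree(rng, 5, ultrametric=False)
        y = rng.normal(size=5)
        est = bm_ancestral_continuous(tree, y)
        internals = est["node"].to_numpy()

        def neg_joint(x):
            vals = np.empty(tree.n_nodes)
            vals[:5] = y
            vals[internals] = x
            s = 0.0
            for v in range(tree.n_nodes):
                if v == tree.root:
                    continue
                b = tree.lengths[v]
                if b <= 0:
                    continue
                s += (vals[v] - vals[tree.parent[v]]) ** 2 / b
            return s

        res = optimize.minimize(neg_joint, np.zeros(len(internals)), method="BFGS",
                                options={"gtol": 1e-12})
        np.testing.assert_allclose(est["estimate"].to_numpy(), res.x, atol=1e-6)
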