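import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinetrait.mk_ancestral import (
    MkModel,
    ancestral_report,
    node_marginals,
    prune_likelihood,
    rjmcmc_ancestral,
    transition_matrix,
)
from spinetrait.pgls import ChainSettings
from spinetrait.treeio import read_tree

from conftest import enum_node_marginals, enum_prune_likelihood, random_tree


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        np.testing.assert_allclose(transition_matrix(MkModel(0.7, 2.0), 0.0), np.eye(2))

    def test_stationary_limit_symmetric_rates(self):
        P = transition_matrix(MkModel(1.0, 1.0), 50.0)
        np.testing.assert_allclose(P, 0.25 + 0.25 * np.ones((2, 2)), atol=1e-12)

    def test_closed_form_reference_point(self):
        # q01 = q10 = 1, t = ln(2)/2: e^{-2t} = 1/2, P00 = (1 + 1/2)/2 = 0.75
        P = transition_matrix(MkModel(1.0, 1.0), math.log(2) / 2)
        assert P[0, 0] == pytest.approx(0.75, abs=1e-12)

    def test_both_rates_zero_rejected(self):
        with pytest.raises(ValueError):
            MkModel(0.0, 0.0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        q01=st.floats(0.0, 50.0),
        q10=st.floats(1e-6, 50.0),
        t=st.floats(0.0, 100.0),
    )
    def test_rows_are_stochastic(self, q01, q10, t):
        P = transition_matrix(MkModel(q01, q10), t)
        assert np.all(P >= -1e-12)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestPruneLikelihood:
    def test_long_branch_independence_limit(self):
        # two tips, both state 0, symmetric rates, very long branches,
        # uniform root: P = sum_root 0.5 * 0.5 * 0.5 = 0.25
        tree = read_tree("(A:200,B:200);")
        lik = prune_likelihood(tree, {"A": 0, "B": 0}, MkModel(1, 1, root="uniform"))
        assert lik == pytest.approx(0.25, abs=1e-9)

    def test_matches_enumeration_on_random_trees(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(3, 7))
            tree = random_tree(rng, n, ultrametric=False)
            tips = {t: int(rng.integers(2)) for t in tree.tip_labels}
            model = MkModel(rng.uniform(0.05, 3), rng.uniform(0.05, 3))
            got = prune_likelihood(tree, tips, model)
            want = enum_prune_likelihood(tree, tips, model)
            assert got == pytest.approx(want, abs=1e-12)

    def test_zero_length_branch_equals_fused_tree(self):
        # (A:0, B:1) cherry with zero stem on A acts like A sits at its parent
        tree = read_tree("((A:0.0,B:1):1,C:2);")
        fused = read_tree("((A:0.000001,B:1):1,C:2);")  # nearly fused reference
        model = MkModel(0.8, 1.3)
        tips = {"A": 1, "B": 0, "C": 0}
        exact = enum_prune_likelihood(tree, tips, model)
        assert prune_likelihood(tree, tips, model) == pytest.approx(exact, abs=1e-12)
        assert prune_likelihood(fused, tips, model) == pytest.approx(exact, rel=1e-4)

    def test_invariant_to_child_order(self):
        a = read_tree("((A:0.3,B:0.6):0.5,(C:0.2,D:0.8):0.4);")
        b = read_tree("((D:0.8,C:0.2):0.4,(B:0.6,A:0.3):0.5);")
        model = MkModel(0.5, 1.5)
        tips = {"A": 0, "B": 1, "C": 1, "D": 0}
        assert prune_likelihood(a, tips, model) == pytest.approx(
            prune_likelihood(b, tips, model), abs=1e-15
        )

    def test_missing_tip_state_names_taxa(self, three_taxon_tree):
        with pytest.raises(ValueError, match="C"):
            prune_likelihood(three_taxon_tree, {"A": 0, "B": 1}, MkModel(1, 1))


class TestNodeMarginals:
    def test_rows_normalized_and_match_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            tree = random_tree(rng, n, ultrametric=False)
            tips = {t: int(rng.integers(2)) for t in tree.tip_labels}
            model = MkModel(rng.uniform(0.05, 3), rng.uniform(0.05, 3))
            M = node_marginals(tree, tips, model)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
            want = enum_node_marginals(tree, tips, model)
            np.testing.assert_allclose(
                M[tree.n_tips :], want[tree.n_tips :], atol=1e-10
            )


class TestRjmcmc:
    def test_fixed_rates_reproduce_exact_marginals(self, balanced_four_tip):
        tips = {"A": 0, "B": 0, "C": 1, "D": 1}
        model = MkModel(0.7, 1.1)
        post = rjmcmc_ancestral(
            balanced_four_tip, tips, ChainSettings(3000, 1000, 2), seed=3,
            fixed_rates=(0.7, 1.1),
        )
        exact = enum_node_marginals(balanced_four_tip, tips, model)
        for _, row in post.node_probs.iterrows():
            assert row["p0"] == pytest.approx(exact[int(row["node"]), 0], abs=1e-10)

    def test_symmetric_configuration_root_is_half(self, balanced_four_tip):
        # one tip of each state in each cherry: exact 0/1 symmetry
        tips = {"A": 0, "B": 1, "C": 1, "D": 0}
        post = rjmcmc_ancestral(
            balanced_four_tip, tips, ChainSettings(10_000, 2_000, 2), seed=5
        )
        root_row = post.node_probs[post.node_probs.node == balanced_four_tip.root]
        assert root_row["p0"].iloc[0] == pytest.approx(0.5, abs=0.03)

    def test_monomorphic_tips_warn_and_support_that_state(self, caplog):
        tree = read_tree("((A:0.2,B:0.2):0.3,(C:0.2,D:0.2):0.3);")
        tips = {t: 0 for t in "ABCD"}
        import logging

        with caplog.at_level(logging.WARNING, logger="spinetrait.mk_ancestral"):
            post = rjmcmc_ancestral(tree, tips, ChainSettings(6000, 1000, 5), seed=6)
        assert "weakly identified" in caplog.text
        assert (post.node_probs["p0"] > 0.9).all()

    def test_seed_determinism(self, balanced_four_tip):
        tips = {"A": 0, "B": 0, "C": 1, "D": 1}
        s = ChainSettings(2000, 500, 5)
        a = rjmcmc_ancestral(balanced_four_tip, tips, s, seed=7)
        b = rjmcmc_ancestral(balanced_four_tip, tips, s, seed=7)
        assert a.samples.equals(b.samples)
        assert a.node_probs.equals(b.node_probs)

    def test_two_rate_posterior_matches_grid_oracle(self):
        """RJ disabled (two-rate model only): the MCMC rate posterior agrees
        with numerical integration over a (q01, q10, hyperprior-mean) grid."""
        tree = read_tree("((A:0.3,B:0.3):0.7,(C:0.5,D:0.5):0.5);")
        tips = {"A": 0, "B": 0, "C": 1, "D": 1}
        post = rjmcmc_ancestral(
            tree, tips, ChainSettings(60_000, 10_000, 5), seed=4, rj=False
        )
        from spinetrait.mk_ancestral import log_prune_likelihood

        qgrid = np.exp(np.linspace(np.log(1e-3), np.log(60), 100))
        mgrid = np.linspace(0.05, 10, 50)
        W = np.zeros((len(qgrid), len(qgrid)))
        for i, q1 in enumerate(qgrid):
            for j, q2 in enumerate(qgrid):
                L = math.exp(log_prune_likelihood(tree, tips, MkModel(q1, q2)))
                prior_m = np.trapezoid(
                    np.exp(-(q1 + q2) / mgrid) / mgrid**2, mgrid
                ) / 10.0
                W[i, j] = L * prior_m
        dl = np.log(qgrid[1]) - np.log(qgrid[0])
        mass = W * np.outer(qgrid, qgrid) * dl * dl
        mass /= mass.sum()
        edges = np.exp(np.linspace(np.log(1e-3), np.log(60), 13))
        oracle = np.array(
            [
                mass[(qgrid >= lo) & (qgrid < hi), :].sum()
                for lo, hi in zip(edges[:-1], edges[1:])
            ]
        )
        h, _ = np.histogram(post.samples["q01"], bins=edges)
        assert h.sum() >= 0.999 * len(post)
        tv = 0.5 * np.abs(oracle - h / h.sum()).sum()
        assert tv < 0.05

    def test_requires_three_tips_and_seed(self):
        tree = read_tree("(A:1,B:1);")
        with pytest.raises(ValueError):
            rjmcmc_ancestral(tree, {"A": 0, "B": 1}, ChainSettings(100, 10, 1), seed=1)
        t3 = read_tree("(A:1,(B:0.5,C:0.5):0.5);")
        with pytest.raises(ValueError, match="seed"):
            rjmcmc_ancestral(t3, {"A": 0, "B": 1, "C": 0}, ChainSettings(100, 10, 1))


class TestAncestralReport:
    def _post(self, balanced_four_tip, tips, seed=9):
        return rjmcmc_ancestral(
            balanced_four_tip, tips, ChainSettings(4000, 1000, 5), seed=seed
        )

    def test_rows_sum_to_one_and_flags(self, balanced_four_tip):
        post = self._post(balanced_four_tip, {"A": 0, "B": 0, "C": 0, "D": 1})
        rep = ancestral_report(post, balanced_four_tip)
        np.testing.assert_allclose(rep["p0"] + rep["p1"], 1.0, atol=1e-9)
        assert set(rep.columns) >= {"node", "fingerprint", "p0", "p1", "supported"}
        # flags follow the 0.95 threshold exactly
        np.testing.assert_array_equal(
            rep["supported"], rep[["p0", "p1"]].max(axis=1) >= 0.95
        )

    def test_threshold_configurable(self, balanced_four_tip):
        post = self._post(balanced_four_tip, {"A": 0, "B": 0, "C": 0, "D": 1})
        rep = ancestral_report(post, balanced_four_tip, threshold=0.5)
        assert rep["supported"].all()

    def test_fingerprints_are_descendant_tip_sets(self, balanced_four_tip):
        post = self._post(balanced_four_tip, {"A": 0, "B": 0, "C": 1, "D": 1})
        rep = ancestral_report(post, balanced_four_tip)
        assert "A|B" in set(rep["fingerprint"])
        assert "A|B|C|D" in set(rep["fingerprint"])
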