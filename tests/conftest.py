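import itertools

import numpy as np
import pytest

from spinetrait.mk_ancestral import MkModel, transition_matrix
from spinetrait.synthetic_data import simulate_yule
from spinetrait.treeio import Phylogeny, read_tree


@pytest.fixture
def three_taxon_tree() -> Phylogeny:
    return read_tree("(A:1,(B:0.5,C:0.5):0.5);")


@pytest.fixture
def balanced_four_tip() -> Phylogeny:
    return read_tree("((A:0.3,B:0.3):0.7,(C:0.3,D:0.3):0.7);")


def random_tree(rng: np.random.Generator, n_tips: int, ultrametric: bool = True) -> Phylogeny:
    """Random Yule tree; non-ultrametric variants jitter each branch length."""
    tree = simulate_yule(
        n_tips, seed=rng, scale_to_depth=1.0 if ultrametric else None
    )
    if not ultrametric:
        factors = rng.uniform(0.3, 2.0, size=tree.n_nodes)
        lengths = tree.lengths * factors
        lengths[tree.root] = 0.0
        tree = tree.copy_with_lengths(lengths)
    return tree


def enum_prune_likelihood(tree: Phylogeny, tip_states: dict, model: MkModel) -> float:
    """Brute-force Mk likelihood: sum over all internal-state assignments of
    the product of edge transition probabilities times the root prior."""
    states = np.zeros(tree.n_nodes, dtype=int)
    for i, lbl in enumerate(tree.tip_labels):
        states[i] = tip_states[lbl]
    internals = [v for v in range(tree.n_tips, tree.n_nodes)]
    pi = model.root_prior()
    P = {v: transition_matrix(model, float(tree.lengths[v]))
         for v in range(tree.n_nodes) if v != tree.root}
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(internals)):
        states[internals] = assign
        p = pi[states[tree.root]]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            p *= P[v][states[tree.parent[v]], states[v]]
        total += p
    return total


def enum_node_marginals(tree: Phylogeny, tip_states: dict, model: MkModel) -> np.ndarray:
    """Brute-force per-internal-node state marginals (normalized)."""
    states = np.zeros(tree.n_nodes, dtype=int)
    for i, lbl in enumerate(tree.tip_labels):
        states[i] = tip_states[lbl]
    internals = [v for v in range(tree.n_tips, tree.n_nodes)]
    pi = model.root_prior()
    P = {v: transition_matrix(model, float(tree.lengths[v]))
         for v in range(tree.n_nodes) if v != tree.root}
    acc = np.zeros((tree.n_nodes, 2))
    for assign in itertools.product((0, 1), repeat=len(internals)):
        states[internals] = assign
        p = pi[states[tree.root]]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            p *= P[v][states[tree.parent[v]], states[v]]
        for v in internals:
            acc[v, states[v]] += p
    sums = acc.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0  # tip rows are unused by callers
    return acc / sums
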