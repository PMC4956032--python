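"""Synthetic trees and traits with the statistical structure the analysis
assumes, so every inference stage is testable without external data.

The generator emulates the study's generative model: a Yule (pure-birth)
phylogeny scaled to unit root depth; a continuous trait drawn from
MVN(X beta, sigma^2 C(lambda, delta, kappa)) where the binary predictor is
assigned either to a clade block (mimicking the real data, where projections
concentrate in large-bodied clades) or i.i.d. Bernoulli (for null
calibration); and a binary character evolved under the 2-state CTMC.
Default truth values for recovery experiments sit at the posterior means the
analysis of the real data produces (beta1 = 3.24, beta2 = 0.88,
lambda = 0.88, kappa = 0.14), with sigma^2 = 0.5 giving tip-value scatter
comparable to ln femur length residuals on a unit-depth tree.

All randomness flows from one master seed through named sub-streams
("tree", "traits", "mk") so components can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mk_ancestral import MkModel, transition_matrix
from .transforms import TransformParams, transform_covariance
from .treeio import Phylogeny

__all__ = [
    "SimulationSpec",
    "simulate_yule",
    "simulate_bm_regression",
    "simulate_mk",
    "assign_clade_block",
    "sub_rng",
]

_STREAMS = ("tree", "traits", "mk")


def sub_rng(seed: int, stream: str) -> np.random.Generator:
    """Named sub-stream of the master seed."""
    if stream not in _STREAMS:
        raise ValueError(f"unknown stream {stream!r}; use one of {_STREAMS}")
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAMS.index(stream),))
    return np.random.default_rng(ss)


@dataclass
class SimulationSpec:
    """Truth values for one simulated dataset."""

    n_tips: int = 150
    birth_rate: float = 1.0
    beta1: float = 3.24
    beta2: float = 0.88
    sigma2: float = 0.5
    lam: float = 0.88
    delta: float = 1.0
    kappa: float = 0.14
    predictor: str = "clade"      # "clade" | "bernoulli"
    predictor_fraction: float = 0.2
    q01: float = 1.0
    q10: float = 1.0
    mk_root_state: int | None = None  # None: draw from stationary distribution
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if min(self.birth_rate, self.sigma2) <= 0:
            raise ValueError("birth rate and sigma2 must be > 0")
        if not (0.0 < self.predictor_fraction < 1.0):
            raise ValueError("predictor_fraction must lie in (0, 1)")
        if self.predictor not in ("clade", "bernoulli"):
            raise ValueError(f"unknown predictor rule {self.predictor!r}")

    def transform_params(self) -> TransformParams:
        return TransformParams(lam=self.lam, delta=self.delta, kappa=self.kappa)

    def as_dict(self) -> dict:
        return {
            "n_tips": self.n_tips,
            "birth_rate": self.birth_rate,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "sigma2": self.sigma2,
            "lambda": self.lam,
            "delta": self.delta,
            "kappa": self.kappa,
            "predictor": self.predictor,
            "predictor_fraction": self.predictor_fraction,
            "q01": self.q01,
            "q10": self.q10,
            "mk_root_state": self.mk_root_state,
            "seed": self.seed,
        }


def simulate_yule(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator | None = None,
    scale_to_depth: float | None = 1.0,
) -> Phylogeny:
    """Yule (pure-birth) tree: exponential waiting times between speciations
    at total rate k * birth_rate, a uniformly chosen lineage splitting each
    time; after the (n-1)-th split the tree grows one further exponential
    interval so tips are contemporaneous (ultrametric).

    ``scale_to_depth`` rescales all branch lengths to the given root-to-tip
    depth (default 1; pass None to keep raw Yule time units).
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # node 0 is the root; each node's edge spans [birth, end] in absolute time
    parent = [-1]
    birth = [0.0]
    end = [0.0]
    active: list[int] = []
    for _ in range(2):
        parent.append(0)
        birth.append(0.0)
        end.append(0.0)
        active.append(len(parent) - 1)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(k)))
        end[node] = t
        for _ in range(2):
            parent.append(node)
            birth.append(t)
            end.append(t)
            active.append(len(parent) - 1)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for node in active:
        end[node] = t
    # remap so the surviving lineages (tips) occupy indices 0..n-1
    n_nodes = len(parent)
    tip_ids = sorted(active)
    tip_set = set(tip_ids)
    internal_ids = [i for i in range(n_nodes) if i not in tip_set]
    remap = {old: new for new, old in enumerate(tip_ids)}
    remap.update({old: n_tips + j for j, old in enumerate(internal_ids)})
    parent_arr = np.full(n_nodes, -1, dtype=np.int64)
    length_arr = np.zeros(n_nodes)
    for old in range(n_nodes):
        new = remap[old]
        p = parent[old]
        parent_arr[new] = remap[p] if p >= 0 else -1
        if p >= 0:
            length_arr[new] = end[old] - birth[old]
    labels = [f"t{i+1}" for i in range(n_tips)]
    tree = Phylogeny(parent_arr, length_arr, labels, remap[0])
    if scale_to_depth is not None:
        depth = float(tree.tip_depths().max())
        tree = tree.copy_with_lengths(tree.lengths * (scale_to_depth / depth))
    return tree


def assign_clade_block(
    tree: Phylogeny, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Set the predictor to 1 for the tips of the internal clade whose size
    is closest to fraction * n_tips (ties broken at random)."""
    n = tree.n_tips
    target = max(1, round(fraction * n))
    sizes = []
    for v in range(n, tree.n_nodes):
        if v == tree.root:
            continue
        sizes.append((abs(len(tree.clade_tips(v)) - target), v))
    if not sizes:
        raise ValueError("tree has no non-root internal nodes")
    best = min(d for d, _ in sizes)
    candidates = sorted(v for d, v in sizes if d == best)
    v = candidates[int(rng.integers(len(candidates)))]
    z = np.zeros(n)
    z[tree.clade_tips(v)] = 1.0
    if z.min() == z.max():  # clade covered everything; fall back to Bernoulli
        z = (rng.random(n) < fraction).astype(float)
        if z.min() == z.max():
            z[int(rng.integers(n))] = 1.0 - z[0]
    return z


def simulate_bm_regression(tree: Phylogeny, spec: SimulationSpec, rng=None):
    """Draw (y, z): the binary predictor per the spec's rule, then
    y ~ MVN(X beta, sigma^2 C(lambda, delta, kappa)) via Cholesky."""
    rng = rng if isinstance(rng, np.random.Generator) else sub_rng(spec.seed, "traits")
    n = tree.n_tips
    if spec.predictor == "clade":
        z = assign_clade_block(tree, spec.predictor_fraction, rng)
    else:
        z = (rng.random(n) < spec.predictor_fraction).astype(float)
        while z.min() == z.max():
            z = (rng.random(n) < spec.predictor_fraction).astype(float)
    C = transform_covariance(tree, spec.transform_params()).matrix
    try:
        L = np.linalg.cholesky(C + 0.0)
    except np.linalg.LinAlgError:
        # PSD but numerically semidefinite (e.g. lambda = 0 duplicates): jitter
        w, V = np.linalg.eigh(C)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("transformed covariance is not positive semidefinite")
        L = V * np.sqrt(np.clip(w, 0.0, None))
    mean = spec.beta1 + spec.beta2 * z
    y = mean + np.sqrt(spec.sigma2) * (L @ rng.standard_normal(n))
    return y, z


def simulate_mk(
    tree: Phylogeny,
    q01: float,
    q10: float,
    root_state: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Evolve a binary character tipward edge-by-edge with the closed-form
    transition matrix; root state fixed or drawn from the stationary
    distribution.  Returns {tip label: state}."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = MkModel(q01, q10)
    state = np.zeros(tree.n_nodes, dtype=int)
    if root_state is None:
        pi = model.root_prior()
        state[tree.root] = int(rng.random() < pi[1])
    else:
        state[tree.root] = int(root_state)
    for v in tree.postorder[::-1]:  # preorder: parents before children
        if v == tree.root:
            continue
        P = transition_matrix(model, float(tree.lengths[v]))
        p1 = P[state[tree.parent[v]], 1]
        state[v] = int(rng.random() < p1)
    return {tree.tip_labels[i]: int(state[i]) for i in range(tree.n_tips)}
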