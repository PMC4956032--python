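"""Binary-character evolution (2-state Mk model) and reversible-jump MCMC
ancestral-state reconstruction.

The character evolves along branches as a continuous-time Markov chain with
gain rate q01 and loss rate q10.  Tip data enter through Felsenstein's
pruning algorithm; ancestral marginals come from the standard up-down
(inside-outside) pass.  The sampler follows the BayesTraits-style setup: an
exponential prior on each rate whose mean m is itself a parameter with a
uniform(0, 10] hyperprior, and a reversible jump between a one-rate model
(q01 = q10) and a two-rate model, with per-sample node marginals averaged
over the retained chain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pgls import ChainSettings
from .treeio import Phylogeny

logger = logging.getLogger("spinetrait.mk_ancestral")

__all__ = [
    "MkModel",
    "MkPosterior",
    "transition_matrix",
    "prune_likelihood",
    "log_prune_likelihood",
    "node_marginals",
    "rjmcmc_ancestral",
    "ancestral_report",
]


@dataclass
class MkModel:
    """Two-state CTMC: q01 = gain rate, q10 = loss rate (events per unit
    branch length)."""

    q01: float
    q10: float
    rate_model: str = "different"  # "equal" | "different"
    root: str = "stationary"       # "stationary" | "uniform"

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be >= 0")
        if self.q01 + self.q10 <= 0:
            raise ValueError("at least one rate must be > 0")
        if self.rate_model == "equal" and self.q01 != self.q10:
            raise ValueError("equal-rate model requires q01 == q10")
        if self.root not in ("stationary", "uniform"):
            raise ValueError(f"unknown root convention {self.root!r}")

    def root_prior(self) -> np.ndarray:
        if self.root == "uniform":
            return np.array([0.5, 0.5])
        s = self.q01 + self.q10
        return np.array([self.q10 / s, self.q01 / s])


def transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """Closed-form 2x2 transition probabilities over a branch of length t:
    P00(t) = (q10 + q01 e^{-(q01+q10) t}) / (q01 + q10), etc."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    q01, q10 = model.q01, model.q10
    s = q01 + q10
    e = math.exp(-s * t)
    return np.array(
        [
            [(q10 + q01 * e) / s, q01 * (1.0 - e) / s],
            [q10 * (1.0 - e) / s, (q01 + q10 * e) / s],
        ]
    )


def _tip_state_vector(tree: Phylogeny, tip_states: dict) -> np.ndarray:
    missing = [t for t in tree.tip_labels if t not in tip_states]
    if missing:
        raise ValueError(f"tip states missing for: {missing}")
    states = np.array([int(tip_states[t]) for t in tree.tip_labels])
    if not np.all(np.isin(states, (0, 1))):
        raise ValueError("tip states must be 0 or 1")
    return states


def _edge_matrices(tree: Phylogeny, model: MkModel) -> np.ndarray:
    P = np.empty((tree.n_nodes, 2, 2))
    for v in range(tree.n_nodes):
        if v == tree.root:
            P[v] = np.eye(2)
        else:
            P[v] = transition_matrix(model, float(tree.lengths[v]))
    return P


def _upward(tree: Phylogeny, states: np.ndarray, P: np.ndarray):
    """Felsenstein pruning: partial likelihoods L[v, s] with per-node
    rescaling; returns (L, log scale total)."""
    n = tree.n_nodes
    L = np.zeros((n, 2))
    log_scale = 0.0
    for v in tree.postorder:
        if v < tree.n_tips:
            L[v, states[v]] = 1.0
            continue
        vec = np.ones(2)
        for c in tree.children[v]:
            vec = vec * (P[c] @ L[c])
        tot = vec.sum()
        if tot <= 0:
            return L, -np.inf
        L[v] = vec / tot
        log_scale += math.log(tot)
    return L, log_scale


def log_prune_likelihood(tree: Phylogeny, tip_states: dict, model: MkModel) -> float:
    states = _tip_state_vector(tree, tip_states)
    P = _edge_matrices(tree, model)
    L, log_scale = _upward(tree, states, P)
    root_val = float(model.root_prior() @ L[tree.root])
    if root_val <= 0 or not np.isfinite(log_scale):
        return -np.inf
    return math.log(root_val) + log_scale


def prune_likelihood(tree: Phylogeny, tip_states: dict, model: MkModel) -> float:
    """Likelihood of the tip data under the Mk model (pruning algorithm)."""
    ll = log_prune_likelihood(tree, tip_states, model)
    return math.exp(ll) if np.isfinite(ll) else 0.0


def node_marginals(tree: Phylogeny, tip_states: dict, model: MkModel) -> np.ndarray:
    """Exact marginal P(state | data, rates) for every node (up-down pass).

    Returns an (n_nodes, 2) array; tip rows are one-hot.
    """
    states = _tip_state_vector(tree, tip_states)
    P = _edge_matrices(tree, model)
    L, log_scale = _upward(tree, states, P)
    if not np.isfinite(log_scale):
        raise ValueError("data have zero likelihood under this model")
    n = tree.n_nodes
    G = np.zeros((n, 2))
    G[tree.root] = model.root_prior()
    # messages S[c, s_p] = sum_{s_c} P[c][s_p, s_c] L[c, s_c]
    S = np.einsum("cij,cj->ci", P, L)
    for v in tree.postorder[::-1]:  # preorder
        for c in tree.children[v]:
            sib = np.ones(2)
            for c2 in tree.children[v]:
                if c2 != c:
                    sib = sib * S[c2]
            G[c] = (G[v] * sib) @ P[c]
    M = G * L
    M = M / M.sum(axis=1, keepdims=True)
    return M


# ----------------------------------------------------------------------
# RJMCMC
# ----------------------------------------------------------------------

@dataclass
class MkPosterior:
    """Retained RJMCMC samples and averaged node-state probabilities."""

    samples: pd.DataFrame  # q01 q10 rate_model m loglik
    node_probs: pd.DataFrame  # node fingerprint p0 p1
    settings: ChainSettings
    seed: int
    root: str

    def __len__(self) -> int:
        return len(self.samples)


def rjmcmc_ancestral(
    tree: Phylogeny,
    tip_states: dict,
    settings: ChainSettings | None = None,
    seed: int | None = None,
    rj: bool = True,
    fixed_rates: tuple | None = None,
    root: str = "stationary",
    hyper_max: float = 10.0,
) -> MkPosterior:
    """Sample transition rates (and the rate-model indicator) and average
    exact per-sample node marginals into ancestral-state probabilities.

    Priors: each rate ~ Exponential(mean m) with m ~ Uniform(0, hyper_max];
    the two rate models have equal prior probability.  ``rj=False`` keeps the
    chain in the two-rate model (fixed dimension); ``fixed_rates=(q01, q10)``
    disables all rate moves so only the (then constant) marginals are
    aggregated — useful for validating the up-down pass.  Reproducible given
    ``seed`` (mandatory).
    """
    if seed is None:
        raise ValueError("seed is required for MCMC")
    settings = settings or ChainSettings()
    if tree.n_tips < 3:
        raise ValueError("need >= 3 tips")
    states = _tip_state_vector(tree, tip_states)
    if states.min() == states.max():
        logger.warning(
            "all tips share state %d: transition rates are weakly identified",
            int(states[0]),
        )
    rng = np.random.default_rng(seed)

    def loglik(q01: float, q10: float) -> float:
        return log_prune_likelihood(
            tree, tip_states, MkModel(q01, q10, root=root)
        )

    def log_rate_prior(q: float, m: float) -> float:
        return -math.log(m) - q / m

    # state
    m = float(rng.uniform(0.0, hyper_max)) or hyper_max / 2
    if fixed_rates is not None:
        q01, q10 = (float(fixed_rates[0]), float(fixed_rates[1]))
        different = q01 != q10
        moves = ["none"]
    else:
        q01 = q10 = float(rng.exponential(m)) + 1e-6
        different = False
        moves = ["rate", "hyper"] + (["jump"] if rj else [])
        if not rj:
            # fixed-dimension run: stay in the two-rate model
            different = True
    cur_ll = loglik(q01, q10)
    if not np.isfinite(cur_ll):
        raise ValueError("initial state has zero likelihood")

    scale_rate, scale_m, scale_u = 0.7, 1.0, 0.7
    n_internal = tree.n_nodes - tree.n_tips
    prob_accum = np.zeros((tree.n_nodes, 2))
    n_accum = 0
    records = []
    acc = tries = 0

    for it in range(1, settings.iterations + 1):
        mv = moves[rng.integers(len(moves))] if len(moves) > 1 else moves[0]
        if mv == "rate":
            tries += 1
            which = int(rng.integers(2)) if different else 0
            step = rng.normal() * scale_rate
            if different:
                q01p, q10p = (q01 * math.exp(step), q10) if which == 0 else (q01, q10 * math.exp(step))
            else:
                q01p = q10p = q01 * math.exp(step)
            new_ll = loglik(q01p, q10p)
            # log-scale random walk: include the q'/q Jacobian in the ratio
            if different:
                old_q, new_q = (q01, q01p) if which == 0 else (q10, q10p)
            else:
                old_q, new_q = q01, q01p
            ratio = (
                new_ll - cur_ll
                + log_rate_prior(new_q, m) - log_rate_prior(old_q, m)
                + math.log(new_q) - math.log(old_q)
            )
            if math.log(rng.random()) < ratio:
                q01, q10, cur_ll = q01p, q10p, new_ll
                acc += 1
        elif mv == "hyper":
            tries += 1
            mp = m + rng.normal() * scale_m
            if 0.0 < mp <= hyper_max:
                lp_new = log_rate_prior(q01, mp) + (log_rate_prior(q10, mp) if different else 0.0)
                lp_old = log_rate_prior(q01, m) + (log_rate_prior(q10, m) if different else 0.0)
                if math.log(rng.random()) < lp_new - lp_old:
                    m = mp
                    acc += 1
        elif mv == "jump":
            tries += 1
            if not different:
                # split: (q, u) -> (q e^u, q e^{-u}); |Jacobian| = 2q
                u = rng.normal() * scale_u
                q01p, q10p = q01 * math.exp(u), q01 * math.exp(-u)
                new_ll = loglik(q01p, q10p)
                log_g = -0.5 * (u / scale_u) ** 2 - math.log(scale_u * math.sqrt(2 * math.pi))
                ratio = (
                    new_ll - cur_ll
                    + log_rate_prior(q01p, m) + log_rate_prior(q10p, m)
                    - log_rate_prior(q01, m)
                    - log_g + math.log(2.0 * q01)
                )
                if math.log(rng.random()) < ratio:
                    q01, q10, cur_ll, different = q01p, q10p, new_ll, True
                    acc += 1
            else:
                # merge: q = sqrt(q01 q10), u = log(q01/q10)/2
                qm = math.sqrt(q01 * q10)
                u = 0.5 * math.log(q01 / q10)
                new_ll = loglik(qm, qm)
                log_g = -0.5 * (u / scale_u) ** 2 - math.log(scale_u * math.sqrt(2 * math.pi))
                ratio = (
                    new_ll - cur_ll
                    + log_rate_prior(qm, m)
                    - log_rate_prior(q01, m) - log_rate_prior(q10, m)
                    + log_g - math.log(2.0 * qm)
                )
                if math.log(rng.random()) < ratio:
                    q01 = q10 = qm
                    cur_ll, different = new_ll, False
                    acc += 1

        if it > settings.burnin and (it - settings.burnin) % settings.thin == 0:
            M = node_marginals(
                tree, tip_states, MkModel(q01, q10, root=root)
            )
            prob_accum += M
            n_accum += 1
            records.append((q01, q10, int(different), m, cur_ll))

    if n_accum == 0:
        raise ValueError("no samples retained; check settings")
    probs = prob_accum / n_accum
    rows = []
    for v in range(tree.n_tips, tree.n_nodes):
        rows.append(
            {
                "node": v,
                "fingerprint": tree.node_fingerprint(v),
                "p0": float(probs[v, 0]),
                "p1": float(probs[v, 1]),
            }
        )
    samples = pd.DataFrame(
        records, columns=["q01", "q10", "rate_model", "m", "loglik"]
    )
    if moves != ["none"] and tries:
        rate = acc / tries
        if not (0.05 <= rate <= 0.7):
            logger.warning("RJMCMC acceptance rate %.3f outside [0.05, 0.7]", rate)
    return MkPosterior(
        samples=samples,
        node_probs=pd.DataFrame(rows),
        settings=settings,
        seed=seed,
        root=root,
    )


def ancestral_report(
    post: MkPosterior, tree: Phylogeny, threshold: float = 0.95
) -> pd.DataFrame:
    """Per-node table of state probabilities with a "supported" flag where
    the better-supported state reaches ``threshold`` (default 0.95)."""
    if len(post) == 0:
        raise ValueError("empty posterior")
    df = post.node_probs.copy()
    df["supported"] = df[["p0", "p1"]].max(axis=1) >= threshold
    return df
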