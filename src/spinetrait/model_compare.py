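"""Marginal likelihoods by the harmonic-mean estimator and log Bayes factors.

The marginal likelihood of each transform model is estimated as the harmonic
mean of the likelihoods sampled by its posterior chain, and models are
compared on the 2-delta convention: logBF(A, B) = 2 (log mL_A - log mL_B),
with values above ~2 conventionally read as positive evidence.  The harmonic
mean is easy to compute from an existing chain but is notoriously unstable
(its value can hinge on the smallest sampled likelihood), so every estimate
is logged together with a leave-out-the-minimum sensitivity; any estimator
with the same signature can stand in behind `compare_models`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .pgls import ChainSettings, Priors, RegressionData, fit_mcmc
from .treeio import Phylogeny

logger = logging.getLogger("spinetrait.model_compare")

__all__ = [
    "ModelComparison",
    "log_marginal_harmonic",
    "log_bayes_factor",
    "compare_models",
    "model_label",
]

#: Default model set: lambda alone, lambda+delta, lambda+kappa.
DEFAULT_MODELS = (
    frozenset({"lambda"}),
    frozenset({"lambda", "delta"}),
    frozenset({"lambda", "kappa"}),
)

_ORDER = {"lambda": 0, "delta": 1, "kappa": 2}


def model_label(model: frozenset | set) -> str:
    if not model:
        return "bm"
    return "+".join(sorted(model, key=_ORDER.get))


@dataclass
class ModelComparison:
    """Per-model log marginal likelihoods and the pairwise 2-delta matrix."""

    labels: list[str]
    log_marginal: dict
    pairwise_logbf: pd.DataFrame
    winner: str
    settings: ChainSettings
    seed: int

    def as_dict(self) -> dict:
        return {
            "models": self.labels,
            "log_marginal": self.log_marginal,
            "pairwise_logbf_2delta": self.pairwise_logbf.to_dict(),
            "winner": self.winner,
            "settings": self.settings.as_dict(),
            "seed": self.seed,
        }


def log_marginal_harmonic(loglik_samples) -> float:
    """Harmonic-mean estimate of the log marginal likelihood.

    Returns -log mean(exp(-logL_i)), evaluated with a log-sum-exp guard.
    Always <= max(logL_i).  A sensitivity diagnostic (dependence on the
    smallest likelihood sample, which dominates the harmonic mean) goes to
    the module log.
    """
    ll = np.asarray(loglik_samples, float)
    if ll.size < 2:
        raise ValueError("need at least 2 likelihood samples")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite log-likelihood samples")
    est = -(logsumexp(-ll) - np.log(ll.size))
    # stability: recompute without the dominating (minimum-likelihood) sample
    keep = np.ones(ll.size, bool)
    keep[np.argmin(ll)] = False
    est_wo = -(logsumexp(-ll[keep]) - np.log(ll.size - 1))
    logger.info(
        "harmonic-mean logML = %.4f (without dominating sample: %.4f, "
        "shift %.4f); the estimator is high-variance — interpret with care",
        est, est_wo, est_wo - est,
    )
    return float(est)


def log_bayes_factor(logml_a: float, logml_b: float) -> float:
    """Log Bayes factor on the 2-delta convention: 2 (logML_A - logML_B)."""
    if not np.isfinite(logml_a) or not np.isfinite(logml_b):
        raise ValueError("log marginal likelihoods must be finite")
    return 2.0 * (logml_a - logml_b)


def compare_models(
    data: RegressionData,
    tree: Phylogeny,
    models=DEFAULT_MODELS,
    settings: ChainSettings | None = None,
    seed: int | None = None,
    priors: Priors | None = None,
) -> ModelComparison:
    """Run one chain per model (independent sub-seeds spawned from ``seed``)
    and assemble harmonic-mean logMLs and the pairwise 2-delta matrix."""
    if seed is None:
        raise ValueError("seed is required")
    models = [frozenset(m) for m in models]
    if len(models) < 2:
        raise ValueError("need >= 2 models to compare")
    settings = settings or ChainSettings()
    labels = [model_label(m) for m in models]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate models in list: {labels}")
    subseeds = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(len(models))]
    logml = {}
    for m, lbl, ss in zip(models, labels, subseeds):
        post = fit_mcmc(data, tree, model=m, settings=settings, seed=ss, priors=priors)
        logml[lbl] = log_marginal_harmonic(post.samples["loglik"].to_numpy())
        logger.info("model %-14s logML(harmonic) = %.3f", lbl, logml[lbl])
    mat = pd.DataFrame(
        [[log_bayes_factor(logml[a], logml[b]) for b in labels] for a in labels],
        index=labels,
        columns=labels,
    )
    winner = max(labels, key=lambda l: logml[l])
    for l in labels:
        if l != winner and mat.loc[winner, l] > 2:
            logger.info(
                "logBF(%s, %s) = %.2f > 2: positive evidence (annotation only)",
                winner, l, mat.loc[winner, l],
            )
    return ModelComparison(
        labels=labels,
        log_marginal=logml,
        pairwise_logbf=mat,
        winner=winner,
        settings=settings,
        seed=seed,
    )
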