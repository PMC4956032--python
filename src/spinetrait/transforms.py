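"""Pagel's lambda, delta, and kappa scalings of the BM covariance.

These three parameters deform the Brownian-motion expectation to capture,
respectively, the strength of phylogenetic signal (lambda multiplies the
shared, off-diagonal covariance), early-vs-late bursts of change through time
(delta raises shared root-to-MRCA path lengths to a power), and punctuational
versus gradual change (kappa raises individual branch lengths to a power, so
kappa -> 0 makes change speciational, independent of branch duration).

Composition order is fixed: kappa acts on branch lengths, the covariance is
then built, delta acts on its entries, and lambda scales the off-diagonal.
At 1 each transform is exactly the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .treeio import Phylogeny, PhyloCovariance, vcv_matrix

logger = logging.getLogger("spinetrait.transforms")

__all__ = [
    "TransformParams",
    "TransformError",
    "apply_kappa",
    "apply_delta",
    "apply_lambda",
    "transform_covariance",
    "covariance_from_incidence",
]

#: Default upper bounds, BayesTraits-style; lambda is always confined to [0, 1].
DEFAULT_CAPS = {"delta": 3.0, "kappa": 3.0}


class TransformError(ValueError):
    """Transform parameter outside its admissible range."""


@dataclass
class TransformParams:
    """Pagel transform values; 1.0 means "absent from the model"."""

    lam: float = 1.0
    delta: float = 1.0
    kappa: float = 1.0
    caps: dict = field(default_factory=lambda: dict(DEFAULT_CAPS))

    def __post_init__(self) -> None:
        validate_lambda(self.lam)
        validate_delta(self.delta, self.caps["delta"])
        validate_kappa(self.kappa, self.caps["kappa"])

    def as_dict(self) -> dict:
        return {"lambda": self.lam, "delta": self.delta, "kappa": self.kappa}


def validate_lambda(lam: float) -> None:
    if not (0.0 <= lam <= 1.0):
        raise TransformError(f"lambda must lie in [0, 1], got {lam}")


def validate_delta(delta: float, cap: float = DEFAULT_CAPS["delta"]) -> None:
    if not (0.0 < delta <= cap):
        raise TransformError(f"delta must lie in (0, {cap}], got {delta}")


def validate_kappa(kappa: float, cap: float = DEFAULT_CAPS["kappa"]) -> None:
    if not (0.0 <= kappa <= cap):
        raise TransformError(f"kappa must lie in [0, {cap}], got {kappa}")


def _pow_branches(lengths: np.ndarray, kappa: float) -> np.ndarray:
    # 0^kappa = 0 by convention for all kappa, including kappa = 0 (zero
    # branches encode resolved polytomies and must stay zero)
    out = np.zeros_like(lengths)
    pos = lengths > 0
    if kappa == 0.0:
        out[pos] = 1.0
    else:
        out[pos] = lengths[pos] ** kappa
    return out


def apply_kappa(tree: Phylogeny, kappa: float, cap: float = DEFAULT_CAPS["kappa"]) -> Phylogeny:
    """Raise every branch length to the power kappa (topology unchanged)."""
    validate_kappa(kappa, cap)
    if kappa == 1.0:
        return tree
    lengths = _pow_branches(tree.lengths, kappa)
    lengths[tree.root] = 0.0
    return tree.copy_with_lengths(lengths)


def apply_delta(C: PhyloCovariance, delta: float, cap: float = DEFAULT_CAPS["delta"]) -> PhyloCovariance:
    """Raise every covariance entry (a shared root-to-MRCA path length) to
    the power delta."""
    validate_delta(delta, cap)
    if delta == 1.0:
        return C
    rec = {"delta": delta} if C.transform == "raw" else {**C.transform, "delta": delta}
    return PhyloCovariance(list(C.taxa), C.matrix ** delta, rec)


def apply_lambda(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal entries by lambda; the diagonal is untouched."""
    validate_lambda(lam)
    if lam == 1.0:
        return C
    m = C.matrix * lam
    np.fill_diagonal(m, np.diag(C.matrix))
    rec = {"lambda": lam} if C.transform == "raw" else {**C.transform, "lambda": lam}
    return PhyloCovariance(list(C.taxa), m, rec)


def transform_covariance(tree: Phylogeny, params: TransformParams) -> PhyloCovariance:
    """Compose the transforms in the fixed order kappa -> delta -> lambda."""
    C = vcv_matrix(apply_kappa(tree, params.kappa, params.caps["kappa"]))
    C = apply_delta(C, params.delta, params.caps["delta"])
    C = apply_lambda(C, params.lam)
    if params.as_dict() == {"lambda": 1.0, "delta": 1.0, "kappa": 1.0}:
        return C
    C.transform = params.as_dict()
    return C


def covariance_from_incidence(
    A: np.ndarray,
    lengths: np.ndarray,
    lam: float = 1.0,
    delta: float = 1.0,
    kappa: float = 1.0,
) -> np.ndarray:
    """Fast transformed-covariance kernel for repeated evaluation (MCMC/ML).

    ``A`` is the tip-by-node edge incidence of the tree and ``lengths`` its
    branch lengths; returns the matrix of ``transform_covariance`` without
    rebuilding tree objects.
    """
    bk = _pow_branches(lengths, kappa)
    C = (A * bk) @ A.T
    if delta != 1.0:
        C = C ** delta
    if lam != 1.0:
        d = np.diag(C).copy()
        C = C * lam
        np.fill_diagonal(C, d)
    return C
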