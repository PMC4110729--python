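"""Alternative epigenetic-barrier measures and their comparison with MFPT.

Two cheaper stand-ins for the exact Markov-chain barrier are implemented:

* the **transitory bit-flip measure** ``P(i, j)``: the fraction of all
  single one-step bit flips applied to the states of attractor ``i`` whose
  *noise-free* relaxation ends in attractor ``j`` (flips that fall back
  into ``i`` count towards ``P(i, i)``, so rows sum to 1);
* the **attractor Hamming distance**: the mean bitwise distance between
  the two attractors' state cycles.

Both are static, symmetric-ish summaries; MFPT is a dynamic quantity and
can differ between the two directions of the same pair — comparing the
measures (correlation/regression) quantifies how much of the barrier is
dynamics rather than geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

from .boolean_core import Attractor, AttractorSet, BooleanNetwork
from .errors import DomainError

__all__ = [
    "FlipTransitionMatrix",
    "transitory_flip_matrix",
    "attractor_hamming",
    "barrier_correlation",
]


@dataclass(frozen=True)
class FlipTransitionMatrix:
    """Row-stochastic ``k x k`` matrix of the transitory bit-flip measure.

    Row ``i`` is an exact rational with denominator
    ``len(attractor_i) * n`` before normalisation (``counts`` keeps the
    integer tallies).
    """

    P: np.ndarray
    counts: np.ndarray
    attractor_ids: tuple[int, ...]


def transitory_flip_matrix(
    net: BooleanNetwork, attractor_set: AttractorSet
) -> FlipTransitionMatrix:
    """Compute ``P(i, j)`` by exhaustive single-flip enumeration.

    Every state of every attractor cycle is perturbed in each of the ``n``
    bits and relaxed under the deterministic dynamics; the destination
    attractor is read off the precomputed basin map.
    """
    k = len(attractor_set)
    n = net.n
    counts = np.zeros((k, k), dtype=np.int64)
    for i, att in enumerate(attractor_set.attractors):
        for s in att.states:
            for b in range(n):
                flipped = s ^ (1 << b)
                counts[i, attractor_set.attractor_of(flipped)] += 1
    denom = counts.sum(axis=1, keepdims=True)
    P = counts / denom
    return FlipTransitionMatrix(
        P=P,
        counts=counts,
        attractor_ids=tuple(a.min_state for a in attractor_set.attractors),
    )


def attractor_hamming(
    att_i: Attractor, att_j: Attractor, method: str = "mean"
) -> float:
    """Hamming distance between two attractors' cycles.

    ``method="mean"`` (default) averages the bitwise distance over all
    cross pairs of cycle states — symmetric, and the natural partner of the
    forward/reverse-averaged MFPT.  ``method="min"`` takes the closest pair
    instead.
    """
    if method not in ("mean", "min"):
        raise DomainError(f"method must be 'mean' or 'min', got {method!r}")
    dists = [
        (x ^ y).bit_count() for x in att_i.states for y in att_j.states
    ]
    return float(np.mean(dists) if method == "mean" else np.min(dists))


def barrier_correlation(
    xs: Sequence[float], ys: Sequence[float]
) -> tuple[float, float, float]:
    """Pearson r and least-squares line for a measure-vs-measure scatter.

    Returns ``(r, slope, intercept)``.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 3:
        raise DomainError("need >= 3 paired points")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise DomainError("degenerate variance: correlation undefined")
    r, _ = scipy.stats.pearsonr(xs, ys)
    fit = scipy.stats.linregress(xs, ys)
    return float(r), float(fit.slope), float(fit.intercept)
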