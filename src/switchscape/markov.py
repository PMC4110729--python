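"""Noisy Boolean dynamics as a Markov chain; first-passage analysis.

Gene expression noise is modelled as an independent per-gene flip
probability ``p_e`` per synchronous step.  One step of the noisy chain is a
mixture: with probability ``(1 - p_e)**n`` no gene flips and the
deterministic map ``D`` is applied; otherwise the state jumps directly to
the flipped state.  The one-step transition probability is therefore

    p(x -> y) = p_e**h(x,y) * (1 - p_e)**(n - h(x,y))        for y != x
                + (1 - p_e)**n * [y == D(x)]

with ``h`` the Hamming distance (the flip term over ``y != x`` plus the
no-flip mass sums exactly to 1).  For ``0 < p_e < 1`` every entry of the
flip kernel is positive, so the chain is irreducible and every mean first
passage time (MFPT) is finite.

The first-passage distribution ``F_k(x, y)`` (probability that the first
visit to ``y`` from ``x`` happens at step ``k``) satisfies
``F_1 = p(x -> y)`` and ``F_k = sum_{z != y} p(x -> z) F_{k-1}(z, y)``;
``MFPT(x, y) = sum_k k F_k``.  Production MFPTs are computed exactly by the
absorbing-chain linear system ``m = 1 + Q m`` (mathematically equal to the
series); the truncated series and a direct stochastic simulation are kept
as independent cross-checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import scipy.linalg

from .boolean_core import AttractorSet, BooleanNetwork
from .errors import CapacityError, DomainError, PrecisionWarning, ReachabilityError

__all__ = [
    "NoisyTransitionMatrix",
    "MfptMatrix",
    "transition_matrix",
    "first_passage_probability",
    "mfpt_states",
    "mfpt_all_states",
    "mfpt_series_oracle",
    "mfpt_monte_carlo",
    "attractor_mfpt_matrix",
]

#: Hard default cap: the flip kernel is dense, so memory is 8 * 4**n bytes.
DEFAULT_MATRIX_CAP = 14


@dataclass(frozen=True)
class NoisyTransitionMatrix:
    """Row-stochastic ``2**n x 2**n`` matrix of the noisy chain."""

    p: np.ndarray
    p_e: float
    n: int


@dataclass(frozen=True)
class MfptMatrix:
    """Pairwise attractor-to-attractor MFPTs; diagonal fixed at 0.

    ``attractor_ids[i]`` is the smallest state code of attractor ``i`` (the
    canonical identifier used in all tabular output).
    """

    values: np.ndarray
    attractor_ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.attractor_ids)


def transition_matrix(
    net: BooleanNetwork, p_e: float, max_n: int = DEFAULT_MATRIX_CAP
) -> NoisyTransitionMatrix:
    """Build the noisy one-step transition matrix."""
    if not 0.0 < p_e < 1.0:
        raise DomainError(f"p_e must lie in (0, 1), got {p_e}")
    n = net.n
    if n > max_n:
        raise CapacityError(
            f"dense 2**{n} x 2**{n} transition matrix exceeds max_n={max_n}; "
            "pass a larger max_n explicitly to proceed"
        )
    codes = np.arange(1 << n, dtype=np.uint64)
    ham = np.bitwise_count(codes[:, None] ^ codes[None, :]).astype(np.float64)
    P = (p_e**ham) * ((1.0 - p_e) ** (n - ham))
    np.fill_diagonal(P, 0.0)
    step = net.next_state_table()
    P[np.arange(1 << n), step] += (1.0 - p_e) ** n
    # rows sum to 1 by construction; guard against accumulated round-off
    rowsum = P.sum(axis=1)
    assert np.all(np.abs(rowsum - 1.0) < 1e-12)
    return NoisyTransitionMatrix(p=P, p_e=float(p_e), n=n)


def first_passage_probability(
    matrix: NoisyTransitionMatrix, x: int, y: int, k: int
) -> float:
    """``F_k(x, y)``: probability the first visit to ``y`` from ``x`` is at step ``k``."""
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if x == y:
        raise DomainError("first-passage time requires x != y")
    P = matrix.p
    f = P[:, y].copy()  # F_1(., y)
    if k == 1:
        return float(f[x])
    Pmask = P.copy()
    Pmask[:, y] = 0.0  # exclude paths through y before step k
    for _ in range(k - 1):
        f = Pmask @ f
    return float(f[x])


def _absorbing_solve(matrix: NoisyTransitionMatrix, targets: np.ndarray) -> np.ndarray:
    """Hitting times of ``targets`` from every non-target state."""
    size = 1 << matrix.n
    mask = np.ones(size, dtype=bool)
    mask[targets] = False
    Q = matrix.p[np.ix_(mask, mask)]
    A = np.eye(mask.sum()) - Q
    try:
        m = scipy.linalg.solve(A, np.ones(mask.sum()))
    except scipy.linalg.LinAlgError as e:  # pragma: no cover - p_e>0 is irreducible
        raise ReachabilityError(f"target set unreachable: {e}") from e
    if not np.all(np.isfinite(m)):
        raise ReachabilityError("target set unreachable (non-finite hitting times)")
    return m, mask


def mfpt_all_states(
    matrix: NoisyTransitionMatrix, target_states: Iterable[int]
) -> np.ndarray:
    """Exact mean hitting time of ``target_states`` from every state.

    Entries at target states are 0.  One linear solve serves all sources,
    which is what makes the all-pairs attractor matrix cheap.
    """
    targets = np.asarray(sorted(set(int(t) for t in target_states)), dtype=np.int64)
    if targets.size == 0:
        raise DomainError("target set must be nonempty")
    m, mask = _absorbing_solve(matrix, targets)
    out = np.zeros(1 << matrix.n)
    out[mask] = m
    return out


def mfpt_states(
    matrix: NoisyTransitionMatrix,
    source_states: Iterable[int],
    target_states: Iterable[int],
) -> float:
    """MFPT from a uniform mixture over ``source_states`` to ``target_states``.

    Solves the absorbing-chain system ``m = 1 + Q m`` exactly; equals
    ``sum_k k F_k`` of the first-passage distribution.
    """
    sources = sorted(set(int(s) for s in source_states))
    targets = set(int(t) for t in target_states)
    if not sources or not targets:
        raise DomainError("source and target sets must be nonempty")
    if targets & set(sources):
        raise DomainError("source and target sets must be disjoint")
    full = mfpt_all_states(matrix, targets)
    return float(np.mean(full[sources]))


def mfpt_series_oracle(
    matrix: NoisyTransitionMatrix,
    x: int,
    target_states: Iterable[int],
    K: int = 100_000,
    tol: float = 1e-9,
) -> float:
    """Truncated series ``sum_{k<=K} k F_k(x, target)`` — a test oracle.

    Iterates the first-passage recursion until the unaccounted tail mass
    drops below ``tol`` or ``K`` is reached; warns (:class:`PrecisionWarning`)
    if the tail is still above ``tol`` at ``K``.  Kept deliberately
    independent of the linear-solve path.
    """
    targets = sorted(set(int(t) for t in target_states))
    if x in targets:
        raise DomainError("source must lie outside the target set")
    P = matrix.p
    Pmask = P.copy()
    Pmask[:, targets] = 0.0
    f = P[:, targets].sum(axis=1)  # F_1(., targets)
    total = 0.0
    mass = 0.0
    for k in range(1, K + 1):
        total += k * f[x]
        mass += f[x]
        if 1.0 - mass < tol:
            break
        f = Pmask @ f
    else:
        warnings.warn(
            f"first-passage tail mass {1.0 - mass:.3e} still above tol={tol} "
            f"at K={K}; MFPT underestimated",
            PrecisionWarning,
            stacklevel=2,
        )
    return float(total)


def mfpt_monte_carlo(
    net: BooleanNetwork,
    p_e: float,
    source: int,
    target_states: Iterable[int],
    reps: int,
    rng: Optional[np.random.Generator] = None,
    max_steps: int = 1_000_000,
) -> tuple[float, float]:
    """Simulate the noisy chain; returns (mean first passage time, std. error).

    Each step draws independent per-gene flips; if none fire the
    deterministic update runs, otherwise the state jumps to the flipped
    state.  Walkers are advanced in lock-step as a vectorised batch.
    """
    if reps < 1:
        raise DomainError(f"reps must be >= 1, got {reps}")
    if not 0.0 < p_e < 1.0:
        raise DomainError(f"p_e must lie in (0, 1), got {p_e}")
    if rng is None:
        rng = np.random.default_rng()
    targets = np.zeros(1 << net.n, dtype=bool)
    targets[sorted(set(int(t) for t in target_states))] = True
    if targets[source]:
        raise DomainError("source must lie outside the target set")
    step = net.next_state_table()
    powers = (np.int64(1) << np.arange(net.n, dtype=np.int64))

    state = np.full(reps, source, dtype=np.int64)
    steps = np.zeros(reps, dtype=np.int64)
    active = np.ones(reps, dtype=bool)
    t = 0
    while active.any():
        t += 1
        if t > max_steps:
            warnings.warn(
                f"{int(active.sum())} of {reps} walkers did not reach the target "
                f"within {max_steps} steps; estimate truncated",
                PrecisionWarning,
                stacklevel=2,
            )
            steps[active] = max_steps
            break
        idx = np.nonzero(active)[0]
        flips = rng.random((idx.size, net.n)) < p_e
        masks = flips @ powers
        cur = state[idx]
        nxt = np.where(masks == 0, step[cur], cur ^ masks)
        state[idx] = nxt
        steps[idx] = t
        active[idx] = ~targets[nxt]
    mean = float(np.mean(steps))
    stderr = float(np.std(steps, ddof=1) / np.sqrt(reps)) if reps > 1 else float("nan")
    return mean, stderr


def attractor_mfpt_matrix(
    net: BooleanNetwork,
    p_e: float,
    attractor_set: AttractorSet,
    max_n: int = DEFAULT_MATRIX_CAP,
    matrix: Optional[NoisyTransitionMatrix] = None,
) -> MfptMatrix:
    """All-pairs attractor MFPT matrix.

    Entry ``(i, j)`` is the mean hitting time of attractor ``j``'s state
    set, started from a uniform mixture over attractor ``i``'s states.
    One linear solve per target attractor serves every source.
    """
    k = len(attractor_set)
    if k < 2:
        raise DomainError(f"need >= 2 attractors, got {k}")
    if matrix is None:
        matrix = transition_matrix(net, p_e, max_n=max_n)
    values = np.zeros((k, k))
    for j, att_j in enumerate(attractor_set.attractors):
        full = mfpt_all_states(matrix, att_j.states)
        for i, att_i in enumerate(attractor_set.attractors):
            if i != j:
                values[i, j] = float(np.mean(full[list(att_i.states)]))
    return MfptMatrix(
        values=values,
        attractor_ids=tuple(a.min_state for a in attractor_set.attractors),
    )
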