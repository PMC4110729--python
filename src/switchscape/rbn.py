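"""Critical random Boolean network (RBN) generation.

A random network with fixed in-degree ``q`` and truth-table output bias
``p_N`` (probability that a table entry is 1) has average sensitivity

    s = 2 * q * p_N * (1 - p_N)

the expected number of nodes to which a single-bit perturbation propagates
in one synchronous step.  ``s = 1`` is the critical regime separating
ordered (perturbations die out) from chaotic (perturbations grow)
dynamics; gene regulatory networks are widely argued to operate near it.
Networks are tuned to criticality by solving ``s = 1`` for ``p_N`` at the
chosen ``q``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .boolean_core import BooleanNetwork
from .errors import ConfigurationError, DomainError

__all__ = [
    "RbnConfig",
    "sensitivity",
    "critical_bias",
    "generate_critical_rbn",
    "empirical_derrida_sensitivity",
]


def sensitivity(q: int, p_N: float) -> float:
    """Average sensitivity ``s = 2 q p_N (1 - p_N)`` of a bias-``p_N`` RBN."""
    if q < 1:
        raise DomainError(f"in-degree q must be >= 1, got {q}")
    if not 0.0 < p_N < 1.0:
        raise DomainError(f"bias p_N must lie in (0, 1), got {p_N}")
    return 2.0 * q * p_N * (1.0 - p_N)


def critical_bias(q: int, branch_root: str = "lower") -> float:
    """Output bias placing a fixed-in-degree-``q`` RBN on the ``s = 1`` contour.

    Solves ``2 q p (1 - p) = 1``; the quadratic has real roots only for
    ``q >= 2`` (the maximum of ``s`` over ``p`` is ``q / 2``).  The lower
    root (sparse expression) is returned by default; ``branch_root="upper"``
    gives the mirror solution.
    """
    if branch_root not in ("lower", "upper"):
        raise DomainError(f"branch_root must be 'lower' or 'upper', got {branch_root!r}")
    if q < 2:
        raise DomainError(
            f"no real critical bias for q={q}: max sensitivity is q/2 = {q / 2}"
        )
    disc = 1.0 - 2.0 / q
    root = math.sqrt(disc)
    p = (1.0 - root) / 2.0 if branch_root == "lower" else (1.0 + root) / 2.0
    return p


@dataclass(frozen=True)
class RbnConfig:
    """Parameters of one random-network draw.

    ``p_N=None`` means "use ``critical_bias(q, branch_root)``".  Input sets
    are sampled without replacement; ``allow_self_input`` controls whether a
    node may regulate itself.
    """

    n: int
    q: int = 2
    p_N: Optional[float] = None
    seed: Optional[int] = None
    allow_self_input: bool = True
    branch_root: str = "lower"

    def resolved_bias(self) -> float:
        if self.p_N is not None:
            return float(self.p_N)
        if self.q == 2:
            return 0.5  # exact double root of 4 p (1 - p) = 1
        return critical_bias(self.q, self.branch_root)


def generate_critical_rbn(
    config: RbnConfig, rng: Optional[np.random.Generator] = None
) -> BooleanNetwork:
    """Draw one RBN: ``q`` distinct inputs per node, Bernoulli(``p_N``) tables.

    Identical ``(config, seed)`` always yields a bit-identical network.
    """
    if config.n < 1:
        raise ConfigurationError(f"n must be >= 1, got {config.n}")
    if config.q < 1:
        raise ConfigurationError(f"q must be >= 1, got {config.q}")
    available = config.n if config.allow_self_input else config.n - 1
    if config.q > available:
        raise ConfigurationError(
            f"cannot wire q={config.q} distinct inputs per node with n={config.n} "
            f"(allow_self_input={config.allow_self_input})"
        )
    p_N = config.resolved_bias()
    if not 0.0 < p_N < 1.0:
        raise ConfigurationError(f"bias p_N must lie in (0, 1), got {p_N}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    inputs, tables = [], []
    for i in range(config.n):
        candidates = np.arange(config.n)
        if not config.allow_self_input:
            candidates = candidates[candidates != i]
        chosen = rng.choice(candidates, size=config.q, replace=False)
        inputs.append(tuple(int(j) for j in chosen))
        tt = (rng.random(1 << config.q) < p_N).astype(int)
        tables.append(tuple(int(v) for v in tt))
    return BooleanNetwork(
        node_names=tuple(f"g{i}" for i in range(config.n)),
        inputs=tuple(inputs),
        truth_tables=tuple(tables),
    )


def empirical_derrida_sensitivity(
    net: BooleanNetwork, samples: int, rng: Optional[np.random.Generator] = None
) -> float:
    """Monte-Carlo estimate of one-step perturbation spread (Derrida plot at
    Hamming distance 1).

    Samples a state ``x`` and a uniformly chosen single-bit flip ``x'``,
    and averages the Hamming distance between ``D(x)`` and ``D(x')``.  On a
    critical network the expectation is 1.
    """
    if samples < 1:
        raise DomainError(f"samples must be >= 1, got {samples}")
    if rng is None:
        rng = np.random.default_rng()
    step = net.next_state_table()
    n = net.n
    xs = rng.integers(0, 1 << n, size=samples)
    bit = rng.integers(0, n, size=samples)
    ys = xs ^ (np.int64(1) << bit)
    diff = np.bitwise_xor(step[xs], step[ys]).astype(np.uint64)
    return float(np.mean(np.bitwise_count(diff)))
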