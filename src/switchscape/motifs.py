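"""The four 2-gene multistable switch motifs and their embedding into RBNs.

Motifs (the field's standard differentiation switches):

* **BS**   — bistable/toggle switch; per-node truth table ``[1, 1, 0, 1]``.
* **MI00** — mutual inhibition, no positive feedback; table ``[0, 1, 0, 0]``.
* **MI0+** — mutual inhibition plus one positive self-feedback loop.
* **MI++** — mutual inhibition plus two positive self-feedback loops; the
  classic tristable switch (e.g. GATA-1/PU.1).

Tables are indexed by the binary input number over rows ``[00, 01, 10, 11]``.
Both tables are "activation gated by an inhibitor": with inputs ``(u, v)``
(``u`` the most-significant bit), ``[0,1,0,0]`` is ``!u & v`` and
``[1,1,0,1]`` is ``!u | v``.  The mutual-inhibition cross-coupling therefore
rides on the most-significant (negated) input slot, while the
least-significant slot carries either the motif's positive self-feedback
(MI0+: first node only; MI++: both nodes) or an external signal (BS, MI00,
and the loop-free MI0+ node).  This is the unique slot assignment under
which the isolated BS is bistable and the isolated MI++ is tristable,
matching the motifs' names; embedding rewires the same slots.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .boolean_core import BooleanNetwork
from .errors import DomainError, EmbeddingError

__all__ = ["MotifKind", "EmbeddingRecord", "motif_network", "embed_motifs"]


class MotifKind(enum.Enum):
    """One of the four multistable switch motifs."""

    BS = "BS"
    MI00 = "MI00"
    MI0P = "MI0+"
    MIPP = "MI++"

    @property
    def truth_table(self) -> tuple[int, int, int, int]:
        return (1, 1, 0, 1) if self is MotifKind.BS else (0, 1, 0, 0)

    @property
    def feedback_loops(self) -> int:
        return {"BS": 0, "MI00": 0, "MI0+": 1, "MI++": 2}[self.value]

    @classmethod
    def parse(cls, name: str) -> "MotifKind":
        key = str(name).strip().upper()
        for kind in cls:
            if kind.value.upper() == key:
                return kind
        raise DomainError(
            f"unknown motif kind {name!r}; expected one of "
            f"{[k.value for k in cls]}"
        )


def _node_has_loop(kind: MotifKind, which: int) -> bool:
    # MI0+: the first node of the pair carries the single positive loop.
    return which < kind.feedback_loops


def motif_network(kind: MotifKind | str, external: int = 0) -> BooleanNetwork:
    """The isolated 2-node motif as a runnable network.

    Input slots that would be driven by the surrounding network are clamped
    to the constant ``external`` (default 0) and folded into a reduced
    1-input truth table, so the returned network is self-contained and can
    be enumerated with :func:`~switchscape.boolean_core.find_attractors`.
    """
    kind = MotifKind.parse(kind) if not isinstance(kind, MotifKind) else kind
    if external not in (0, 1):
        raise DomainError(f"external clamp must be 0 or 1, got {external}")
    tt4 = kind.truth_table
    inputs, tables = [], []
    for which, (me, partner) in enumerate(((0, 1), (1, 0))):
        if _node_has_loop(kind, which):
            inputs.append((partner, me))  # (inhibitor, self-activation)
            tables.append(tt4)
        else:
            # clamp the 2**0 (external) slot: reduced table over the partner bit
            inputs.append((partner,))
            tables.append((tt4[external], tt4[2 + external]))
    return BooleanNetwork(
        node_names=("A", "B"), inputs=tuple(inputs), truth_tables=tuple(tables)
    )


@dataclass(frozen=True)
class EmbeddingRecord:
    """What an embedding changed: which node pairs, and how slots were wired.

    ``rewired_inputs`` has one entry per motif node as
    ``(node, (msb_source, lsb_source))``; ``degree_adjusted`` lists nodes
    whose original in-degree was not 2 and whose input list was truncated
    or extended to the motif's 2-input arity.
    """

    motif_kind: Optional[MotifKind]
    node_pairs: tuple[tuple[int, int], ...]
    rewired_inputs: tuple[tuple[int, tuple[int, int]], ...] = ()
    degree_adjusted: tuple[int, ...] = ()


def embed_motifs(
    net: BooleanNetwork,
    kind: MotifKind | str,
    copies: int,
    rng: Optional[np.random.Generator] = None,
) -> tuple[BooleanNetwork, EmbeddingRecord]:
    """Embed ``copies`` (0, 1 or 2) identical motif copies into ``net``.

    Per copy, two distinct nodes are chosen uniformly at random; their truth
    tables are replaced by the motif table and their inputs rewired: the
    most-significant slot is cross-wired to the partner (the mutual
    inhibition), and the least-significant slot becomes a positive
    self-loop where the motif has one, otherwise it keeps one of the node's
    original (external) sources.  No other node is touched and the node
    count never changes.  The same RNG state always produces the same
    embedding.
    """
    kind = MotifKind.parse(kind) if not isinstance(kind, MotifKind) else kind
    if copies not in (0, 1, 2):
        raise EmbeddingError(f"copies must be 0, 1 or 2, got {copies}")
    if copies == 0:
        return net, EmbeddingRecord(motif_kind=None, node_pairs=())
    if net.n < 2 * copies:
        raise EmbeddingError(
            f"need {2 * copies} distinct nodes to embed {copies} cop(ies), "
            f"network has {net.n}"
        )
    if rng is None:
        rng = np.random.default_rng()
    chosen = rng.choice(net.n, size=2 * copies, replace=False)
    pairs = tuple(
        (int(chosen[2 * c]), int(chosen[2 * c + 1])) for c in range(copies)
    )

    new_inputs = [list(row) for row in net.inputs]
    new_tables = [tuple(row) for row in net.truth_tables]
    rewired, adjusted = [], []
    for i, j in pairs:
        for which, (node, partner) in enumerate(((i, j), (j, i))):
            if len(net.inputs[node]) != 2:
                adjusted.append(node)
            if _node_has_loop(kind, which):
                lsb = node  # positive self-feedback
            else:
                # retain an original external source (prefer one that is
                # neither the partner nor the node itself)
                orig = list(net.inputs[node])
                external = [s for s in orig if s not in (node, partner)]
                if external:
                    lsb = external[0]
                elif orig:
                    lsb = orig[0]
                else:
                    raise EmbeddingError(
                        f"node {node} has no input to retain as external source"
                    )
            new_inputs[node] = [partner, lsb]
            new_tables[node] = kind.truth_table
            rewired.append((node, (partner, lsb)))

    out = BooleanNetwork(
        node_names=net.node_names,
        inputs=tuple(tuple(r) for r in new_inputs),
        truth_tables=tuple(new_tables),
    )
    return out, EmbeddingRecord(
        motif_kind=kind,
        node_pairs=pairs,
        rewired_inputs=tuple(rewired),
        degree_adjusted=tuple(adjusted),
    )
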