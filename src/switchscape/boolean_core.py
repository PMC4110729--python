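"""Synchronous Boolean networks: representation, dynamics, exhaustive attractor search.

A network of ``n`` genes defines a deterministic map ``D`` over the
``2**n`` binary expression states.  Repeated application of ``D`` from any
start state terminates in an attractor — a fixed point ("point attractor")
or a cycle ("cyclic attractor") — and the set of states draining into an
attractor is its basin.  In the cell-differentiation reading, attractors
stand in for cell types and basins for their stability neighbourhoods.

Conventions (fixed once, documented everywhere):

* **State encoding** — node 0 is the *least-significant* bit of the integer
  state code: state ``(b0, b1, ..., b_{n-1})`` has code ``sum(b_i << i)``.
* **Truth-table indexing** — a node's inputs are listed most-significant
  bit first.  For a node with inputs ``(j1, j0)`` in state ``s``, the table
  row consulted is the binary number ``2*s[j1] + s[j0]``, i.e. the *last*
  listed input is the ``2**0`` input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CapacityError, DimensionError, NetworkValidationError

__all__ = [
    "BooleanNetwork",
    "NetworkState",
    "Attractor",
    "AttractorSet",
    "synchronous_update",
    "trajectory_to_attractor",
    "find_attractors",
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
]

#: Default node-count cap for exhaustive (2**n) enumeration.
DEFAULT_EXHAUSTIVE_CAP = 20


@dataclass(frozen=True)
class NetworkState:
    """One expression state of an ``n``-node network.

    ``bits[i]`` is the value of node ``i``; ``int_code`` packs the bits with
    node 0 as the least-significant bit.
    """

    bits: tuple[int, ...]
    int_code: int

    @classmethod
    def from_bits(cls, bits: Sequence[int]) -> "NetworkState":
        bits = tuple(int(b) for b in bits)
        if any(b not in (0, 1) for b in bits):
            raise DimensionError(f"state bits must be 0/1, got {bits}")
        code = 0
        for i, b in enumerate(bits):
            code |= b << i
        return cls(bits=bits, int_code=code)

    @classmethod
    def from_int(cls, code: int, n: int) -> "NetworkState":
        if not 0 <= code < (1 << n):
            raise DimensionError(f"int_code {code} out of range for n={n}")
        return cls(bits=tuple((code >> i) & 1 for i in range(n)), int_code=code)

    @property
    def n(self) -> int:
        return len(self.bits)

    def __str__(self) -> str:  # bit string, node 0 first
        return "".join(str(b) for b in self.bits)


@dataclass(frozen=True)
class BooleanNetwork:
    """An ``n``-node synchronous Boolean network.

    Parameters
    ----------
    node_names
        One identifier per node.
    inputs
        ``inputs[i]`` is the ordered tuple of input node indices of node
        ``i``, most-significant bit first (the last element is the ``2**0``
        input).
    truth_tables
        ``truth_tables[i][t]`` is node ``i``'s next value when its inputs
        spell the binary number ``t``; length must be ``2**len(inputs[i])``.
    """

    node_names: tuple[str, ...]
    inputs: tuple[tuple[int, ...], ...]
    truth_tables: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        n = len(self.node_names)
        object.__setattr__(self, "node_names", tuple(str(s) for s in self.node_names))
        object.__setattr__(
            self, "inputs", tuple(tuple(int(j) for j in row) for row in self.inputs)
        )
        object.__setattr__(
            self,
            "truth_tables",
            tuple(tuple(int(v) for v in row) for row in self.truth_tables),
        )
        if len(self.inputs) != n or len(self.truth_tables) != n:
            raise NetworkValidationError(
                "node_names, inputs and truth_tables must have equal length"
            )
        if n < 1:
            raise NetworkValidationError("a network needs at least one node")
        for i, (inp, tt) in enumerate(zip(self.inputs, self.truth_tables)):
            if any(not 0 <= j < n for j in inp):
                raise NetworkValidationError(f"node {i}: input index out of range")
            if len(tt) != (1 << len(inp)):
                raise NetworkValidationError(
                    f"node {i}: truth table length {len(tt)} != 2**{len(inp)}"
                )
            if any(v not in (0, 1) for v in tt):
                raise NetworkValidationError(f"node {i}: truth-table entries must be 0/1")

    @property
    def n(self) -> int:
        return len(self.node_names)

    def step_int(self, code: int) -> int:
        """Apply the deterministic map ``D`` to a single integer state code."""
        if not 0 <= code < (1 << self.n):
            raise DimensionError(f"state code {code} out of range for n={self.n}")
        out = 0
        for i in range(self.n):
            idx = 0
            for j in self.inputs[i]:
                idx = (idx << 1) | ((code >> j) & 1)
            out |= self.truth_tables[i][idx] << i
        return out

    def next_state_table(self) -> np.ndarray:
        """Vectorised ``D`` over all ``2**n`` states; entry ``x`` is ``D(x)``."""
        n = self.n
        codes = np.arange(1 << n, dtype=np.int64)
        out = np.zeros(1 << n, dtype=np.int64)
        for i in range(n):
            idx = np.zeros(1 << n, dtype=np.int64)
            for j in self.inputs[i]:
                idx = (idx << 1) | ((codes >> j) & 1)
            tt = np.asarray(self.truth_tables[i], dtype=np.int64)
            out |= tt[idx] << i
        return out


@dataclass(frozen=True)
class Attractor:
    """A point or cyclic attractor.

    ``states`` holds integer codes in cycle order starting from the
    smallest member; ``D`` maps each listed state to the next (and the last
    back to the first).
    """

    states: tuple[int, ...]
    kind: str  # "point" | "cyclic"
    basin_size: int

    def __len__(self) -> int:
        return len(self.states)

    @property
    def min_state(self) -> int:
        return self.states[0]


@dataclass(frozen=True)
class AttractorSet:
    """All attractors of a network plus the total basin map.

    ``basin_map[x]`` is the index (into ``attractors``) of the attractor
    reached noise-free from state ``x``.  Attractors are ordered by their
    smallest member state code, so the listing is reproducible.
    """

    attractors: tuple[Attractor, ...]
    basin_map: np.ndarray

    def __len__(self) -> int:
        return len(self.attractors)

    def attractor_of(self, code: int) -> int:
        return int(self.basin_map[code])


def synchronous_update(net: BooleanNetwork, state: NetworkState) -> NetworkState:
    """One synchronous step: every node applies its logic function at once."""
    if state.n != net.n:
        raise DimensionError(f"state has {state.n} bits, network has {net.n} nodes")
    return NetworkState.from_int(net.step_int(state.int_code), net.n)


def trajectory_to_attractor(
    net: BooleanNetwork, start: NetworkState
) -> tuple[tuple[int, ...], int]:
    """Iterate ``D`` from ``start`` until a state recurs.

    Returns ``(cycle_states, transient_length)`` where ``cycle_states`` are
    integer codes in the order first encountered on the cycle and
    ``transient_length`` counts the steps taken before entering it.
    Termination is guaranteed within ``2**n`` steps.
    """
    if start.n != net.n:
        raise DimensionError(f"state has {start.n} bits, network has {net.n} nodes")
    seen: dict[int, int] = {}
    code = start.int_code
    step = 0
    while code not in seen:
        seen[code] = step
        code = net.step_int(code)
        step += 1
    entry = seen[code]
    ordered = sorted(seen, key=seen.get)
    return tuple(ordered[entry:]), entry


def find_attractors(
    net: BooleanNetwork, max_n: int = DEFAULT_EXHAUSTIVE_CAP
) -> AttractorSet:
    """Exhaustively enumerate every attractor and the full basin map.

    All ``2**n`` states are resolved at once by pointer doubling on the
    functional graph of ``D``: composing ``D`` with itself ``n+1`` times
    yields ``D**(2**(n+1))``, which maps every state onto its attractor
    cycle (transients are shorter than ``2**n``).  Cost is ``O(n * 2**n)``.

    Raises :class:`CapacityError` for ``n > max_n``; raise the cap
    explicitly to go bigger.
    """
    n = net.n
    if n > max_n:
        raise CapacityError(
            f"exhaustive enumeration over 2**{n} states exceeds the cap "
            f"max_n={max_n}; pass a larger max_n explicitly to proceed"
        )
    step = net.next_state_table()
    reach = step.copy()
    for _ in range(n + 1):  # D^(2**(n+1)) : image is exactly the cycle states
        reach = reach[reach]
    cycle_states = np.unique(reach)

    on_cycle = set(int(s) for s in cycle_states)
    attractor_index: dict[int, int] = {}
    attractors_states: list[tuple[int, ...]] = []
    for s in cycle_states:  # ascending, so each cycle is met at its min member
        s = int(s)
        if s in attractor_index:
            continue
        cyc = [s]
        cur = int(step[s])
        while cur != s:
            cyc.append(cur)
            cur = int(step[cur])
        idx = len(attractors_states)
        attractors_states.append(tuple(cyc))
        for c in cyc:
            attractor_index[c] = idx

    cycle_attr = np.empty(1 << n, dtype=np.int64)
    cycle_attr.fill(-1)
    for c, idx in attractor_index.items():
        cycle_attr[c] = idx
    basin_map = cycle_attr[reach]
    sizes = np.bincount(basin_map, minlength=len(attractors_states))

    attractors = tuple(
        Attractor(
            states=states,
            kind="point" if len(states) == 1 else "cyclic",
            basin_size=int(sizes[i]),
        )
        for i, states in enumerate(attractors_states)
    )
    assert int(sizes.sum()) == 1 << n
    return AttractorSet(attractors=attractors, basin_map=basin_map)


# ---------------------------------------------------------------------------
# Network JSON dialect
# ---------------------------------------------------------------------------

def network_to_dict(net: BooleanNetwork) -> dict:
    """Serialise to the package's JSON dialect (bit-exact round trip)."""
    return {
        "nodes": list(net.node_names),
        "inputs": [list(row) for row in net.inputs],
        "truth_tables": [list(row) for row in net.truth_tables],
    }


def network_from_dict(d: dict) -> BooleanNetwork:
    try:
        return BooleanNetwork(
            node_names=tuple(d["nodes"]),
            inputs=tuple(tuple(r) for r in d["inputs"]),
            truth_tables=tuple(tuple(r) for r in d["truth_tables"]),
        )
    except KeyError as e:
        raise NetworkValidationError(f"network JSON missing key {e}") from e


def save_network(net: BooleanNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1)
        fh.write("\n")


def load_network(path) -> BooleanNetwork:
    with open(path) as fh:
        return network_from_dict(json.load(fh))
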