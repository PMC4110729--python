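import numpy as np
import pytest

from switchscape import BooleanNetwork


@pytest.fixture
def toggle():
    """Two genes, each the NOT of the other: the classic toggle switch.

    Attractors (synchronous): fixed points 10 and 01 plus the 2-cycle
    {00, 11}.
    """
    return BooleanNetwork(
        node_names=("a", "b"), inputs=((1,), (0,)), truth_tables=((1, 0), (1, 0))
    )


@pytest.fixture
def identity_net():
    """One self-copying gene: fixed points 0 and 1."""
    return BooleanNetwork(node_names=("x",), inputs=((0,),), truth_tables=((0, 1),))


@pytest.fixture
def copy_ring():
    """Four genes in a ring, each copying its neighbour (a permutation map)."""
    return BooleanNetwork(
        node_names=tuple("abcd"),
        inputs=(((1,), (2,), (3,), (0,))),
        truth_tables=tuple([(0, 1)] * 4),
    )


def random_network(rng: np.random.Generator, n: int, max_q: int = 3) -> BooleanNetwork:
    """An arbitrary (not necessarily critical) network for property tests."""
    inputs, tables = [], []
    for _ in range(n):
        q = int(rng.integers(1, min(max_q, n) + 1))
        inputs.append(tuple(int(j) for j in rng.choice(n, size=q, replace=False)))
        tables.append(tuple(int(v) for v in rng.integers(0, 2, size=1 << q)))
    return BooleanNetwork(
        node_names=tuple(f"g{i}" for i in range(n)),
        inputs=tuple(inputs),
        truth_tables=tuple(tables),
    )
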