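import numpy as np
import pytest

import genebreadth as gb


@pytest.fixture
def toy_ppi() -> gb.PPINetwork:
    """7-node graph: a star (h hub, 4 leaves) plus an edge pair and an isolate."""
    edges = [
        ("hub", "l1", 0.9), ("hub", "l2", 0.8), ("hub", "l3", 0.7),
        ("hub", "l4", 0.6), ("a", "b", 0.5),
    ]
    g = gb.PPINetwork.from_edges(edges)
    g.graph.add_node("iso")
    return g


@pytest.fixture
def toy_terms() -> gb.TermCollection:
    return gb.TermCollection(
        {"GO:1": "BP", "GO:2": "CC", "hsa1": "KEGG"},
        {"GO:1": frozenset({"l1", "l2", "a"}),
         "GO:2": frozenset({"l3", "b"}),
         "hsa1": frozenset({"l1", "l4", "hub"})},
    )


@pytest.fixture
def separable_data():
    """Linearly separable two-feature toy set (positive iff feature0 > 2)."""
    rng = np.random.default_rng(42)
    n = 80
    y = np.array([1] * 50 + [0] * 30)
    x0 = np.where(y == 1, rng.uniform(3, 5, n), rng.uniform(0, 1, n))
    x1 = rng.uniform(0, 1, n)
    return np.column_stack([x0, x1]), y


def brute_force_tail(N: int, M: int, n: int, m: int) -> float:
    """Independent oracle: enumerate the upper tail of the hypergeometric."""
    from math import comb

    total = 0
    for k in range(m, n + 1):
        if k > M or n - k > N - M:
            continue
        total += comb(M, k) * comb(N - M, n - k)
    return total / comb(N, n)
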