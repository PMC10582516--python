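import itertools
import os

import igraph as ig
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bionetkit as bk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATA_DIR = os.path.join(os.path.dirname(__file__), os.pardir, "data")


def clique_pair(size: int, bridges: int = 1) -> ig.Graph:
    """Two size-cliques joined by `bridges` edges (a0-b0, a1-b1, ...)."""
    edges = [(f"a{i}", f"a{j}") for i, j in itertools.combinations(range(size), 2)]
    edges += [(f"b{i}", f"b{j}") for i, j in itertools.combinations(range(size), 2)]
    edges += [(f"a{i}", f"b{i}") for i in range(bridges)]
    return bk.build_network(edges)


def random_named_graph(n: int, p: float, seed: int) -> ig.Graph:
    rng = np.random.default_rng(seed)
    edges = [
        (f"v{i:02d}", f"v{j:02d}")
        for i, j in itertools.combinations(range(n), 2)
        if rng.random() < p
    ]
    g = ig.Graph(n=n, edges=[], directed=False)
    g.vs["name"] = [f"v{i:02d}" for i in range(n)]
    if edges:
        idx = {v: k for k, v in enumerate(g.vs["name"])}
        g.add_edges([(idx[a], idx[b]) for a, b in edges])
    return g


def int_edges(g: ig.Graph) -> list[tuple[int, int]]:
    return [(e.source, e.target) for e in g.es]


@pytest.fixture
def path5() -> ig.Graph:
    return bk.build_network([("v1", "v2"), ("v2", "v3"), ("v3", "v4"), ("v4", "v5")])


@pytest.fixture
def star5() -> ig.Graph:
    return bk.build_network([("c", f"l{i}") for i in range(1, 5)])


@pytest.fixture
def triangle_plus_edge() -> ig.Graph:
    return bk.build_network([("A", "B"), ("B", "C"), ("C", "A"), ("D", "E")])


@pytest.fixture
def two_cliques5() -> ig.Graph:
    return clique_pair(5)
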