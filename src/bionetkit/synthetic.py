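"""Synthetic fixture generators with known ground truth.

Every generator is deterministic given its seed and echoes its parameters into
the returned object, so downstream statistics (planted community recovery,
power-law exponent recovery, separation signs, enrichment) can be checked
against construction-time truth without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .graph_core import build_bipartite
from .topology import sample_discrete_power_law

__all__ = [
    "PlantedGraph",
    "planted_partition",
    "power_law_degree_sample",
    "annotated_planted_graph",
    "toy_diseasome",
]


@dataclass
class PlantedGraph:
    """A planted-partition graph together with its ground-truth membership."""

    graph: ig.Graph
    true_membership: dict[str, int]
    params: dict


def _sample_pair_indices(total: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Uniformly sample Binomial(total, p) distinct indices from range(total)."""
    count = rng.binomial(total, p)
    if count == 0:
        return np.zeros(0, dtype=np.int64)
    picked: np.ndarray = np.unique(rng.integers(0, total, size=int(count * 1.2) + 8))
    while picked.size < count:
        extra = rng.integers(0, total, size=count)
        picked = np.unique(np.concatenate([picked, extra]))
    return rng.permutation(picked)[:count]


def planted_partition(
    n_blocks: int,
    block_size: int,
    p_in: float,
    p_out: float,
    seed: int | None = None,
) -> PlantedGraph:
    """Planted-partition graph: independent edge coin-flips with probability
    p_in inside a block and p_out between blocks."""
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if n_blocks < 1 or block_size < 1:
        raise ValueError("n_blocks and block_size must be positive")
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    width = len(str(n - 1))
    names = [f"v{i:0{width}d}" for i in range(n)]
    blocks = [list(range(b * block_size, (b + 1) * block_size)) for b in range(n_blocks)]
    edges: list[tuple[int, int]] = []
    s = block_size
    within_pairs = [(i, j) for i in range(s) for j in range(i + 1, s)]
    for b in range(n_blocks):
        base = b * s
        for t in _sample_pair_indices(len(within_pairs), p_in, rng):
            i, j = within_pairs[t]
            edges.append((base + i, base + j))
    for b1 in range(n_blocks):
        for b2 in range(b1 + 1, n_blocks):
            for t in _sample_pair_indices(s * s, p_out, rng):
                edges.append((b1 * s + int(t) // s, b2 * s + int(t) % s))
    g = ig.Graph(n=n, edges=edges, directed=False)
    g.vs["name"] = names
    membership = {names[v]: b + 1 for b, block in enumerate(blocks) for v in block}
    return PlantedGraph(
        graph=g,
        true_membership=membership,
        params={
            "n_blocks": n_blocks,
            "block_size": block_size,
            "p_in": p_in,
            "p_out": p_out,
            "seed": seed,
        },
    )


def power_law_degree_sample(
    alpha: float, xmin: int, n: int, seed: int | None = None
) -> np.ndarray:
    """n i.i.d. draws from the discrete power law p(k) ∝ k^-alpha, k >= xmin."""
    return sample_discrete_power_law(alpha, xmin, n, seed=seed)


def annotated_planted_graph(
    pg: PlantedGraph,
    n_terms: int,
    term_size: int,
    overlap_mode: str = "random",
    seed: int | None = None,
) -> pd.DataFrame:
    """Annotation table whose term placement has a known relationship to the
    planted blocks.

    ``same_block``
        consecutive term pairs (T0,T1), (T2,T3), ... are sampled inside the
        same block, so those pairs overlap topologically and each term is
        enriched in its block's community.
    ``cross_block``
        term t is placed in block t mod n_blocks, so consecutive terms land in
        different blocks and their pairs separate.
    ``random``
        vertices sampled uniformly from the whole graph: a calibrated null.
    """
    if overlap_mode not in ("same_block", "cross_block", "random"):
        raise ValueError(f"unknown overlap_mode {overlap_mode!r}")
    params = pg.params
    nb, s = params["n_blocks"], params["block_size"]
    if overlap_mode != "random" and term_size > s:
        raise ValueError("term_size must not exceed block size for block modes")
    if overlap_mode == "random" and term_size > nb * s:
        raise ValueError("term_size exceeds number of vertices")
    rng = np.random.default_rng(seed)
    names = pg.graph.vs["name"]
    rows = []
    for t in range(n_terms):
        if overlap_mode == "random":
            pool = np.arange(nb * s)
        elif overlap_mode == "same_block":
            b = (t // 2) % nb
            pool = np.arange(b * s, (b + 1) * s)
        else:  # cross_block: consecutive terms in different blocks
            b = t % nb
            pool = np.arange(b * s, (b + 1) * s)
        chosen = rng.choice(pool, size=term_size, replace=False)
        tid = f"T{t:03d}"
        rows += [
            {"term_id": tid, "term_name": f"term {t}", "vertex_id": names[int(v)]}
            for v in sorted(chosen)
        ]
    return pd.DataFrame(rows, columns=["term_id", "term_name", "vertex_id"])


def toy_diseasome(
    n_dis: int,
    n_genes: int,
    edges_per_disease: int,
    seed: int | None = None,
) -> ig.Graph:
    """Random bipartite disease–gene network: each disease is linked to
    ``edges_per_disease`` distinct random genes. Diseases form the left part,
    genes the right."""
    if n_dis < 1 or n_genes < 1 or edges_per_disease < 1:
        raise ValueError("counts must be positive")
    if edges_per_disease > n_genes:
        raise ValueError("edges_per_disease cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    wd, wg = len(str(n_dis - 1)), len(str(n_genes - 1))
    rows = []
    for d in range(n_dis):
        genes = rng.choice(n_genes, size=edges_per_disease, replace=False)
        rows += [(f"D{d:0{wd}d}", f"g{int(g):0{wg}d}") for g in sorted(genes)]
    return build_bipartite(rows)
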