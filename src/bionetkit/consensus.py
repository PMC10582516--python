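"""Consensus clustering: co-clustering matrices from resampled runs, per-cluster
robustness, and per-vertex bridgeness.

The consensus matrix M records, for every vertex pair, the fraction of
resampled clustering runs that placed the two vertices in the same community,
out of the runs in which both were sampled. Cluster robustness is the mean of
M over pairs inside a cluster; bridgeness converts each vertex's consensus row
into an affiliation distribution over the communities of a reference
clustering and measures how far it is from being concentrated on one
community: B = 0 means the vertex clearly belongs to a single community,
B = 1 means it bridges every community with equal strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .community import Clustering, cluster
from .graph_core import vertex_names

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusMatrix",
    "consensus_matrix",
    "cluster_robustness",
    "bridgeness",
    "influence_table",
]


@dataclass
class ConsensusMatrix:
    """Symmetric vertex-by-vertex co-clustering frequency matrix."""

    ids: list[str]
    matrix: np.ndarray
    sample_fraction: float
    reps: int
    algorithm: str
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def consensus_matrix(
    net: ig.Graph,
    algorithm: str,
    sample_fraction: float = 0.8,
    reps: int = 500,
    seed: int | None = None,
) -> ConsensusMatrix:
    """Build a consensus matrix by repeatedly clustering random vertex subsamples.

    Each rep draws ``sample_fraction`` of the vertices uniformly without
    replacement, clusters the induced subgraph, and accumulates co-membership
    counts. M_ij = (# runs with i, j together) / (# runs where both were
    sampled); pairs never co-sampled get 0 (their count is logged). Per-rep
    seeds derive from the master seed by a spawned seed sequence (rep order is
    the counter).
    """
    if not 0.0 < sample_fraction <= 1.0:
        raise ValueError("sample_fraction must be in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    names = vertex_names(net)
    n = len(names)
    k = max(1, int(round(sample_fraction * n)))
    together = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(reps)
    for child in children:
        rng = np.random.default_rng(child)
        sample = np.sort(rng.choice(n, size=k, replace=False))
        sub = net.induced_subgraph(sample.tolist())
        cl = cluster(sub, algorithm, seed=int(child.generate_state(1)[0] % 2**31))
        co_sampled[np.ix_(sample, sample)] += 1.0
        sub_names = vertex_names(sub)
        for comm in cl.communities():
            idx = np.array([int(sample[sub_names.index(v)]) for v in comm])
            together[np.ix_(idx, idx)] += 1.0
    never = int((co_sampled[np.triu_indices(n, 1)] == 0).sum())
    if never:
        logger.info("consensus_matrix: %d vertex pairs never co-sampled (entries set to 0)", never)
    with np.errstate(invalid="ignore"):
        M = np.where(co_sampled > 0, together / np.maximum(co_sampled, 1), 0.0)
    return ConsensusMatrix(
        ids=names,
        matrix=M,
        sample_fraction=sample_fraction,
        reps=reps,
        algorithm=algorithm,
        seed=seed,
    )


def _check_vertices(cm: ConsensusMatrix, clustering: Clustering) -> None:
    if set(cm.ids) != set(clustering.membership):
        raise ValueError("consensus matrix and clustering cover different vertex sets")


def cluster_robustness(cm: ConsensusMatrix, clustering: Clustering) -> pd.Series:
    """Mean consensus value over vertex pairs inside each cluster.

    Ranges from 0 (the subsampled runs never reproduce the cluster) to 1 (they
    always do). Singleton clusters are 1 by convention (no pair to disagree).
    """
    _check_vertices(cm, clustering)
    pos = {v: i for i, v in enumerate(cm.ids)}
    out = {}
    for c, members in enumerate(clustering.communities(), start=1):
        idx = np.array([pos[v] for v in members])
        if idx.size < 2:
            out[c] = 1.0
            continue
        sub = cm.matrix[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, 1)
        out[c] = float(sub[iu].mean())
    return pd.Series(out, name="robustness").rename_axis("community")


def bridgeness(cm: ConsensusMatrix, clustering: Clustering) -> pd.DataFrame:
    """Per-vertex bridgeness from consensus affiliations.

    Vertex i's affiliation with community c is the sum of its consensus entries
    over c's members (itself excluded), renormalized to a probability vector
    p_i; all-zero rows get the uniform affiliation. Then
    B_i = 1 - sqrt(K/(K-1)) * ||p_i - 1/K||_2, which is 0 when p_i is
    concentrated on one community and 1 when p_i is uniform over the K
    communities.
    """
    _check_vertices(cm, clustering)
    K = clustering.n_communities
    if K < 2:
        raise ValueError("bridgeness undefined for a single community")
    pos = {v: i for i, v in enumerate(cm.ids)}
    comm_idx = [np.array([pos[v] for v in members]) for members in clustering.communities()]
    n = len(cm.ids)
    P = np.zeros((n, K))
    for c, idx in enumerate(comm_idx):
        P[:, c] = cm.matrix[:, idx].sum(axis=1)
        P[idx, c] -= np.diag(cm.matrix)[idx]  # exclude self-affiliation
    totals = P.sum(axis=1)
    zero = totals <= 0
    P[zero] = 1.0 / K
    P[~zero] = P[~zero] / totals[~zero, None]
    dev = np.sqrt(((P - 1.0 / K) ** 2).sum(axis=1))
    B = 1.0 - np.sqrt(K / (K - 1.0)) * dev
    return pd.DataFrame({"vertex_id": cm.ids, "bridgeness": np.clip(B, 0.0, 1.0)})


def influence_table(
    bt: pd.DataFrame,
    centrality: pd.Series | dict,
    b_threshold: float = 0.5,
    c_threshold: float = 0.5,
    centrality_name: str = "centrality",
) -> pd.DataFrame:
    """Pair bridgeness with a normalized centrality and label the quadrants.

    The centrality must be normalized to [0, 1] (e.g. semi-local centrality or
    PageRank divided by its maximum). Quadrants at the (0.5, 0.5) thresholds:
    high B / low C = "global bridge", low B / high C = "local hub",
    high B / high C = "bridging hub", low B / low C = "peripheral".
    """
    cent = pd.Series(centrality, dtype=float)
    if set(cent.index) != set(bt["vertex_id"]):
        raise ValueError("centrality and bridgeness tables cover different vertex sets")
    vals = cent.to_numpy()
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("centrality must be normalized to [0, 1]")
    out = bt.copy()
    out[centrality_name] = [cent[v] for v in out["vertex_id"]]

    def label(b: float, c: float) -> str:
        if b >= b_threshold:
            return "bridging hub" if c >= c_threshold else "global bridge"
        return "local hub" if c >= c_threshold else "peripheral"

    out["quadrant"] = [label(b, c) for b, c in zip(out["bridgeness"], out[centrality_name])]
    return out
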