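"""Vertex centrality measures and randomized-graph null models.

The centrality matrix follows the usual seven-measure panel for undirected
protein-interaction networks:

==== =========================================================================
DEG  vertex degree
BET  betweenness (raw shortest-path pair counts, unnormalized)
CC   local clustering coefficient (0 for degree < 2)
SL   semi-local centrality, normalized to [0, 1] by the maximum value
mnSP mean shortest-path length to reachable vertices
PR   PageRank (damping 0.85), sums to 1
sdSP standard deviation of shortest-path lengths to reachable vertices
==== =========================================================================

Shortest-path statistics are computed within components: unreachable pairs are
dropped (and counted in a log message) rather than imputed.
"""

from __future__ import annotations

import logging
import random

import igraph as ig
import numpy as np
import pandas as pd

from .graph_core import vertex_names

logger = logging.getLogger(__name__)

__all__ = [
    "calc_centrality",
    "semi_local_centrality",
    "random_graph",
    "compare_to_random",
    "CENTRALITY_COLUMNS",
]

CENTRALITY_COLUMNS = ("DEG", "BET", "CC", "SL", "mnSP", "PR", "sdSP")

PAGERANK_DAMPING = 0.85


def semi_local_centrality(net: ig.Graph, normalize: bool = False) -> np.ndarray:
    """Semi-local centrality: a two-hop aggregation of neighbourhood sizes.

    With N(w) the number of distinct vertices within distance <= 2 of w
    (excluding w itself), Q(u) = sum of N(w) over neighbours w of u, and
    CL(v) = sum of Q(u) over neighbours u of v. Isolated vertices score 0.
    If ``normalize``, values are divided by the maximum CL so they lie in [0, 1].
    """
    n = net.vcount()
    if n == 0:
        return np.zeros(0)
    # neighborhood_size counts the vertex itself
    N = np.asarray(net.neighborhood_size(order=2), dtype=float) - 1.0
    adj = net.get_adjlist()
    Q = np.array([sum(N[w] for w in adj[u]) for u in range(n)])
    CL = np.array([sum(Q[u] for u in adj[v]) for v in range(n)])
    if normalize:
        top = CL.max()
        if top > 0:
            CL = CL / top
    return CL


def _sp_stats(net: ig.Graph) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex mean and sd of finite shortest-path lengths (self excluded)."""
    n = net.vcount()
    mn = np.zeros(n)
    sd = np.zeros(n)
    dropped = 0
    d = np.asarray(net.distances(), dtype=float)
    np.fill_diagonal(d, np.inf)
    for i in range(n):
        row = d[i]
        finite = row[np.isfinite(row)]
        dropped += (n - 1) - finite.size
        if finite.size:
            mn[i] = finite.mean()
            sd[i] = finite.std()  # population sd; 0 for a single reachable vertex
    if dropped:
        logger.info("shortest-path stats: %d unreachable vertex pairs dropped", dropped)
    return mn, sd


def calc_centrality(net: ig.Graph) -> pd.DataFrame:
    """Compute the 7-column centrality matrix, indexed by vertex ID."""
    if net.vcount() == 0:
        raise ValueError("empty graph")
    deg = np.asarray(net.degree(), dtype=int)
    bet = np.asarray(net.betweenness(), dtype=float)
    cc = np.asarray(net.transitivity_local_undirected(mode="zero"), dtype=float)
    sl = semi_local_centrality(net, normalize=True)
    mnsp, sdsp = _sp_stats(net)
    pr = np.asarray(net.pagerank(damping=PAGERANK_DAMPING), dtype=float)
    df = pd.DataFrame(
        {
            "DEG": deg,
            "BET": bet,
            "CC": cc,
            "SL": sl,
            "mnSP": mnsp,
            "PR": pr,
            "sdSP": sdsp,
        },
        index=pd.Index(vertex_names(net), name="vertex_id"),
    )
    return df


def random_graph(
    model: str,
    params: dict | None = None,
    seed: int | None = None,
    template: ig.Graph | None = None,
) -> ig.Graph:
    """Generate a randomized graph under one of three null models.

    ``gnp``
        Erdős–Rényi G(n, p); params ``n``, ``p``.
    ``barabasi_albert``
        Preferential attachment; params ``n``, ``m`` (edges added per vertex).
    ``perturb``
        Copy of ``template`` after ``n_add`` random non-edges are added and
        ``n_remove`` random existing edges removed (both default 0).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if seed is not None:
        random.seed(int(rng.integers(2**31)))  # igraph generators draw from `random`
    if model == "gnp":
        n, p = int(params["n"]), float(params["p"])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p must be in [0,1], got {p}")
        g = ig.Graph.Erdos_Renyi(n=n, p=p)
    elif model == "barabasi_albert":
        n, m = int(params["n"]), int(params["m"])
        if m >= n:
            raise ValueError(f"need m < n, got m={m}, n={n}")
        g = ig.Graph.Barabasi(n=n, m=m)
        g.simplify(multiple=True, loops=True)
    elif model == "perturb":
        if template is None:
            raise ValueError("perturb model needs a template graph")
        n_add = int(params.get("n_add", 0))
        n_remove = int(params.get("n_remove", 0))
        g = template.copy()
        for _ in range(n_add):
            non_edges = _sample_non_edge(g, rng)
            if non_edges is None:
                break
            g.add_edge(*non_edges)
        if n_remove > 0:
            k = min(n_remove, g.ecount())
            drop = rng.choice(g.ecount(), size=k, replace=False)
            g.delete_edges(sorted(int(e) for e in drop))
        return g
    else:
        raise ValueError(f"unknown model {model!r}")
    g.vs["name"] = [f"v{i}" for i in range(g.vcount())]
    return g


def _sample_non_edge(g: ig.Graph, rng: np.random.Generator, max_tries: int = 1000):
    n = g.vcount()
    if n < 2:
        return None
    for _ in range(max_tries):
        i, j = rng.integers(0, n, size=2)
        if i != j and g.get_eid(int(i), int(j), error=False) < 0:
            return int(i), int(j)
    return None


def compare_to_random(
    net: ig.Graph,
    measure: str,
    model: str = "gnp",
    n_reps: int = 100,
    seed: int | None = None,
    model_params: dict | None = None,
) -> pd.DataFrame:
    """Compare observed centrality values to an ensemble of size-matched
    randomized graphs.

    The null ensemble matches the observed vertex and edge counts (gnp with
    p = 2m/(n(n-1)); Barabási–Albert with m ≈ |E|/|V|; perturb on the observed
    graph). Because random graphs have no vertex correspondence with the
    observed one, values are compared rank-by-rank: row k holds the observed
    k-th largest value next to the null mean/sd of k-th largest values.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if measure not in CENTRALITY_COLUMNS:
        raise ValueError(f"unknown measure {measure!r}")
    n, m = net.vcount(), net.ecount()
    obs = np.sort(calc_centrality(net)[measure].to_numpy())[::-1]
    if model_params is None:
        if model == "gnp":
            model_params = {"n": n, "p": 2 * m / (n * (n - 1)) if n > 1 else 0.0}
        elif model == "barabasi_albert":
            model_params = {"n": n, "m": max(1, round(m / n))}
        else:
            model_params = {"n_add": 0, "n_remove": 0}
    ss = np.random.SeedSequence(seed)
    null = np.empty((n_reps, n))
    for r, child in enumerate(ss.spawn(n_reps)):
        g = random_graph(
            model,
            model_params,
            seed=int(child.generate_state(1)[0] % 2**31),
            template=net if model == "perturb" else None,
        )
        vals = np.sort(calc_centrality(g)[measure].to_numpy())[::-1]
        if vals.size != n:  # perturb keeps n; gnp/ba are built with n
            vals = np.resize(vals, n)
        null[r] = vals
    return pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "observed": obs,
            "null_mean": null.mean(axis=0),
            "null_sd": null.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(n),
        }
    )
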