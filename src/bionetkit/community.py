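"""Community detection, modularity measures, re-clustering, summaries and
cluster-driven layout.

Standard algorithms (fast-greedy ``fc``, walktrap ``wt``, spin-glass ``sg``,
leading-eigenvector ``lec``, ``louvain``, ``infomap``) are delegated to igraph.
``spectral`` is a native implementation of recursive modularity-matrix
bisection with Kernighan–Lin-style fine-tuning: after each leading-eigenvector
split, sweeps move one vertex at a time between the two groups (each vertex at
most once per sweep, best visited state kept) until no sweep improves Q.

Memberships are canonical: community indices are 1-based and consecutive,
numbered by the order of each community's lexicographically smallest vertex ID,
so results are stable under vertex relabeling.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd

from .graph_core import vertex_names

logger = logging.getLogger(__name__)

__all__ = [
    "Clustering",
    "ALGORITHMS",
    "cluster",
    "spectral_cluster",
    "modularity",
    "normalized_modularity",
    "NormalizedModularity",
    "recluster",
    "clustering_summary",
    "cluster_layout",
]

ALGORITHMS = ("fc", "wt", "sg", "lec", "louvain", "infomap", "spectral")

_TOL = 1e-9


@dataclass
class Clustering:
    """A partition of a network's vertices.

    ``membership`` maps vertex ID to a 1-based, consecutive community index;
    ``modularity`` is Newman's Q recomputed from the membership.
    """

    algorithm: str
    membership: dict[str, int]
    modularity: float
    params: dict = field(default_factory=dict)

    @property
    def n_communities(self) -> int:
        return max(self.membership.values()) if self.membership else 0

    def communities(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_communities)]
        for v, c in self.membership.items():
            out[c - 1].append(v)
        return [sorted(c) for c in out]

    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities()]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"vertex_id": sorted(self.membership), "community": [self.membership[v] for v in sorted(self.membership)]}
        )


def _canonical_membership(names: list[str], labels: list[int]) -> dict[str, int]:
    """Renumber communities 1..K by order of each community's smallest vertex ID."""
    groups: dict[int, list[str]] = {}
    for name, lab in zip(names, labels):
        groups.setdefault(lab, []).append(name)
    order = sorted(groups, key=lambda lab: min(groups[lab]))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return {name: remap[lab] for name, lab in zip(names, labels)}


def modularity(net: ig.Graph, membership) -> float:
    """Newman modularity Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)."""
    m = net.ecount()
    if m == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    labels = _membership_vector(net, membership)
    k = np.asarray(net.degree(), dtype=float)
    n_comm = max(labels) + 1
    within = np.zeros(n_comm)
    for e in net.es:
        if labels[e.source] == labels[e.target]:
            within[labels[e.source]] += 1.0
    deg_sum = np.zeros(n_comm)
    for i, lab in enumerate(labels):
        deg_sum[lab] += k[i]
    return float((within / m - (deg_sum / (2.0 * m)) ** 2).sum())


def _membership_vector(net: ig.Graph, membership) -> list[int]:
    """0-based membership list aligned with graph vertex order."""
    if isinstance(membership, Clustering):
        membership = membership.membership
    if isinstance(membership, dict):
        missing = [v for v in vertex_names(net) if v not in membership]
        if missing:
            raise ValueError(f"membership missing vertices, e.g. {missing[:3]}")
        raw = [membership[v] for v in vertex_names(net)]
    else:
        raw = list(membership)
        if len(raw) != net.vcount():
            raise ValueError("membership length does not match vertex count")
    uniq = {lab: i for i, lab in enumerate(dict.fromkeys(raw))}
    return [uniq[lab] for lab in raw]


def _singleton_clustering(net: ig.Graph, algorithm: str) -> Clustering:
    names = vertex_names(net)
    return Clustering(
        algorithm=algorithm,
        membership=_canonical_membership(names, list(range(len(names)))),
        modularity=0.0,
    )


def cluster(
    net: ig.Graph,
    algorithm: str,
    seed: int | None = None,
    spins: int = 25,
    walktrap_steps: int = 4,
) -> Clustering:
    """Run a community-detection algorithm and return a canonical Clustering.

    ``fc``/``wt``/``lec`` are deterministic; ``louvain``/``sg``/``infomap`` are
    seeded through ``seed``. ``spins`` sets the spin-glass state count (the
    sgG1/sgG2/sgG5 summary variants are this algorithm at different spin
    counts). A graph with no edges yields all-singleton communities with Q = 0.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if net.ecount() == 0:
        return _singleton_clustering(net, algorithm)
    if algorithm == "spectral":
        return spectral_cluster(net, fine_tune=True)
    if seed is not None:
        random.seed(seed)  # python-igraph draws from the stdlib `random` RNG
    if algorithm == "fc":
        vc = net.community_fastgreedy().as_clustering()
    elif algorithm == "wt":
        vc = net.community_walktrap(steps=walktrap_steps).as_clustering()
    elif algorithm == "lec":
        vc = net.community_leading_eigenvector()
    elif algorithm == "louvain":
        vc = net.community_multilevel()
    elif algorithm == "infomap":
        vc = net.community_infomap()
    else:  # sg
        if not net.is_connected():
            raise ValueError("spin-glass clustering requires a connected graph")
        vc = net.community_spinglass(spins=spins)
    names = vertex_names(net)
    membership = _canonical_membership(names, list(vc.membership))
    params = {"seed": seed}
    if algorithm == "sg":
        params["spins"] = spins
    return Clustering(
        algorithm=algorithm,
        membership=membership,
        modularity=modularity(net, membership),
        params=params,
    )


# --- native spectral bisection with fine-tuning -------------------------------


def _leading_eig(Bg: np.ndarray) -> tuple[float, np.ndarray]:
    w, v = np.linalg.eigh(Bg)
    return float(w[-1]), v[:, -1]


def _fine_tune(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan–Lin sweeps on a bisection vector s in {-1,+1}^n.

    Each sweep moves every vertex at most once (greedy best flip at each step,
    even if locally negative), then keeps the best state visited. Sweeps repeat
    while they improve s^T B s by more than a small tolerance.
    """
    n = s.size
    best = s.copy()
    q = lambda v: float(v @ Bg @ v)
    best_q = q(best)
    improved = True
    while improved:
        improved = False
        s_cur = best.copy()
        q_cur = best_q
        Bs = Bg @ s_cur
        moved = np.zeros(n, dtype=bool)
        sweep_best_q = best_q
        sweep_best = best.copy()
        for _ in range(n):
            # gain of flipping i: q' - q = -4 s_i (Bs)_i + 4 B_ii
            gains = -4.0 * s_cur * Bs + 4.0 * np.diag(Bg)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            q_cur += gains[i]
            s_cur[i] = -s_cur[i]
            Bs = Bs + 2.0 * s_cur[i] * Bg[:, i]
            moved[i] = True
            if q_cur > sweep_best_q + _TOL:
                sweep_best_q = q_cur
                sweep_best = s_cur.copy()
        if sweep_best_q > best_q + _TOL:
            best_q = sweep_best_q
            best = sweep_best
            improved = True
    return best


def _refine_partition(B: np.ndarray, labels: np.ndarray, tol: float) -> np.ndarray:
    """Greedy single-vertex moves between existing communities while ΔQ > 0.

    Divisive bisection is greedy, so a split made early can strand single
    vertices in the wrong community; this partition-level pass relocates them.
    Only strictly improving moves are accepted, so the refined partition never
    has lower Q than its input.
    """
    labels = labels.copy()
    comms = sorted(set(labels.tolist()))
    index = {c: j for j, c in enumerate(comms)}
    lab = np.array([index[c] for c in labels])
    K = len(comms)
    if K < 2:
        return labels
    ind = np.zeros((labels.size, K))
    ind[np.arange(labels.size), lab] = 1.0
    W = B @ ind  # W[i, c] = sum of B_ij over j in community c
    diag = np.diag(B)
    while True:
        own = W[np.arange(lab.size), lab] - diag
        gains = W - own[:, None]  # Δ(2mQ)/2 of moving i into each community
        gains[np.arange(lab.size), lab] = -np.inf
        i = int(np.argmax(gains.max(axis=1)))
        d = int(np.argmax(gains[i]))
        if gains[i, d] <= tol:
            break
        c = lab[i]
        lab[i] = d
        W[:, c] -= B[:, i]
        W[:, d] += B[:, i]
    return lab


def spectral_cluster(net: ig.Graph, fine_tune: bool = True, tol: float = _TOL) -> Clustering:
    """Recursive modularity-matrix bisection (leading eigenvector), optionally
    with Kernighan–Lin fine-tuning after every split.

    Disconnected graphs are clustered per component. Recursion on a vertex
    group g uses the generalized modularity matrix
    B(g)_ij = B_ij - delta_ij * sum_{k in g} B_ik, and stops when the leading
    eigenvalue is <= tol or the proposed split does not increase Q. With
    ``fine_tune``, Kernighan–Lin sweeps refine each bisection and a final
    partition-level pass relocates single vertices between communities while
    it improves Q.
    """
    names = vertex_names(net)
    if net.ecount() == 0:
        return _singleton_clustering(net, "spectral" if fine_tune else "lec")
    m = net.ecount()
    A = np.asarray(net.get_adjacency().data, dtype=float)
    k = A.sum(axis=1)
    B = A - np.outer(k, k) / (2.0 * m)
    def bisect_all(tune: bool) -> np.ndarray:
        labels = np.full(net.vcount(), -1, dtype=int)
        next_label = [0]

        def assign(idx: np.ndarray) -> None:
            labels[idx] = next_label[0]
            next_label[0] += 1

        def divide(idx: np.ndarray) -> None:
            if idx.size == 1:
                assign(idx)
                return
            Bsub = B[np.ix_(idx, idx)]
            Bg = Bsub - np.diag(Bsub.sum(axis=1))
            lam, vec = _leading_eig(Bg)
            if lam <= tol:
                assign(idx)
                return
            s = np.where(vec >= 0.0, 1.0, -1.0)
            if tune:
                s = _fine_tune(Bg, s)
            dq = float(s @ Bg @ s) / (4.0 * m)
            if dq <= tol or np.all(s == s[0]):
                assign(idx)
                return
            divide(idx[s > 0])
            divide(idx[s < 0])

        for comp in net.connected_components():
            divide(np.asarray(comp, dtype=int))
        return labels

    def partition_q(labels: np.ndarray) -> float:
        total = 0.0
        for c in set(labels.tolist()):
            idx = np.flatnonzero(labels == c)
            total += B[np.ix_(idx, idx)].sum()
        return total / (2.0 * m)

    labels = bisect_all(tune=fine_tune)
    if fine_tune:
        # Divisive bisection is greedy: refine both the tuned and the untuned
        # recursion at the partition level and keep the better candidate, so
        # fine-tuning can never return a worse partition than plain bisection.
        candidates = [_refine_partition(B, labels, tol), _refine_partition(B, bisect_all(tune=False), tol)]
        labels = max(candidates, key=partition_q)
    membership = _canonical_membership(names, labels.tolist())
    return Clustering(
        algorithm="spectral" if fine_tune else "lec",
        membership=membership,
        modularity=modularity(net, membership),
        params={"fine_tune": fine_tune},
    )


# --- normalized modularity ----------------------------------------------------


@dataclass
class NormalizedModularity:
    q_norm: float
    q_obs: float
    null_mean: float
    null_sd: float
    n_rand: int


def normalized_modularity(
    net: ig.Graph,
    clustering: Clustering,
    n_rand: int = 10,
    seed: int | None = None,
) -> NormalizedModularity:
    """Observed Q divided by the mean Q obtained by re-clustering
    degree-preserving rewired copies of the network with the same algorithm."""
    if n_rand < 10:
        raise ValueError("n_rand must be >= 10")
    if not clustering.algorithm:
        raise ValueError("clustering has no algorithm label")
    ss = np.random.SeedSequence(seed)
    null_q = np.empty(n_rand)
    for r, child in enumerate(ss.spawn(n_rand)):
        sub_seed = int(child.generate_state(1)[0] % 2**31)
        random.seed(sub_seed)
        g = net.copy()
        g.rewire(n=10 * g.ecount())  # degree-preserving double-edge swaps
        cl = cluster(g, clustering.algorithm, seed=sub_seed, **{
            k: v for k, v in clustering.params.items() if k == "spins"
        })
        null_q[r] = cl.modularity
    mean = float(null_q.mean())
    return NormalizedModularity(
        q_norm=clustering.modularity / mean if mean != 0 else math.inf,
        q_obs=clustering.modularity,
        null_mean=mean,
        null_sd=float(null_q.std(ddof=1)),
        n_rand=n_rand,
    )


# --- re-clustering ------------------------------------------------------------


def recluster(
    net: ig.Graph,
    clustering: Clustering,
    size_threshold: int,
    algorithm: str | None = None,
    seed: int | None = None,
    recurse: bool = False,
) -> Clustering:
    """Split oversized communities by re-running a clustering algorithm on each
    community's induced subgraph.

    Communities larger than ``size_threshold`` are replaced by their
    sub-communities; indices are renumbered consecutively. With ``recurse``,
    passes repeat until no community exceeds the threshold or a pass changes
    nothing.
    """
    if size_threshold < 2:
        raise ValueError("size_threshold must be >= 2")
    algorithm = algorithm or clustering.algorithm
    names = vertex_names(net)
    name_to_idx = {v: i for i, v in enumerate(names)}
    current = dict(clustering.membership)
    while True:
        groups: dict[int, list[str]] = {}
        for v, c in current.items():
            groups.setdefault(c, []).append(v)
        changed = False
        new_labels: dict[str, tuple] = {}
        for c, members in groups.items():
            if len(members) <= size_threshold:
                for v in members:
                    new_labels[v] = (c, 0)
                continue
            sub = net.induced_subgraph([name_to_idx[v] for v in members])
            sub_cl = cluster(sub, algorithm, seed=seed)
            if sub_cl.n_communities > 1:
                changed = True
            for v, sc in sub_cl.membership.items():
                new_labels[v] = (c, sc)
        flat = {v: lab for v, lab in new_labels.items()}
        uniq = {lab: i for i, lab in enumerate(dict.fromkeys(flat[v] for v in names))}
        current = {v: uniq[flat[v]] for v in names}
        if not (recurse and changed):
            break
    membership = _canonical_membership(names, [current[v] for v in names])
    q = modularity(net, membership) if net.ecount() else 0.0
    return Clustering(
        algorithm=f"{clustering.algorithm}+{algorithm}",
        membership=membership,
        modularity=q,
        params={"size_threshold": size_threshold, "recurse": recurse},
    )


# --- summaries ----------------------------------------------------------------

SUMMARY_COLUMNS = (
    "N", "mod", "C", "Cn1", "Cn100", "mu",
    "Min. C", "1st Qu. C", "Median C", "Mean C", "3rd Qu. C", "Max. C",
)


def clustering_summary(
    net: ig.Graph,
    clusterings: list[Clustering],
    large_size: int = 100,
) -> pd.DataFrame:
    """Per-algorithm summary: modularity, community counts (total, singletons,
    >= ``large_size``), the fraction mu of edges between communities, and the
    quartile summary of community sizes."""
    rows = {}
    names = set(vertex_names(net))
    m = net.ecount()
    for cl in clusterings:
        if set(cl.membership) != names:
            raise ValueError(f"clustering {cl.algorithm!r} is not over this network's vertices")
        sizes = np.asarray(cl.sizes())
        if m:
            labels = _membership_vector(net, cl)
            between = sum(1 for e in net.es if labels[e.source] != labels[e.target])
            mu = between / m
            mod = cl.modularity
        else:
            mu, mod = 0.0, 0.0
        rows[cl.algorithm] = {
            "N": net.vcount(),
            "mod": mod,
            "C": sizes.size,
            "Cn1": int((sizes == 1).sum()),
            "Cn100": int((sizes >= large_size).sum()),
            "mu": mu,
            "Min. C": float(sizes.min()),
            "1st Qu. C": float(np.quantile(sizes, 0.25)),
            "Median C": float(np.median(sizes)),
            "Mean C": float(sizes.mean()),
            "3rd Qu. C": float(np.quantile(sizes, 0.75)),
            "Max. C": float(sizes.max()),
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(SUMMARY_COLUMNS))


# --- layout -------------------------------------------------------------------


def cluster_layout(net: ig.Graph, membership, seed: int | None = 0) -> pd.DataFrame:
    """Cluster-driven 2-D layout: each community is laid out independently with
    Fruchterman–Reingold, scaled to a radius proportional to sqrt(size), and
    placed on a grid (largest community first) so community bounding boxes
    never overlap. Deterministic given the seed."""
    labels = _membership_vector(net, membership)
    names = vertex_names(net)
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    order = sorted(groups, key=lambda lab: (-len(groups[lab]), min(names[i] for i in groups[lab])))
    r_max = max(math.sqrt(len(groups[lab])) for lab in order)
    pitch = 2.0 * r_max * 1.1
    ncol = math.ceil(math.sqrt(len(order)))
    coords = np.zeros((net.vcount(), 2))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(order))
    for slot, (lab, child) in enumerate(zip(order, children)):
        idx = groups[lab]
        sub = net.induced_subgraph(idx)
        random.seed(int(child.generate_state(1)[0] % 2**31))
        xy = np.asarray(sub.layout_fruchterman_reingold().coords)
        if xy.shape[0] == 1:
            xy = np.zeros((1, 2))
        else:
            xy = xy - xy.mean(axis=0)
            extent = np.abs(xy).max()
            if extent > 0:
                xy = xy / extent  # into [-1, 1]^2
        r = math.sqrt(len(idx))
        xy = xy * r
        row, col = divmod(slot, ncol)
        centre = np.array([col * pitch, -row * pitch])
        for v, p in zip(idx, xy):
            coords[v] = centre + p
    return pd.DataFrame({"vertex_id": names, "x": coords[:, 0], "y": coords[:, 1]})
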