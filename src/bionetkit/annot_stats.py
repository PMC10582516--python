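"""Annotation-pair overlap/separation statistics, permutation significance,
over-representation analysis, and intra-class edge enrichment.

The separation statistic follows the disease-module localization framework:
for annotation sets A and B on a network, d_AA is the mean over members of A
of the distance to the nearest *other* member of A, d_AB the mean over all
members of A and B of the distance to the nearest member of the opposite set
(members shared by both sets contribute distance 0), and

    s_AB = d_AB - (d_AA + d_BB) / 2.

Negative s_AB means the two sets overlap topologically; positive means they
occupy separated network neighbourhoods. Significance comes from permuting
the vertex-annotation assignment (term multiplicities preserved), which keeps
the network fixed so the full distance matrix is computed once.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .graph_core import _validate_annotations, vertex_names

logger = logging.getLogger(__name__)

__all__ = [
    "annotation_sets",
    "mean_set_distance",
    "separation",
    "SeparationResult",
    "calc_annotation_pairs",
    "run_permutation_test",
    "ora",
    "intra_class_edges",
    "IntraClassResult",
]


def annotation_sets(net: ig.Graph, attr_name: str) -> dict[str, list[int]]:
    """Term -> vertex-index list from a semicolon-joined vertex attribute."""
    if attr_name not in net.vs.attribute_names():
        raise ValueError(f"vertex attribute {attr_name!r} not found")
    sets: dict[str, list[int]] = {}
    for v in net.vs:
        for term in (v[attr_name] or "").split(";"):
            if term:
                sets.setdefault(term, []).append(v.index)
    return sets


def _indices(net: ig.Graph, vertices) -> np.ndarray:
    pos = {v: i for i, v in enumerate(vertex_names(net))}
    try:
        return np.asarray(sorted(pos[str(v)] for v in vertices), dtype=int)
    except KeyError as exc:
        raise ValueError(f"vertex {exc.args[0]!r} not in network") from exc


def _nearest(D: np.ndarray, rows: np.ndarray, cols: np.ndarray, exclude_self: bool) -> np.ndarray:
    """For each row vertex, distance to the nearest column vertex."""
    sub = D[np.ix_(rows, cols)].astype(float, copy=True)
    if exclude_self:
        col_pos = {c: j for j, c in enumerate(cols)}
        for i, r in enumerate(rows):
            if r in col_pos:
                sub[i, col_pos[r]] = np.inf
    return sub.min(axis=1)


def _set_distances(D: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray):
    """(d_AA, d_BB, d_AB, n_unreachable) from a full distance matrix."""
    dropped = 0

    def finite_mean(vals: np.ndarray) -> tuple[float, int]:
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            raise ValueError("no finite distances between annotation sets")
        return float(finite.mean()), int(vals.size - finite.size)

    d_aa, d1 = finite_mean(_nearest(D, idx_a, idx_a, exclude_self=True))
    d_bb, d2 = finite_mean(_nearest(D, idx_b, idx_b, exclude_self=True))
    cross = np.concatenate(
        [_nearest(D, idx_a, idx_b, exclude_self=False), _nearest(D, idx_b, idx_a, exclude_self=False)]
    )
    d_ab, d3 = finite_mean(cross)
    return d_aa, d_bb, d_ab, d1 + d2 + d3


def _distance_matrix(net: ig.Graph) -> np.ndarray:
    return np.asarray(net.distances(), dtype=float)


def mean_set_distance(net: ig.Graph, A, B, mode: str = "between") -> float:
    """Mean nearest-member shortest-path distance.

    ``within`` (requires A only, |A| >= 2): mean over a in A of the distance to
    the nearest other member of A. ``between``: mean over members of A of the
    nearest member of B and vice versa; shared members contribute 0.
    Unreachable members are dropped (count logged).
    """
    idx_a = _indices(net, A)
    D = _distance_matrix(net)
    if mode == "within":
        if idx_a.size < 2:
            raise ValueError("mode='within' needs at least 2 vertices")
        vals = _nearest(D, idx_a, idx_a, exclude_self=True)
    elif mode == "between":
        idx_b = _indices(net, B)
        vals = np.concatenate(
            [_nearest(D, idx_a, idx_b, False), _nearest(D, idx_b, idx_a, False)]
        )
    else:
        raise ValueError("mode must be 'within' or 'between'")
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("no finite distances")
    if finite.size < vals.size:
        logger.info("mean_set_distance: dropped %d unreachable members", vals.size - finite.size)
    return float(finite.mean())


@dataclass
class SeparationResult:
    d_aa: float
    d_bb: float
    d_ab: float
    s_ab: float
    size_a: int
    size_b: int
    n_unreachable: int


def separation(net: ig.Graph, A, B) -> SeparationResult:
    """Topological separation s_AB = d_AB - (d_AA + d_BB)/2 of two vertex sets."""
    idx_a, idx_b = _indices(net, A), _indices(net, B)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("each annotation set needs at least 2 vertices")
    D = _distance_matrix(net)
    d_aa, d_bb, d_ab, dropped = _set_distances(D, idx_a, idx_b)
    return SeparationResult(
        d_aa=d_aa,
        d_bb=d_bb,
        d_ab=d_ab,
        s_ab=d_ab - (d_aa + d_bb) / 2.0,
        size_a=int(idx_a.size),
        size_b=int(idx_b.size),
        n_unreachable=dropped,
    )


def _resolve_pairs(sets: dict[str, list[int]], pairs) -> list[tuple[str, str]]:
    usable = sorted(t for t, idx in sets.items() if len(idx) >= 2)
    if pairs is None or pairs == "all":
        return list(itertools.combinations(usable, 2))
    out = []
    for a, b in pairs:
        for t in (a, b):
            if t not in sets:
                raise ValueError(f"term {t!r} absent from annotation attribute")
        out.append((a, b))
    return out


def _permuted_sets(
    sets: dict[str, list[int]],
    n: int,
    rng: np.random.Generator,
    null_model: str = "term",
):
    """Randomly re-place annotation terms on the graph.

    ``term`` (default): each term independently gets a uniform random vertex
    set of its own size, so shared membership between terms is broken — the
    null against which both proximity and co-annotation count as overlap.
    ``global``: one shared vertex relabeling for all terms, which preserves
    the co-occurrence structure and randomizes only the placement.
    """
    if null_model == "term":
        return {
            t: rng.permutation(n)[: len(idx)] for t, idx in sorted(sets.items())
        }
    if null_model == "global":
        perm = rng.permutation(n)
        return {t: perm[np.asarray(idx)] for t, idx in sets.items()}
    raise ValueError(f"unknown null_model {null_model!r}")


def calc_annotation_pairs(
    net: ig.Graph,
    attr_name: str,
    pairs=None,
    seed: int | None = None,
    null_model: str = "term",
) -> pd.DataFrame:
    """Observed s_AB for each annotation pair next to the s_AB of a single
    randomly permuted annotation assignment — a quick screen before the full
    permutation test."""
    sets = annotation_sets(net, attr_name)
    pair_list = _resolve_pairs(sets, pairs)
    D = _distance_matrix(net)
    rng = np.random.default_rng(seed)
    permuted = _permuted_sets(sets, net.vcount(), rng, null_model)
    rows = []
    for a, b in pair_list:
        ia, ib = np.asarray(sets[a]), np.asarray(sets[b])
        *_, s_obs = _sep_only(D, ia, ib)
        *_, s_perm = _sep_only(D, permuted[a], permuted[b])
        rows.append({"term_a": a, "term_b": b, "s_obs": s_obs, "s_permuted": s_perm})
    return pd.DataFrame(rows)


def _sep_only(D, ia, ib):
    d_aa, d_bb, d_ab, _ = _set_distances(D, np.sort(ia), np.sort(ib))
    return d_aa, d_bb, d_ab, d_ab - (d_aa + d_bb) / 2.0


def run_permutation_test(
    net: ig.Graph,
    attr_name: str,
    pairs=None,
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "overlap",
    null_model: str = "term",
) -> pd.DataFrame:
    """Permutation significance of annotation-pair separation.

    The null shuffles the vertex-annotation assignment (each term keeps its
    multiplicity; the graph is untouched — see ``_permuted_sets`` for the two
    null models). Empirical p-values use the +1 correction,
    p = (1 + #{null as or more extreme}) / (n_perm + 1), with
    ``alternative="overlap"`` counting null s_AB <= observed and
    ``"separation"`` the opposite tail. Bonferroni is over the tested pairs;
    q-values use the Benjamini–Hochberg estimator.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if alternative not in ("overlap", "separation"):
        raise ValueError("alternative must be 'overlap' or 'separation'")
    sets = annotation_sets(net, attr_name)
    pair_list = _resolve_pairs(sets, pairs)
    if not pair_list:
        raise ValueError("no annotation pairs to test")
    D = _distance_matrix(net)
    obs = {}
    for a, b in pair_list:
        obs[(a, b)] = _sep_only(D, np.asarray(sets[a]), np.asarray(sets[b]))
    rng = np.random.default_rng(seed)
    n = net.vcount()
    null = {pair: np.empty(n_perm) for pair in pair_list}
    for r in range(n_perm):
        permuted = _permuted_sets(sets, n, rng, null_model)
        for pair in pair_list:
            a, b = pair
            *_, s = _sep_only(D, permuted[a], permuted[b])
            null[pair][r] = s
    rows = []
    for pair in pair_list:
        a, b = pair
        d_aa, d_bb, d_ab, s_obs = obs[pair]
        ns = null[pair]
        if alternative == "overlap":
            extreme = int((ns <= s_obs).sum())
        else:
            extreme = int((ns >= s_obs).sum())
        p = (1 + extreme) / (n_perm + 1)
        sd = float(ns.std(ddof=1))
        rows.append(
            {
                "term_a": a,
                "term_b": b,
                "d_AA": d_aa,
                "d_BB": d_bb,
                "d_AB": d_ab,
                "s_AB": s_obs,
                "null_mean": float(ns.mean()),
                "null_sd": sd,
                "z": (s_obs - ns.mean()) / sd if sd > 0 else np.nan,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    out["q"] = false_discovery_control(out["p"], method="bh")
    out["n_perm"] = n_perm
    return out


def ora(
    groups: dict[str, set],
    ann: pd.DataFrame,
    universe,
    include_zero: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in vertex groups.

    For a group of size n and a term annotating K of the N universe vertices,
    with k group members carrying the term, p is the upper hypergeometric tail
    P(X >= k). Rows with k = 0 are omitted unless ``include_zero``;
    Benjamini–Hochberg adjustment is applied across all reported rows.
    """
    universe = {str(v) for v in universe}
    if not universe:
        raise ValueError("empty universe")
    ann = _validate_annotations(ann)
    term_sets: dict[str, set] = {}
    term_names: dict[str, str] = {}
    for tid, tname, vid in zip(ann["term_id"], ann["term_name"], ann["vertex_id"]):
        term_sets.setdefault(tid, set()).add(vid)
        term_names.setdefault(tid, tname)
    dropped = sum(len(s - universe) for s in term_sets.values())
    if dropped:
        logger.info("ora: dropped %d annotated vertices outside the universe", dropped)
    term_sets = {t: s & universe for t, s in term_sets.items()}
    N = len(universe)
    rows = []
    for gname in sorted(groups):
        gset = {str(v) for v in groups[gname]} & universe
        n = len(gset)
        for tid in sorted(term_sets):
            tset = term_sets[tid]
            K = len(tset)
            if K == 0:
                continue
            members = sorted(gset & tset)
            k = len(members)
            if k == 0 and not include_zero:
                continue
            p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
            rows.append(
                {
                    "group": gname,
                    "term_id": tid,
                    "term_name": term_names[tid],
                    "overlap": k,
                    "group_size": n,
                    "term_size": K,
                    "universe_size": N,
                    "p": min(p, 1.0),
                    "vertices": ";".join(members),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out.insert(8, "p_adj", false_discovery_control(out["p"], method="bh"))
    return out


@dataclass
class IntraClassResult:
    observed: int
    null_mean: float
    null_sd: float
    p: float
    n_perm: int


def intra_class_edges(
    net: ig.Graph,
    class_attr: str,
    n_perm: int = 1000,
    seed: int | None = None,
) -> IntraClassResult:
    """Count edges joining two vertices of the same class and compare with a
    label-permutation null (class sizes preserved). p is the upper-tail
    empirical probability with the +1 correction."""
    if class_attr not in net.vs.attribute_names():
        raise ValueError(f"vertex attribute {class_attr!r} not found")
    labels = np.asarray([str(v[class_attr]) for v in net.vs])
    edges = np.asarray([(e.source, e.target) for e in net.es], dtype=int)
    if edges.size == 0:
        raise ValueError("network has no edges")

    def count(lab: np.ndarray) -> int:
        return int((lab[edges[:, 0]] == lab[edges[:, 1]]).sum())

    observed = count(labels)
    rng = np.random.default_rng(seed)
    null = np.array([count(rng.permutation(labels)) for _ in range(n_perm)])
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return IntraClassResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p=p,
        n_perm=n_perm,
    )
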