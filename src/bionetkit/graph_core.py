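"""Network construction, file I/O, annotation attachment, and bipartite handling.

Graphs are held as undirected :class:`igraph.Graph` objects whose vertices carry a
string ``name`` attribute (the vertex ID — e.g. an Entrez gene ID stored as text).
All I/O coerces IDs to stripped strings so that numeric-looking identifiers never
get silently re-typed.

Bipartite networks (e.g. a disease–gene "diseasome") are ordinary graphs with an
additional per-vertex ``part`` attribute in ``{"left", "right"}``; every edge must
join a left vertex to a right one.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import igraph as ig
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "build_network",
    "read_graph",
    "write_graph",
    "largest_connected_component",
    "annotate_vertices",
    "apply_matrix_to_graph",
    "read_annotations",
    "write_annotations",
    "build_bipartite",
    "project_bipartite",
    "rewire_bipartite",
    "vertex_names",
]

ANNOTATION_COLUMNS = ("term_id", "term_name", "vertex_id")


def vertex_names(net: ig.Graph) -> list[str]:
    """Vertex IDs in graph order."""
    return list(net.vs["name"]) if net.vcount() else []


def _clean_id(value, row_index: int | None = None) -> str:
    s = str(value).strip()
    if not s or s.lower() == "nan":
        where = f" in row {row_index}" if row_index is not None else ""
        raise ValueError(f"empty or malformed vertex ID{where}")
    return s


def build_network(
    edge_table: Iterable[Sequence] | pd.DataFrame,
    keep_lcc: bool = False,
    simplify: bool = True,
) -> ig.Graph:
    """Build an undirected network from a two-column edge table.

    Parameters
    ----------
    edge_table
        Iterable of ``(id_a, id_b)`` rows (extra columns ignored) or a DataFrame
        whose first two columns are the endpoints. IDs are coerced to stripped
        strings.
    keep_lcc
        Retain only the largest connected component (ties broken by the component
        containing the lexicographically smallest vertex ID).
    simplify
        Remove self-loops and duplicate edges (default on: molecular interaction
        networks are simple undirected graphs).
    """
    if isinstance(edge_table, pd.DataFrame):
        rows = edge_table.iloc[:, :2].itertuples(index=False, name=None)
    else:
        rows = edge_table
    edges: list[tuple[str, str]] = []
    for i, row in enumerate(rows):
        try:
            a, b = row[0], row[1]
        except (TypeError, IndexError) as exc:
            raise ValueError(f"malformed edge row {i}: {row!r}") from exc
        edges.append((_clean_id(a, i), _clean_id(b, i)))
    if not edges:
        raise ValueError("no edges")
    names = sorted({v for e in edges for v in e})
    index = {v: k for k, v in enumerate(names)}
    g = ig.Graph(
        n=len(names),
        edges=[(index[a], index[b]) for a, b in edges],
        directed=False,
    )
    g.vs["name"] = names
    if simplify:
        g.simplify(multiple=True, loops=True)
    if keep_lcc:
        g = largest_connected_component(g)
    return g


def largest_connected_component(net: ig.Graph) -> ig.Graph:
    """Induced subgraph on the largest component (idempotent).

    Size ties are resolved deterministically in favour of the component containing
    the smallest vertex ID.
    """
    if net.vcount() == 0:
        raise ValueError("empty network")
    comps = net.connected_components()
    sizes = [len(c) for c in comps]
    max_size = max(sizes)
    candidates = [i for i, s in enumerate(sizes) if s == max_size]
    best = min(candidates, key=lambda i: min(net.vs[v]["name"] for v in comps[i]))
    return net.induced_subgraph(comps[best])


def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".gml":
        return "gml"
    if ext == ".graphml":
        return "graphml"
    return "edgelist"


def _read_edgelist(path: str) -> ig.Graph:
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", "\t").split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            rows.append((tokens[0], tokens[1]))
    if not rows:
        raise ValueError("no edges")
    # Header heuristic: drop the first row iff both its tokens are non-numeric
    # and neither re-appears as an endpoint anywhere else.
    if len(rows) > 1:
        a, b = rows[0]
        others = {t for r in rows[1:] for t in r}

        def _numeric(s: str) -> bool:
            try:
                float(s)
                return True
            except ValueError:
                return False

        if not _numeric(a) and not _numeric(b) and a not in others and b not in others:
            rows = rows[1:]
    return build_network(rows, simplify=True)


def read_graph(path: str, format: str | None = None) -> ig.Graph:
    """Read a network from ``edgelist`` (TSV/CSV), ``gml`` or ``graphml``.

    The vertex name/label attribute becomes the string vertex ID.
    """
    fmt = format or _detect_format(path)
    if fmt == "edgelist":
        return _read_edgelist(path)
    if fmt not in ("gml", "graphml"):
        raise ValueError(f"unknown format: {fmt!r}")
    try:
        if fmt == "gml":
            g = ig.Graph.Read_GML(path)
        else:
            g = ig.Graph.Read_GraphML(path)
    except Exception as exc:  # igraph raises InternalError with parser context
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if g.is_directed():
        g = g.as_undirected()
    attrs = g.vs.attribute_names()
    if "name" not in attrs:
        for alt in ("label", "id"):
            if alt in attrs:
                g.vs["name"] = g.vs[alt]
                break
        else:
            g.vs["name"] = [str(i) for i in range(g.vcount())]
    g.vs["name"] = [_clean_id(v) for v in g.vs["name"]]
    for junk in ("id", "label"):
        if junk in g.vs.attribute_names() and junk != "name":
            del g.vs[junk]
    g.simplify(multiple=True, loops=True)
    return g


def _canonical_order(net: ig.Graph) -> ig.Graph:
    """Copy of *net* with vertices sorted by ID (deterministic writer order)."""
    order = sorted(range(net.vcount()), key=lambda i: net.vs[i]["name"])
    return net.permute_vertices([order.index(i) for i in range(net.vcount())])


def sorted_edge_list(net: ig.Graph) -> list[tuple[str, str]]:
    names = vertex_names(net)
    pairs = [tuple(sorted((names[e.source], names[e.target]))) for e in net.es]
    return sorted(pairs)


def write_graph(net: ig.Graph, path: str, format: str | None = None) -> None:
    """Write a network with deterministic vertex/edge ordering."""
    fmt = format or _detect_format(path)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write("id_a\tid_b\n")
            for a, b in sorted_edge_list(net):
                fh.write(f"{a}\t{b}\n")
        return
    if fmt not in ("gml", "graphml"):
        raise ValueError(f"unknown format: {fmt!r}")
    g = _canonical_order(net)
    if fmt == "gml":
        g.write_gml(path)
    else:
        g.write_graphml(path)


def read_annotations(path: str) -> pd.DataFrame:
    """Read a 3-column annotation table (term_id, term_name, vertex_id) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError("annotation table needs 3 columns: term_id, term_name, vertex_id")
    df = df.iloc[:, :3]
    df.columns = list(ANNOTATION_COLUMNS)
    return _validate_annotations(df)


def _validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    ann = ann.copy()
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            raise ValueError(f"annotation table missing column {col!r}")
        ann[col] = ann[col].astype(str).str.strip()
    if (ann["term_id"] == "").any() or (ann["vertex_id"] == "").any():
        raise ValueError("annotation rows must have non-empty term_id and vertex_id")
    return ann.drop_duplicates(ignore_index=True)


def write_annotations(ann: pd.DataFrame, path: str) -> None:
    _validate_annotations(ann).to_csv(path, sep="\t", index=False)


def annotate_vertices(
    net: ig.Graph,
    ann: pd.DataFrame,
    attr_name: str,
    id_field: str = "term_id",
) -> ig.Graph:
    """Attach annotation terms as a semicolon-joined vertex attribute.

    Each vertex gets ``attr_name`` set to the sorted, de-duplicated ";"-join of its
    terms (``id_field`` selects term_id or term_name); vertices without annotation
    get "". Rows referencing unknown vertices are skipped with a logged count.
    """
    if not attr_name:
        raise ValueError("attr_name must be non-empty")
    if id_field not in ("term_id", "term_name"):
        raise ValueError(f"id_field must be term_id or term_name, got {id_field!r}")
    ann = _validate_annotations(ann)
    known = set(vertex_names(net))
    skipped = int((~ann["vertex_id"].isin(known)).sum())
    if skipped:
        logger.info("annotate_vertices: skipped %d rows for vertices not in network", skipped)
    ann = ann[ann["vertex_id"].isin(known)]
    terms: dict[str, set[str]] = {}
    for term, vid in zip(ann[id_field], ann["vertex_id"]):
        terms.setdefault(vid, set()).add(term)
    net.vs[attr_name] = [";".join(sorted(terms.get(v, ()))) for v in vertex_names(net)]
    return net


def apply_matrix_to_graph(
    net: ig.Graph,
    values: pd.DataFrame,
    overwrite: bool = False,
    missing=np.nan,
) -> ig.Graph:
    """Store per-vertex numeric columns as vertex attributes.

    ``values`` is keyed by vertex ID (its index, or a ``vertex_id`` column).
    Vertices absent from the table get ``missing``.
    """
    if values.empty and values.shape[1] == 0:
        return net
    df = values.copy()
    if "vertex_id" in df.columns:
        df = df.set_index("vertex_id")
    df.index = df.index.astype(str)
    existing = set(net.vs.attribute_names())
    for col in df.columns:
        if col in existing and not overwrite:
            raise ValueError(f"vertex attribute {col!r} already exists (pass overwrite=True)")
        lookup = df[col].to_dict()
        net.vs[col] = [lookup.get(v, missing) for v in vertex_names(net)]
    return net


# --- bipartite networks -------------------------------------------------------


def build_bipartite(edge_table: Iterable[Sequence] | pd.DataFrame) -> ig.Graph:
    """Build a bipartite network; first column = left part, second = right part.

    Left and right ID namespaces must be disjoint.
    """
    if isinstance(edge_table, pd.DataFrame):
        rows = edge_table.iloc[:, :2].itertuples(index=False, name=None)
    else:
        rows = edge_table
    edges = [(_clean_id(a, i), _clean_id(b, i)) for i, (a, b) in enumerate(rows)]
    if not edges:
        raise ValueError("no edges")
    left = sorted({a for a, _ in edges})
    right = sorted({b for _, b in edges})
    clash = set(left) & set(right)
    if clash:
        raise ValueError(f"IDs appear in both parts: {sorted(clash)[:5]}")
    names = left + right
    index = {v: k for k, v in enumerate(names)}
    g = ig.Graph(n=len(names), edges=[(index[a], index[b]) for a, b in edges], directed=False)
    g.vs["name"] = names
    g.vs["part"] = ["left"] * len(left) + ["right"] * len(right)
    g.simplify(multiple=True, loops=True)
    return g


def _check_bipartite(bn: ig.Graph) -> None:
    if "part" not in bn.vs.attribute_names():
        raise ValueError("not a bipartite network (missing 'part' vertex attribute)")
    part = bn.vs["part"]
    for e in bn.es:
        if part[e.source] == part[e.target]:
            raise ValueError("edge within one part; network is not bipartite")


def project_bipartite(bn: ig.Graph, onto: str = "left") -> ig.Graph:
    """One-mode projection: two same-part vertices are joined iff they share a
    neighbour in the opposite part. Unweighted simple graph; vertices of the
    chosen part with no co-neighbour remain as isolated vertices."""
    _check_bipartite(bn)
    if onto not in ("left", "right"):
        raise ValueError("onto must be 'left' or 'right'")
    keep = [v.index for v in bn.vs if v["part"] == onto]
    if not keep:
        raise ValueError(f"part {onto!r} is empty")
    names = sorted(bn.vs[v]["name"] for v in keep)
    index = {v: k for k, v in enumerate(names)}
    pairs: set[tuple[int, int]] = set()
    for v in bn.vs:
        if v["part"] == onto:
            continue
        nbrs = sorted(bn.vs[u]["name"] for u in bn.neighbors(v.index))
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                pairs.add((index[nbrs[i]], index[nbrs[j]]))
    g = ig.Graph(n=len(names), edges=sorted(pairs), directed=False)
    g.vs["name"] = names
    return g


def rewire_bipartite(bn: ig.Graph, n_swaps: int | None = None, seed: int | None = None) -> ig.Graph:
    """Degree-preserving randomization of a bipartite network.

    Performs ``n_swaps`` attempted double-edge swaps (default 10×|E|), rejecting
    any swap that would create a duplicate edge, so the degree sequences of both
    parts are preserved exactly.
    """
    _check_bipartite(bn)
    if bn.ecount() < 2:
        raise ValueError("need at least 2 edges to rewire")
    if n_swaps is None:
        n_swaps = 10 * bn.ecount()
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    rng = np.random.default_rng(seed)
    part = bn.vs["part"]
    # orient every edge left -> right
    edges = []
    for e in bn.es:
        a, b = e.source, e.target
        if part[a] != "left":
            a, b = b, a
        edges.append((a, b))
    edge_set = set(edges)
    m = len(edges)
    for _ in range(n_swaps):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == c or b == d:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
    g = ig.Graph(n=bn.vcount(), edges=sorted(edge_set), directed=False)
    g.vs["name"] = bn.vs["name"]
    g.vs["part"] = part
    return g
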