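"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (path enumeration, direct
formula evaluation, exact combinatorics) and deliberately avoids the code
paths under test.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def bfs_distances(n: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """All-pairs shortest-path matrix by repeated BFS (inf if unreachable)."""
    adj = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    D = np.full((n, n), np.inf)
    for s in range(n):
        D[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if not np.isfinite(D[s, v]):
                    D[s, v] = D[s, u] + 1
                    q.append(v)
    return D


def brute_betweenness(n: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """Betweenness by explicit enumeration of all shortest paths per pair."""
    adj = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    D = bfs_distances(n, edges)
    bc = np.zeros(n)

    def shortest_paths(s: int, t: int) -> list[list[int]]:
        if not np.isfinite(D[s, t]):
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for v in adj[u]:
                if D[s, v] == len(path) and D[v, t] == D[s, t] - len(path):
                    extend(path + [v])

        extend([s])
        return paths

    for s, t in itertools.combinations(range(n), 2):
        paths = shortest_paths(s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def brute_modularity(n: int, edges: list[tuple[int, int]], labels: list[int]) -> float:
    """Q by the literal double sum over ordered vertex pairs."""
    m = len(edges)
    A = np.zeros((n, n))
    for a, b in edges:
        A[a, b] += 1
        A[b, a] += 1
    k = A.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - k[i] * k[j] / (2 * m)
    return q / (2 * m)


def all_partitions(items: list):
    """Every set partition of items (Bell-number many — keep items small)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1 :]
        yield smaller + [[first]]


def max_modularity_partition(n: int, edges: list[tuple[int, int]]):
    """Exhaustive max-modularity partition (n <= 10 or so)."""
    best_q, best = -math.inf, None
    for parts in all_partitions(list(range(n))):
        labels = [0] * n
        for c, block in enumerate(parts):
            for v in block:
                labels[v] = c
        q = brute_modularity(n, edges, labels)
        if q > best_q:
            best_q, best = q, parts
    return best_q, best


def hypergeom_tail_exact(k: int, N: int, K: int, n: int):
    """Exact upper-tail P(X >= k) as a fraction, via binomial coefficients."""
    from fractions import Fraction

    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return Fraction(acc, total)


def brute_bridgeness(M: np.ndarray, communities: list[list[int]]) -> np.ndarray:
    """Direct evaluation of the affiliation-deviation bridgeness formula."""
    K = len(communities)
    n = M.shape[0]
    B = np.zeros(n)
    for i in range(n):
        p = np.array([sum(M[i, j] for j in c if j != i) for c in communities])
        if p.sum() == 0:
            p = np.full(K, 1.0 / K)
        else:
            p = p / p.sum()
        B[i] = 1.0 - math.sqrt(K / (K - 1)) * math.sqrt(((p - 1.0 / K) ** 2).sum())
    return B


def entropy_rate_by_markov(A: np.ndarray, x: np.ndarray) -> float:
    """Entropy rate via the transition matrix and its stationary eigenvector.

    Builds P row-by-row from the weighted-walk definition, extracts the
    stationary distribution as the leading left eigenvector, and evaluates
    sum_i pi_i * H(P_i) — an independent route to the closed-form used by the
    implementation.
    """
    n = A.shape[0]
    P = np.zeros((n, n))
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        P[i, nbrs] = x[nbrs] / x[nbrs].sum()
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmax(np.real(w))])
    pi = np.abs(pi) / np.abs(pi).sum()
    sr = 0.0
    for i in range(n):
        row = P[i][P[i] > 0]
        sr += pi[i] * float(-(row * np.log(row)).sum())
    return sr
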