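"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives the quantity from first principles (explicit loops,
exhaustive enumeration) without touching the library's implementation
paths, so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def mi_bruteforce(x, y, n_bins: int) -> float:
    """Binned MI from an explicitly built contingency table (nats)."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)

    def bins(v):
        order = sorted(range(n), key=lambda i: (v[i], i))
        rank = [0] * n
        for r, i in enumerate(order):
            rank[i] = r
        return [(r * n_bins) // n for r in rank]

    bx, by = bins(x), bins(y)
    joint = [[0] * n_bins for _ in range(n_bins)]
    for i in range(n):
        joint[bx[i]][by[i]] += 1
    rows = [sum(row) for row in joint]
    cols = [sum(joint[i][j] for i in range(n_bins)) for j in range(n_bins)]
    mi = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            c = joint[i][j]
            if c:
                mi += (c / n) * math.log(c * n / (rows[i] * cols[j]))
    return max(0.0, mi)


def dpi_bruteforce(edges: dict[tuple[str, str], float], tolerance: float = 0.0):
    """DPI pruning by exhaustive triangle enumeration on the frozen edge set."""
    nodes = sorted({n for e in edges for n in e})
    def key(a, b):
        return (a, b) if a <= b else (b, a)
    removed = set()
    for a, b, c in itertools.combinations(nodes, 3):
        trio = [key(a, b), key(a, c), key(b, c)]
        if not all(t in edges for t in trio):
            continue
        for t in trio:
            others = min(edges[o] for o in trio if o != t)
            if edges[t] < (1.0 - tolerance) * others:
                removed.add(t)
    return {e: w for e, w in edges.items() if e not in removed}


def scc_bruteforce(nodes, edges) -> dict:
    """SCC partition from pairwise reachability (transitive closure)."""
    nodes = list(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = [[False] * n for _ in range(n)]
    for i in range(n):
        reach[i][i] = True
    for u, v in edges:
        if u != v:
            reach[idx[u]][idx[v]] = True
    for k in range(n):
        for i in range(n):
            if reach[i][k]:
                for j in range(n):
                    if reach[k][j]:
                        reach[i][j] = True
    comp = {}
    cid = 0
    for i, u in enumerate(nodes):
        if u in comp:
            continue
        comp[u] = cid
        for j in range(i + 1, n):
            if reach[i][j] and reach[j][i]:
                comp[nodes[j]] = cid
        cid += 1
    return comp


def triad_census_bruteforce(g) -> dict[tuple, int]:
    """Connected 3-node motif counts by enumerating all node triples.

    Keys are canonical 6-bit arc masks (minimum over node permutations);
    only weakly connected triads are counted.
    """
    nodes = sorted(g.nodes)
    arcs = {(u, v) for u, v in g.edges if u != v}
    counts: dict[int, int] = {}
    arc_order = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1))
    for trip in itertools.combinations(nodes, 3):
        present = []
        for ia, ib in itertools.permutations(range(3), 2):
            if (trip[ia], trip[ib]) in arcs:
                present.append((ia, ib))
        if not present:
            continue
        # weak connectivity on 3 nodes: any two distinct undirected pairs
        # cover all three nodes, so connected iff >= 2 distinct pairs
        und = {frozenset(p) for p in present}
        if len(und) < 2:
            continue
        best = 1 << 6
        for perm in itertools.permutations(range(3)):
            mask = 0
            for ia, ib in present:
                arc = (perm[ia], perm[ib])
                mask |= 1 << arc_order.index(arc)
            best = min(best, mask)
        counts[best] = counts.get(best, 0) + 1
    return counts


def betweenness_bruteforce(g) -> dict:
    """Directed betweenness by explicit enumeration of all simple paths."""
    import networkx as nx

    nodes = list(g.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = list(nx.all_simple_paths(g, s, t))
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            sp = [p for p in paths if len(p) == shortest]
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in sp if v in p[1:-1])
                if through:
                    score[v] += through / len(sp)
    norm = (n - 1) * (n - 2)
    return {v: (s / norm if norm else 0.0) for v, s in score.items()}


def es_bruteforce(stats, genes, members: set, weight: int) -> float:
    """GSEA running-sum ES with an explicit walk down the list."""
    n = len(genes)
    hits = [g in members for g in genes]
    k = sum(hits)
    if weight == 0:
        w = [1.0 if h else 0.0 for h in hits]
    else:
        w = [abs(s) ** weight if h else 0.0 for s, h in zip(stats, hits)]
    total = sum(w)
    if total == 0:
        w = [1.0 if h else 0.0 for h in hits]
        total = float(k)
    running = 0.0
    best = 0.0
    for i in range(n):
        if hits[i]:
            running += w[i] / total
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Element-by-element topological overlap dissimilarity."""
    g = a.shape[0]
    out = np.zeros((g, g))
    k = [sum(a[i, u] for u in range(g) if u != i) for i in range(g)]
    for i in range(g):
        for j in range(g):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(g) if u not in (i, j))
            tom = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
            out[i, j] = 1.0 - tom
    return out


def hypergeom_tail_bruteforce(overlap: int, size_a: int, size_b: int, universe: int) -> float:
    """Upper-tail P(X >= overlap) from explicit binomial coefficients."""
    num = 0
    for k in range(overlap, min(size_a, size_b) + 1):
        num += math.comb(size_a, k) * math.comb(universe - size_a, size_b - k)
    return num / math.comb(universe, size_b)
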