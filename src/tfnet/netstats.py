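"""Connectivity, centrality, motif-census and regulon-similarity statistics.

These are the statistics used to contrast regenerating-PNS-like networks
(dense, hierarchical, feed-forward-loop enriched) with non-regenerating
CNS-like ones (sparse, bi-layered): global/local clustering coefficients,
betweenness and in/out-degree, a 13-class census of connected 3-node
directed motifs with degree-preserving-null z-scores, and a signed-weight
similarity of a TF's regulon across two networks.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd

from tfnet.datatypes import (
    CentralityTable,
    DirectedNetwork,
    MotifReport,
    SignedNetwork,
)

__all__ = [
    "clustering_coefficients",
    "centrality",
    "degree_preserving_randomize",
    "motif_zscores",
    "regulon_similarity",
    "triad_classes",
]

#: networkx triad-census codes of the 13 connected 3-node directed classes
#: (the full 16-type census minus the empty, single-arc and single-mutual
#: types, whose underlying graphs are disconnected on 3 nodes)
CONNECTED_TRIADS = (
    "021D",
    "021U",
    "021C",
    "111D",
    "111U",
    "030T",
    "030C",
    "201",
    "120D",
    "120U",
    "120C",
    "210",
    "300",
)

#: the feed-forward loop (A->B, B->C, A->C) in triad-census nomenclature
FFL = "030T"
CYCLE_3 = "030C"


@lru_cache(maxsize=1)
def triad_classes() -> tuple[str, ...]:
    """The 13 connected 3-node directed motif classes.

    Derived by enumerating all 64 arc subsets on 3 labelled nodes, keeping
    the weakly connected ones, and grouping by isomorphism; asserted to
    match the named census codes.
    """
    canon_to_class: dict[int, int] = {}
    n_classes = 0
    for mask in range(64):
        arcs = _mask_to_arcs(mask)
        g = nx.DiGraph()
        g.add_nodes_from(range(3))
        g.add_edges_from(arcs)
        if not nx.is_weakly_connected(g):
            continue
        c = _canonical_mask(mask)
        if c not in canon_to_class:
            canon_to_class[c] = n_classes
            n_classes += 1
    assert n_classes == len(CONNECTED_TRIADS)
    return CONNECTED_TRIADS


# arcs indexed as (0,1),(1,0),(0,2),(2,0),(1,2),(2,1)
_ARC_ORDER = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1))


def _mask_to_arcs(mask: int) -> list[tuple[int, int]]:
    return [arc for bit, arc in enumerate(_ARC_ORDER) if mask >> bit & 1]


def _arcs_to_mask(arcs) -> int:
    idx = {arc: bit for bit, arc in enumerate(_ARC_ORDER)}
    m = 0
    for a in arcs:
        m |= 1 << idx[a]
    return m


def _canonical_mask(mask: int) -> int:
    arcs = _mask_to_arcs(mask)
    best = 1 << 6
    for perm in permutations(range(3)):
        m = _arcs_to_mask([(perm[u], perm[v]) for u, v in arcs])
        best = min(best, m)
    return best


def _as_graph(net) -> nx.Graph | nx.DiGraph:
    if isinstance(net, (SignedNetwork, DirectedNetwork)):
        return net.to_graph()
    return net


def clustering_coefficients(net) -> CentralityTable:
    """Local and global (transitivity) clustering on the undirected projection.

    Local CC of a node with degree < 2 is 0; the global coefficient is
    3 x triangles / connected triples.  The mean local CC is reported
    alongside, but transitivity is the headline global value.
    """
    g = _as_graph(net)
    und = g.to_undirected() if g.is_directed() else g.copy()
    und.remove_edges_from(nx.selfloop_edges(und))
    if und.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    local = nx.clustering(und)
    table = pd.DataFrame({"local_clustering": pd.Series(local)})
    return CentralityTable(
        per_node=table,
        global_clustering=nx.transitivity(und),
        mean_local_clustering=float(np.mean(list(local.values()))) if local else 0.0,
    )


def centrality(net: DirectedNetwork) -> CentralityTable:
    """Betweenness, in-/out-degree and local clustering per node.

    Betweenness uses directed unweighted shortest paths, normalized by
    (n-1)(n-2); degrees exclude self-loops.
    """
    g = net.to_graph(include_self_loops=False) if isinstance(net, DirectedNetwork) else _as_graph(net)
    btw = nx.betweenness_centrality(g, normalized=True)
    und = g.to_undirected()
    local = nx.clustering(und)
    table = pd.DataFrame(
        {
            "betweenness": pd.Series(btw),
            "in_degree": pd.Series(dict(g.in_degree())),
            "out_degree": pd.Series(dict(g.out_degree())),
            "local_clustering": pd.Series(local),
        }
    )
    glob = nx.transitivity(und) if und.number_of_nodes() >= 3 else None
    return CentralityTable(per_node=table, global_clustering=glob)


def degree_preserving_randomize(
    g: nx.DiGraph, n_swaps: int | None = None, seed: int = 0
) -> nx.DiGraph:
    """Randomize a digraph by repeated double-edge swaps.

    Each attempt picks two arcs (u->v, x->y) and rewires to (u->y, x->v)
    unless that would create a self-loop or a duplicate arc.  In- and
    out-degree sequences are preserved exactly; graphs with no legal swap
    are returned unchanged.  Deterministic given ``seed``.
    """
    if g.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to swap")
    rng = np.random.default_rng(seed)
    out = nx.DiGraph()
    out.add_nodes_from(g.nodes)
    out.add_edges_from(g.edges)
    edges = list(out.edges)
    m = len(edges)
    if n_swaps is None:
        n_swaps = 10 * m
    for _ in range(n_swaps):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if u == y or x == v:
            continue
        if out.has_edge(u, y) or out.has_edge(x, v):
            continue
        out.remove_edge(u, v)
        out.remove_edge(x, y)
        out.add_edge(u, y)
        out.add_edge(x, v)
        edges[i] = (u, y)
        edges[j] = (x, v)
    return out


def _census_13(g: nx.DiGraph) -> dict[str, int]:
    simple = nx.DiGraph()
    simple.add_nodes_from(g.nodes)
    simple.add_edges_from((u, v) for u, v in g.edges if u != v)
    census = nx.triadic_census(simple)
    return {name: census[name] for name in CONNECTED_TRIADS}


def motif_zscores(
    net: DirectedNetwork | nx.DiGraph, n_random: int = 1000, seed: int = 0
) -> MotifReport:
    """Census of the 13 connected 3-node motifs with randomized-null z-scores.

    Counts come from an exhaustive triad census (self-loops ignored); the
    null ensemble is ``n_random`` degree-preserving edge-swap randomizations
    of the input.  z = (obs - mean) / sd, undefined (NA) where the null sd
    is 0.
    """
    g = net.to_graph(include_self_loops=False) if isinstance(net, DirectedNetwork) else net
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    observed = _census_13(g)
    rng = np.random.default_rng(seed)
    null_counts = {name: np.empty(n_random) for name in CONNECTED_TRIADS}
    for r in range(n_random):
        rg = degree_preserving_randomize(g, seed=int(rng.integers(0, 2**31 - 1)))
        c = _census_13(rg)
        for name in CONNECTED_TRIADS:
            null_counts[name][r] = c[name]
    rows = []
    for name in CONNECTED_TRIADS:
        mean = float(null_counts[name].mean())
        sd = float(null_counts[name].std(ddof=0))
        z = (observed[name] - mean) / sd if sd > 0 else np.nan
        rows.append(
            {
                "motif": name,
                "observed": observed[name],
                "null_mean": mean,
                "null_sd": sd,
                "z": z,
            }
        )
    return MotifReport(table=pd.DataFrame(rows), n_random=n_random, seed=seed)


def regulon_similarity(netA: SignedNetwork, netB: SignedNetwork, tf: str) -> float:
    """Pearson correlation of a TF's signed-MI regulon across two networks.

    The two weight vectors are taken over the union of the TF's partners in
    the networks, with absent partners filled with 0, so the statistic
    reflects both shared membership and agreement in mode of action.
    Returns NaN when either regulon is empty or the correlation is
    undefined (zero variance).
    """
    if tf not in set(netA.nodes):
        raise KeyError(f"TF {tf!r} missing from first network")
    if tf not in set(netB.nodes):
        raise KeyError(f"TF {tf!r} missing from second network")
    ra = netA.regulon(tf)
    rb = netB.regulon(tf)
    if not ra or not rb:
        return float("nan")
    union = sorted(set(ra) | set(rb))
    va = np.array([ra.get(t, 0.0) for t in union])
    vb = np.array([rb.get(t, 0.0) for t in union])
    if len(union) < 2 or va.std() == 0 or vb.std() == 0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])
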