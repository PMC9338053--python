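"""Edge orientation with binding evidence and vertex-sort stratification.

An inferred undirected pair becomes a directed regulatory edge only when a
physical binding record supports that orientation; unsupported pairs are
kept as undirected residuals and excluded from hierarchy sorting (they
still count in undirected statistics).  The directed network is then
condensed by strongly connected components and stratified by iterative
leaf removal on the condensation DAG and on its transpose: a node's level
interval is [L_up, D + 1 - L_down] (1 = bottom, D = dendrogram depth), and
the strata are TOP (lo = hi = D), BOTTOM (lo = hi = 1) and MIDDLE
otherwise.  Self-loops are ignored in all leaf-removal degree counts:
purely self-regulating TFs are bottom-level by definition.
"""

from __future__ import annotations

import networkx as nx

from tfnet.datatypes import (
    DirectedEdge,
    DirectedNetwork,
    EvidenceEdgeList,
    LayeredNetwork,
    SignedNetwork,
)

__all__ = ["orient_edges", "condense_sccs", "vertex_sort"]


def orient_edges(net: SignedNetwork, evidence: EvidenceEdgeList) -> DirectedNetwork:
    """Orient undirected MI edges using physical binding evidence.

    Edge {a, b} becomes a->b if (a, b) is in the evidence, b->a if (b, a)
    is, both if both.  Pairs without evidence are retained as undirected
    residual edges.  Evidence self-loops on network nodes are added as
    directed self-edges (carried for bookkeeping; ignored by vertex_sort).
    """
    edges: dict[tuple[str, str], DirectedEdge] = {}
    residual = {}
    for (a, b), e in net.edges.items():
        fwd = (a, b) in evidence
        rev = (b, a) in evidence
        if fwd:
            edges[(a, b)] = DirectedEdge(a, b, e.mi, e.sign, evidence=True)
        if rev:
            edges[(b, a)] = DirectedEdge(b, a, e.mi, e.sign, evidence=True)
        if not fwd and not rev:
            residual[(a, b)] = e
    node_set = set(net.nodes)
    for tf, tgt in sorted(evidence.pairs):
        if tf == tgt and tf in node_set:
            edges[(tf, tf)] = DirectedEdge(tf, tf, 0.0, 1, evidence=True)
    return DirectedNetwork(
        nodes=list(net.nodes),
        edges=edges,
        residual_edges=residual,
        params={**net.params, "stage": "orient_edges"},
    )


def condense_sccs(net: DirectedNetwork) -> tuple[nx.DiGraph, dict[str, int]]:
    """Collapse strongly connected components into supernodes.

    Returns the condensation DAG (nodes are integer SCC ids with a
    ``members`` attribute) and the node -> SCC id map.  Acyclic apart from
    discarded self-loops.
    """
    g = net.to_graph(include_self_loops=False)
    if g.number_of_edges() == 0 and not any(u == v for (u, v) in net.edges):
        if not net.edges:
            raise ValueError("no directed edges to condense")
    sccs = sorted(nx.strongly_connected_components(g), key=lambda s: sorted(s)[0])
    supernode = {n: i for i, comp in enumerate(sccs) for n in comp}
    dag = nx.DiGraph()
    for i, comp in enumerate(sccs):
        dag.add_node(i, members=sorted(comp))
    for u, v in g.edges:
        su, sv = supernode[u], supernode[v]
        if su != sv:
            dag.add_edge(su, sv)
    return dag, supernode


def _leaf_removal_levels(dag: nx.DiGraph) -> dict[int, int]:
    """Iterative leaf removal: level 1 = out-degree-0 nodes, then repeat."""
    out_deg = {n: dag.out_degree(n) for n in dag.nodes}
    level: dict[int, int] = {}
    frontier = [n for n, d in out_deg.items() if d == 0]
    current = 1
    while frontier:
        next_frontier = []
        for n in frontier:
            level[n] = current
        for n in frontier:
            for p in dag.predecessors(n):
                out_deg[p] -= 1
                if out_deg[p] == 0:
                    next_frontier.append(p)
        frontier = next_frontier
        current += 1
    return level


def vertex_sort(net: DirectedNetwork) -> LayeredNetwork:
    """Stratify a directed network into TOP / MIDDLE / BOTTOM layers.

    Leaf removal on the condensation DAG gives each supernode its
    level-from-bottom L_up (sinks = 1); leaf removal on the transpose gives
    L_down.  With D the maximum level, a node's interval is
    [L_up, D + 1 - L_down]; TOP means lo = hi = D, BOTTOM lo = hi = 1, and
    every interval-straddling node is MIDDLE.  All members of an SCC
    inherit their supernode's assignment.
    """
    n_directed = sum(1 for (u, v) in net.edges if u != v)
    if n_directed == 0:
        raise ValueError("no hierarchy to sort: network has no directed edges")
    dag, supernode = condense_sccs(net)
    l_up = _leaf_removal_levels(dag)
    l_down = _leaf_removal_levels(dag.reverse(copy=True))
    depth = max(l_up.values())

    levels: dict[str, tuple[str, tuple[int, int]]] = {}
    for node, scc in supernode.items():
        lo = l_up[scc]
        hi = depth + 1 - l_down[scc]
        if depth == 1:
            # condensation without inter-layer edges (e.g. one big cycle):
            # every node is simultaneously top- and bottom-level, which has
            # no hierarchy reading; label MIDDLE (self-symmetric under
            # edge reversal)
            stratum = "MIDDLE"
        elif lo == hi == depth:
            stratum = "TOP"
        elif lo == hi == 1:
            stratum = "BOTTOM"
        else:
            stratum = "MIDDLE"
        levels[node] = (stratum, (lo, hi))
    return LayeredNetwork(network=net, levels=levels, supernode=supernode, depth=depth)
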