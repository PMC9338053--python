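"""Module projection onto a PPI background with degree-aware significance.

A gene module is scored by the number of protein-interaction edges induced
among its members.  The null preserves each member's connectivity class:
every module gene is replaced by a uniformly chosen non-module gene from
the same log2-spaced degree bin (1, 2, 3-4, 5-8, ...), the standard
degree-matched null; bins with no replacement candidates are widened with
a warning.  Per-node hub p-values are computed analogously from
within-module degrees.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from tfnet.datatypes import PPISubnetwork, canonical_pair

__all__ = ["induced_subnetwork", "ppi_permutation_significance", "degree_bin"]


def _edge_pairs(ppi) -> set[tuple[str, str]]:
    if isinstance(ppi, pd.DataFrame):
        it = zip(ppi["a"].astype(str), ppi["b"].astype(str))
    else:
        it = ((str(a), str(b)) for a, b in ppi)
    return {canonical_pair(a, b) for a, b in it if a != b}


def _adjacency(pairs: set[tuple[str, str]]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, b in pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def degree_bin(degree: int) -> int:
    """Log2-spaced degree class: 1 | 2 | 3-4 | 5-8 | 9-16 | ..."""
    if degree < 1:
        raise ValueError("degree bins are defined for degree >= 1")
    return int(np.ceil(np.log2(degree)))


def _induced_edge_count(members: set[str], adj: dict[str, set[str]]) -> int:
    return sum(len(adj.get(g, set()) & members) for g in members) // 2


def induced_subnetwork(genes, ppi) -> PPISubnetwork:
    """Subgraph of the PPI induced by a gene list.

    Duplicate PPI rows are deduplicated; genes absent from the PPI node set
    are reported separately rather than dropped silently.
    """
    pairs = _edge_pairs(ppi)
    adj = _adjacency(pairs)
    genes = list(dict.fromkeys(str(g) for g in genes))
    present = [g for g in genes if g in adj]
    absent = [g for g in genes if g not in adj]
    mset = set(present)
    edges = sorted({canonical_pair(a, b) for a, b in pairs if a in mset and b in mset})
    within = pd.Series(
        {g: len(adj.get(g, set()) & mset) for g in present}, dtype=int
    )
    return PPISubnetwork(
        genes=present,
        absent_genes=absent,
        edges=edges,
        within_degree=within,
        n_edges=len(edges),
    )


def ppi_permutation_significance(
    module_genes, ppi, n_perm: int = 1000, seed: int = 0
) -> PPISubnetwork:
    """Degree-matched permutation p for a module's PPI connectivity.

    The statistic is the induced edge count; p is the add-one upper tail
    over ``n_perm`` degree-binned replacements of the module.  The returned
    subnetwork carries a per-gene hub table (observed within-module degree
    and its analogous permutation p).  Deterministic given ``seed``.
    """
    sub = induced_subnetwork(module_genes, ppi)
    if len(sub.genes) < 2:
        raise ValueError("module must share at least 2 genes with the PPI")
    pairs = _edge_pairs(ppi)
    adj = _adjacency(pairs)
    rng = np.random.default_rng(seed)
    module = list(sub.genes)
    mset = set(module)
    degree = {g: len(adj[g]) for g in adj}
    bins: dict[int, list[str]] = {}
    for g in adj:
        bins.setdefault(degree_bin(degree[g]), []).append(g)
    for b in bins:
        bins[b].sort()

    def candidates_for(g: str) -> list[str]:
        b = degree_bin(degree[g])
        width = 0
        while True:
            pool = []
            for bb in range(b - width, b + width + 1):
                pool.extend(x for x in bins.get(bb, []) if x not in mset)
            if pool:
                if width > 0:
                    warnings.warn(
                        f"degree bin {b} had no replacement candidates for {g!r}; "
                        f"widened to +/-{width}"
                    )
                return pool
            width += 1
            if width > max(bins) + 1:
                raise ValueError(f"no non-module replacement candidates for {g!r}")

    # group module genes by (possibly widened) candidate pool so that genes
    # sharing a pool get distinct replacements, like the observed module
    pools: dict[tuple[str, ...], list[str]] = {}
    for g in module:
        pools.setdefault(tuple(candidates_for(g)), []).append(g)

    obs = sub.n_edges
    obs_within = sub.within_degree
    null_counts = np.empty(n_perm, dtype=int)
    null_within_ge = {g: 0 for g in module}
    for r in range(n_perm):
        replacement: dict[str, str] = {}
        for pool, members in pools.items():
            pool_arr = list(pool)
            if len(pool_arr) >= len(members):
                picks = rng.choice(len(pool_arr), size=len(members), replace=False)
            else:
                picks = rng.integers(0, len(pool_arr), size=len(members))
            for g, p_i in zip(members, picks):
                replacement[g] = pool_arr[p_i]
        perm_set = set(replacement.values())
        null_counts[r] = _induced_edge_count(perm_set, adj)
        for g in module:
            d_null = len(adj[replacement[g]] & perm_set)
            if d_null >= obs_within[g]:
                null_within_ge[g] += 1

    pvalue = (1.0 + (null_counts >= obs).sum()) / (1.0 + n_perm)
    hub = pd.DataFrame(
        {
            "gene": module,
            "within_degree": [int(obs_within[g]) for g in module],
            "pvalue": [(1.0 + null_within_ge[g]) / (1.0 + n_perm) for g in module],
        }
    ).sort_values(["pvalue", "within_degree"], ascending=[True, False]).reset_index(drop=True)

    return PPISubnetwork(
        genes=module,
        absent_genes=sub.absent_genes,
        edges=sub.edges,
        within_degree=sub.within_degree,
        n_edges=obs,
        pvalue=float(pvalue),
        hub_table=hub,
        n_perm=n_perm,
        seed=seed,
    )
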