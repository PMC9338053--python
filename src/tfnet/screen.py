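"""GSEA-style screen of TF-target gene sets against a ranked gene list.

Genes are ranked by the directional p-value, -sign(logFC) * log10(p), so
the head of the list holds genes up-regulated by the treatment and the tail
genes down-regulated.  A TF-target set enriched at the tail (ES < 0) marks
the TF as a candidate negative regulator (repressor) of the treatment-
associated program; enrichment at the head (ES > 0) a positive regulator.

The screen permutes gene-set membership (random sets of matched size) --
sample-label permutation is impossible from a ranked list alone.  The
permutation p-value is two-sided on |ES| against all matched-size null
sets, which keeps null p-values uniform while the sign information is
carried by ES and NES (NES = ES normalized by the mean |null ES| of
matching sign, the standard convention).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from tfnet.datatypes import EnrichmentResult, GeneSetCollection, RankedGeneList

logger = logging.getLogger("tfnet")

__all__ = ["rank_genes", "enrichment_score", "screen_collection"]


def rank_genes(de_table: pd.DataFrame) -> RankedGeneList:
    """Rank genes by the directional p-value, -sign(logFC) * log10(p).

    Requires columns gene, logFC, pvalue with p in (0, 1] and finite logFC.
    A p-value of exactly 0 is refused: apply an explicit floor (e.g. the
    smallest representable p of the upstream test) before ranking rather
    than relying on silent clamping.
    """
    required = {"gene", "logFC", "pvalue"}
    if not required <= set(de_table.columns):
        raise ValueError(f"DE table requires columns {sorted(required)}")
    p = de_table["pvalue"].to_numpy(dtype=float)
    lfc = de_table["logFC"].to_numpy(dtype=float)
    if (p <= 0).any():
        bad = de_table.loc[p <= 0, "gene"].tolist()
        raise ValueError(
            f"p-value of 0 (or below) for {bad}: floor the p-values explicitly "
            "(no silent clamping is applied)"
        )
    if (p > 1).any() or not np.isfinite(lfc).all():
        raise ValueError("p-values must lie in (0, 1] and logFC must be finite")
    stat = -np.sign(lfc) * np.log10(p)
    return RankedGeneList(table=pd.DataFrame({"gene": de_table["gene"], "stat": stat}))


def _es_profile(
    stats: np.ndarray, hit_mask: np.ndarray, weight: int
) -> tuple[float, np.ndarray, int]:
    n = len(stats)
    k = int(hit_mask.sum())
    if not 1 <= k < n:
        raise ValueError("need 1 <= |set intersect list| < |list|")
    if weight == 0:
        w = np.ones(k)
    else:
        w = np.abs(stats[hit_mask]) ** weight
    total = w.sum()
    if total == 0:  # all hit statistics exactly 0: fall back to equal steps
        w = np.ones(k)
        total = float(k)
    inc = np.full(n, -1.0 / (n - k))
    inc[hit_mask] = w / total
    profile = np.cumsum(inc)
    peak = int(np.argmax(np.abs(profile)))
    return float(profile[peak]), profile, peak


def enrichment_score(
    ranked: RankedGeneList, gene_set, weight: int = 1
) -> tuple[float, np.ndarray, list[str]]:
    """Running-sum enrichment score of a gene set against a ranked list.

    Walking down the list, the running sum rises by |stat|^weight
    (normalized to total 1 over the set's hits) at each set member and
    falls by 1/(N - N_hits) otherwise; ES is the signed extremum.  Returns
    (ES, running-sum profile, leading-edge genes): the set members at or
    before the peak for ES >= 0, at or after the trough for ES < 0.
    """
    if weight not in (0, 1):
        raise ValueError("weight must be 0 or 1")
    genes = ranked.genes
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    es, profile, peak = _es_profile(ranked.stats, hit_mask, weight)
    hit_pos = np.flatnonzero(hit_mask)
    if es >= 0:
        lead = [genes[i] for i in hit_pos if i <= peak]
    else:
        lead = [genes[i] for i in hit_pos if i >= peak]
    return es, profile, lead


def screen_collection(
    ranked: RankedGeneList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 10,
    weight: int = 1,
    seed: int = 0,
) -> EnrichmentResult:
    """Screen every gene set of a collection against the ranked list.

    Sets whose intersection with the list is below ``min_size`` are
    dropped (logged); sets with an empty intersection are kept as
    untestable rows, excluded from FDR.  The null for each set is
    ``n_perm`` random same-size subsets of the list; p is the add-one
    two-sided tail of |ES|, NES normalizes ES by the mean |null ES| of
    matching sign, and BH FDR is computed over the tested sets.  The
    output table is ordered by NES ascending (candidate negative
    regulators first).  Deterministic given ``seed``.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    rng = np.random.default_rng(seed)
    genes = ranked.genes
    stats = ranked.stats
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows = []
    for name, (_desc, members) in collection:
        pos = np.array(sorted(gene_pos[g] for g in members if g in gene_pos), dtype=int)
        k = len(pos)
        if k == 0:
            rows.append(
                {
                    "set": name,
                    "es": np.nan,
                    "nes": np.nan,
                    "pvalue": np.nan,
                    "size": 0,
                    "leading_edge": [],
                    "untestable": True,
                }
            )
            continue
        if k < min_size:
            logger.info("screen_collection: dropping set %r (size %d < %d)", name, k, min_size)
            continue
        hit_mask = np.zeros(n, dtype=bool)
        hit_mask[pos] = True
        es, _profile, peak = _es_profile(stats, hit_mask, weight)
        null_es = np.empty(n_perm)
        for r in range(n_perm):
            null_mask = np.zeros(n, dtype=bool)
            null_mask[rng.choice(n, size=k, replace=False)] = True
            null_es[r], _, _ = _es_profile(stats, null_mask, weight)
        pvalue = (1.0 + (np.abs(null_es) >= abs(es)).sum()) / (1.0 + n_perm)
        same_sign = np.abs(null_es[np.sign(null_es) == np.sign(es)]) if es != 0 else np.abs(null_es)
        denom = same_sign.mean() if len(same_sign) else np.abs(null_es).mean()
        nes = es / denom if denom > 0 else np.nan
        if es >= 0:
            lead = [genes[i] for i in pos if i <= peak]
        else:
            lead = [genes[i] for i in pos if i >= peak]
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": nes,
                "pvalue": pvalue,
                "size": k,
                "leading_edge": lead,
                "untestable": False,
            }
        )

    table = pd.DataFrame(rows)
    if table.empty or bool(table["untestable"].all()):
        raise ValueError("all gene sets were filtered out or untestable")
    tested = ~table["untestable"]
    from scipy.stats import false_discovery_control

    fdr = np.full(len(table), np.nan)
    fdr[tested.to_numpy()] = false_discovery_control(
        table.loc[tested, "pvalue"].to_numpy(), method="bh"
    )
    table["fdr"] = fdr
    table = table.sort_values(
        ["untestable", "nes", "set"], ascending=[True, True, True], kind="mergesort"
    ).reset_index(drop=True)
    table = table[["set", "es", "nes", "pvalue", "fdr", "size", "leading_edge", "untestable"]]
    return EnrichmentResult(table=table, n_permutations=n_perm, seed=seed)
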