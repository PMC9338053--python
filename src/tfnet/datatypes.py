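"""Shared domain types for the TF-network pipeline.

Expression matrices, evidence lists, the network at its three pipeline
stages (signed-undirected, evidence-oriented, level-stratified) and the
result containers of the downstream statistics.  All containers validate
their invariants at construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "EvidenceEdgeList",
    "SignedNetwork",
    "DirectedNetwork",
    "LayeredNetwork",
    "RankedGeneList",
    "GeneSetCollection",
    "GroundTruthModel",
    "MIParams",
    "MotifReport",
    "CentralityTable",
    "EnrichmentResult",
    "CoexpressionModules",
    "ModuleEigengenes",
    "OverlapResult",
    "PPISubnetwork",
    "canonical_pair",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) ordering for an undirected gene pair."""
    return (a, b) if a <= b else (b, a)


def _check_unique(ids, what: str) -> None:
    seen: dict = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = True
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression with per-sample metadata.

    ``values`` is a real matrix aligned to ``gene_ids`` (rows) and
    ``sample_ids`` (columns).  ``metadata`` is a DataFrame indexed by sample
    id with at least the columns ``condition``, ``timepoint``, ``replicate``.
    NaN entries are permitted (missing measurements); infinities are not.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if np.isinf(self.values).any():
            raise ValueError("expression values must be finite (NaN allowed for missing)")
        missing_meta = set(self.sample_ids) - set(map(str, self.metadata.index))
        if missing_meta:
            raise ValueError(f"metadata missing for samples: {sorted(missing_meta)}")
        required = {"condition", "timepoint", "replicate"}
        absent = required - set(self.metadata.columns)
        if absent:
            raise ValueError(f"metadata lacks required columns: {sorted(absent)}")
        self.metadata = self.metadata.loc[[s for s in self.sample_ids]]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_values(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None
        return self.values[i]

    def groups(self) -> pd.core.groupby.DataFrameGroupBy:
        return self.metadata.groupby(["condition", "timepoint"], observed=True)


@dataclass
class EvidenceEdgeList:
    """Physical TF->target binding evidence: (tf, target, source) records.

    (tf, target) pairs are deduplicated; provenance tags of merged duplicates
    are joined with ';'.
    """

    records: pd.DataFrame  # columns: tf, target, source

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, copy=True)
        for col in ("tf", "target"):
            if col not in df.columns:
                raise ValueError(f"evidence list lacks column {col!r}")
            df[col] = df[col].astype(str).str.strip()
        if "source" not in df.columns:
            df["source"] = "unknown"
        df = (
            df.groupby(["tf", "target"], sort=True)["source"]
            .apply(lambda s: ";".join(sorted(set(map(str, s)))))
            .reset_index()
        )
        self.records = df
        self._pairs = set(zip(df["tf"], df["target"]))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self._pairs

    def __len__(self) -> int:
        return len(self.records)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._pairs)


@dataclass
class SignedEdge:
    a: str
    b: str
    mi: float
    sign: int
    consensus: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-edge not allowed: {self.a}")
        if (self.a, self.b) != canonical_pair(self.a, self.b):
            raise ValueError(f"edge ({self.a}, {self.b}) not in canonical order")
        if not np.isfinite(self.mi) or self.mi < 0:
            raise ValueError(f"mi must be finite and >= 0, got {self.mi}")
        if self.sign not in (+1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if not 0.0 <= self.consensus <= 1.0:
            raise ValueError(f"consensus must be in [0, 1], got {self.consensus}")


@dataclass
class SignedNetwork:
    """Undirected signed-MI network (post-inference, pre-orientation)."""

    nodes: list[str]
    edges: dict[tuple[str, str], SignedEdge]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = [str(n) for n in self.nodes]
        _check_unique(self.nodes, "node ids")
        node_set = set(self.nodes)
        for key, e in self.edges.items():
            if key != (e.a, e.b):
                raise ValueError(f"edge key {key} does not match edge ({e.a}, {e.b})")
            if e.a not in node_set or e.b not in node_set:
                raise ValueError(f"edge ({e.a}, {e.b}) references unknown node")

    def add_edge(self, a: str, b: str, mi: float, sign: int, consensus: float) -> None:
        a, b = canonical_pair(a, b)
        self.edges[(a, b)] = SignedEdge(a, b, float(mi), int(sign), float(consensus))

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.edges

    def regulon(self, tf: str) -> dict[str, float]:
        """Signed MI weights of every partner of ``tf``."""
        if tf not in set(self.nodes):
            raise KeyError(f"{tf!r} not in network")
        out: dict[str, float] = {}
        for (a, b), e in self.edges.items():
            if a == tf:
                out[b] = e.sign * e.mi
            elif b == tf:
                out[a] = e.sign * e.mi
        return out

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), e in self.edges.items():
            g.add_edge(a, b, mi=e.mi, sign=e.sign, consensus=e.consensus)
        return g


@dataclass
class DirectedEdge:
    tf: str
    target: str
    mi: float
    sign: int
    evidence: bool = True


@dataclass
class DirectedNetwork:
    """Evidence-oriented network: directed TF->target edges plus undirected
    residual edges for pairs with no orientation evidence."""

    nodes: list[str]
    edges: dict[tuple[str, str], DirectedEdge]
    residual_edges: dict[tuple[str, str], SignedEdge] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = [str(n) for n in self.nodes]
        _check_unique(self.nodes, "node ids")
        node_set = set(self.nodes)
        for (u, v), e in self.edges.items():
            if (u, v) != (e.tf, e.target):
                raise ValueError(f"edge key {(u, v)} does not match ({e.tf}, {e.target})")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
        for key, e in self.residual_edges.items():
            if key != canonical_pair(*key):
                raise ValueError(f"residual edge key {key} not canonical")

    def to_graph(self, include_self_loops: bool = True) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), e in self.edges.items():
            if u == v and not include_self_loops:
                continue
            g.add_edge(u, v, mi=e.mi, sign=e.sign, evidence=e.evidence)
        return g


STRATA = ("TOP", "MIDDLE", "BOTTOM")


@dataclass
class LayeredNetwork:
    """Directed network plus vertex-sort stratification.

    ``levels`` maps node -> (stratum, (lo, hi)) where [lo, hi] is the
    level-interval from leaf removal on the condensation DAG and its
    transpose (1 = bottom).  ``supernode`` maps node -> SCC id.
    """

    network: DirectedNetwork
    levels: dict[str, tuple[str, tuple[int, int]]]
    supernode: dict[str, int]
    depth: int

    def __post_init__(self) -> None:
        sorted_nodes = {n for n in self.levels}
        for n in sorted_nodes:
            stratum, (lo, hi) = self.levels[n]
            if stratum not in STRATA:
                raise ValueError(f"unknown stratum {stratum!r} for node {n}")
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid level interval [{lo}, {hi}] for node {n}")
        # SCC members share stratum and interval
        by_scc: dict[int, set] = {}
        for n in sorted_nodes:
            by_scc.setdefault(self.supernode[n], set()).add(self.levels[n])
        for scc_id, assigned in by_scc.items():
            if len(assigned) > 1:
                raise ValueError(f"SCC {scc_id} members disagree on stratum/interval")

    def stratum(self, node: str) -> str:
        return self.levels[node][0]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node": n,
                "stratum": s,
                "level_lo": lo,
                "level_hi": hi,
                "scc": self.supernode[n],
            }
            for n, (s, (lo, hi)) in sorted(self.levels.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class RankedGeneList:
    """Genes ordered by a directional significance statistic, descending.

    The statistic is -sign(logFC) * log10(p): large positive values are
    strongly up-regulated genes, large negative strongly down-regulated.
    Ties are broken by gene symbol ascending.  No duplicate genes.
    """

    table: pd.DataFrame  # columns: gene, stat

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table, copy=True)
        if not {"gene", "stat"} <= set(df.columns):
            raise ValueError("ranked list requires columns 'gene' and 'stat'")
        df["gene"] = df["gene"].astype(str)
        _check_unique(df["gene"].tolist(), "genes in ranked list")
        df = df.sort_values(
            ["stat", "gene"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        self.table = df

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    @property
    def stats(self) -> np.ndarray:
        return self.table["stat"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSetCollection:
    """Ordered mapping set_name -> (description, member genes)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_desc, genes) in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            _check_unique(genes, f"genes in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, name: str) -> list[str]:
        return list(self.sets[name][1])


@dataclass
class GroundTruthModel:
    """Hidden layered regulatory network behind the synthetic generator.

    ``tf_levels`` maps TF -> level index (1 = bottom of the TF pyramid).
    ``edges`` maps (regulator, target) -> signed effect weight; regulators
    are always TFs, targets are TFs or effector genes.  ``condition_effects``
    maps (condition, timepoint) -> per-top-TF additive shift array.
    ``cycle_members`` groups TFs that form declared regulatory cycles.
    """

    tf_levels: dict[str, int]
    edges: dict[tuple[str, str], float]
    targets: list[str]
    condition_effects: dict[tuple[str, int], np.ndarray]
    noise_sd: float
    seed: int
    cycle_members: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        in_cycle = {tf for grp in self.cycle_members.values() for tf in grp}
        for (reg, tgt), w in self.edges.items():
            if w == 0:
                raise ValueError(f"zero weight on edge {reg}->{tgt}")
            if reg not in self.tf_levels:
                raise ValueError(f"regulator {reg!r} is not a TF")
            if tgt in self.tf_levels:
                lr, lt = self.tf_levels[reg], self.tf_levels[tgt]
                if lt > lr:
                    raise ValueError(f"edge {reg}->{tgt} goes up the hierarchy")
                if lt == lr and not (reg in in_cycle and tgt in in_cycle):
                    raise ValueError(
                        f"equal-level edge {reg}->{tgt} outside declared cycle group"
                    )

    @property
    def tfs(self) -> list[str]:
        return list(self.tf_levels)

    @property
    def top_tfs(self) -> list[str]:
        top = max(self.tf_levels.values())
        return [t for t, l in self.tf_levels.items() if l == top]

    def tf_tf_edges(self) -> set[tuple[str, str]]:
        return {
            (r, t) for (r, t) in self.edges if t in self.tf_levels and r in self.tf_levels
        }

    def undirected_true_pairs(self) -> set[tuple[str, str]]:
        """Ground-truth edge set as canonical undirected pairs."""
        return {canonical_pair(r, t) for (r, t) in self.edges}

    def true_stratum(self, tf: str) -> str:
        lvl = self.tf_levels[tf]
        top = max(self.tf_levels.values())
        if lvl == top:
            return "TOP"
        if lvl == 1:
            return "BOTTOM"
        return "MIDDLE"


@dataclass
class MIParams:
    """Settings of the MI network-inference stage.

    ``n_bins`` "auto" resolves to max(3, floor(sqrt(n_samples))).  The
    permutation/bootstrap defaults mirror common regulon-inference practice:
    100 permutations, BH FDR 0.05, 100 bootstraps, 95% consensus.
    ``dpi_tolerance`` is the DPI epsilon (0 = strict weakest-edge pruning).
    """

    n_bins: int | str = "auto"
    n_permutations: int = 100
    fdr_alpha: float = 0.05
    n_bootstraps: int = 100
    consensus: float = 0.95
    dpi_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bins != "auto":
            if int(self.n_bins) < 2:
                raise ValueError("n_bins must be >= 2 or 'auto'")
            self.n_bins = int(self.n_bins)
        if self.n_permutations < 20:
            raise ValueError("n_permutations must be >= 20")
        if not 0.0 < self.consensus <= 1.0:
            raise ValueError("consensus must be in (0, 1]")
        if not 0.0 <= self.dpi_tolerance < 1.0:
            raise ValueError("dpi_tolerance must be in [0, 1)")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")

    def resolve_bins(self, n_samples: int) -> int:
        if self.n_bins == "auto":
            return max(3, int(np.floor(np.sqrt(n_samples))))
        return int(self.n_bins)

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MotifReport:
    """Per-class 3-node motif census with degree-preserving null z-scores.

    ``table`` has one row per connected triad class (13 classes) with
    observed count, null mean/sd and z-score (None where sd == 0).
    """

    table: pd.DataFrame  # columns: motif, observed, null_mean, null_sd, z
    n_random: int
    seed: int

    def __post_init__(self) -> None:
        if (self.table["observed"] < 0).any():
            raise ValueError("observed motif counts must be non-negative")

    def zscore(self, motif: str) -> Optional[float]:
        row = self.table.loc[self.table["motif"] == motif]
        if row.empty:
            raise KeyError(f"unknown motif class {motif!r}")
        z = row["z"].iloc[0]
        return None if pd.isna(z) else float(z)


@dataclass
class CentralityTable:
    """Per-node centralities plus the network-level clustering coefficient."""

    per_node: pd.DataFrame  # index: node; columns as available
    global_clustering: Optional[float] = None
    mean_local_clustering: Optional[float] = None

    def __post_init__(self) -> None:
        if "local_clustering" in self.per_node.columns:
            cc = self.per_node["local_clustering"]
            if ((cc < -1e-12) | (cc > 1 + 1e-12)).any():
                raise ValueError("local clustering coefficients must lie in [0, 1]")


@dataclass
class EnrichmentResult:
    """TF-regulator screen output: per-set ES/NES/p/q table ranked by NES."""

    table: pd.DataFrame
    # columns: set, es, nes, pvalue, fdr, size, leading_edge (list), untestable
    n_permutations: int
    seed: int

    def ranked(self, ascending: bool = True) -> pd.DataFrame:
        """Screen table ordered by NES (ascending = negative regulators first)."""
        ok = self.table.loc[~self.table["untestable"]]
        return ok.sort_values(["nes", "set"], ascending=[ascending, True]).reset_index(
            drop=True
        )


@dataclass
class CoexpressionModules:
    """Gene -> module labels from TOM clustering (module 0 = unassigned)."""

    labels: pd.Series  # index: gene, values: int module ids
    beta: float
    merge_heights: np.ndarray
    cut_height: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        min_size = self.params.get("min_module_size", 0)
        sizes = self.labels[self.labels != 0].value_counts()
        if (sizes < min_size).any():
            raise ValueError("module below min_module_size escaped relabeling")

    def module_genes(self, module: int) -> list[str]:
        return self.labels.index[self.labels == module].tolist()

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})


@dataclass
class ModuleEigengenes:
    """Module eigengene profiles, per-gene kME, and hub flags (kME > 0.7)."""

    eigengenes: pd.DataFrame  # index: sample, columns: module id
    kme: pd.Series  # index: gene, correlation with own-module eigengene
    hub: pd.Series  # index: gene, bool
    hub_threshold: float = 0.7

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.eigengenes.to_numpy(), axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("eigengenes must be unit-norm over samples")
        finite = self.kme.dropna()
        if ((finite < -1 - 1e-9) | (finite > 1 + 1e-9)).any():
            raise ValueError("kME must lie in [-1, 1]")
        if bool((self.hub & ~(self.kme > self.hub_threshold)).any()):
            raise ValueError("hub flag set for gene with kME <= threshold")


@dataclass
class OverlapResult:
    """Hypergeometric overlap of two gene sets within a universe."""

    odds_ratio: float
    pvalue: float
    adjusted_pvalue: float
    overlap: list[str]
    universe_size: int
    size_a: int
    size_b: int

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")
        if self.odds_ratio < 0:
            raise ValueError("odds ratio must be >= 0")


@dataclass
class PPISubnetwork:
    """Module projection onto a PPI background with connectivity statistics."""

    genes: list[str]
    absent_genes: list[str]
    edges: list[tuple[str, str]]
    within_degree: pd.Series
    n_edges: int
    pvalue: Optional[float] = None
    hub_table: Optional[pd.DataFrame] = None
    n_perm: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")
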