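"""Readers and writers for the pipeline's file formats.

Expression TSV + metadata TSV, GMT gene sets, evidence/PPI/DE edge tables,
and network serialization to SIF / GraphML / TSV.  Readers validate rather
than coerce: malformed input is a hard error naming the offending record,
and every dropped record is logged with its reason.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from tfnet.datatypes import (
    DirectedEdge,
    DirectedNetwork,
    EvidenceEdgeList,
    ExpressionMatrix,
    GeneSetCollection,
    LayeredNetwork,
    SignedEdge,
    SignedNetwork,
    canonical_pair,
)

logger = logging.getLogger("tfnet")

__all__ = [
    "read_expression",
    "read_gene_sets",
    "read_evidence",
    "read_ppi",
    "read_de_table",
    "write_network",
    "read_network",
    "write_expression",
]

NETWORK_FORMATS = ("sif", "graphml", "tsv")
#: fraction of samples that must be observed for a gene to survive loading
MAX_MISSING_FRACTION = 0.5


def read_expression(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Load a genes x samples TSV plus a sample-metadata TSV.

    The expression file has a header row of sample ids and gene ids in the
    first column.  Genes with missing values in more than half of the
    samples are dropped (logged).  Duplicate ids, non-numeric cells and
    metadata/sample mismatches are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g).strip() for g in df.index]
    samples = [str(s).strip() for s in df.columns]
    dup_genes = sorted({g for g in genes if genes.count(g) > 1})
    if dup_genes:
        raise ValueError(f"duplicate gene ids in {path}: {dup_genes}")
    dup_samples = sorted({s for s in samples if samples.count(s) > 1})
    if dup_samples:
        raise ValueError(f"duplicate sample ids in {path}: {dup_samples}")

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() in ("", "NA", "NaN", "nan"):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(raw)
            except ValueError:
                raise ValueError(
                    f"non-numeric expression value {raw!r} at gene {genes[i]!r}, "
                    f"sample {samples[j]!r}"
                ) from None

    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str).str.strip()
    missing = set(samples) - set(meta.index)
    extra = set(meta.index) - set(samples)
    if missing or extra:
        raise ValueError(
            f"metadata/sample mismatch: missing metadata for {sorted(missing)}, "
            f"metadata without samples for {sorted(extra)}"
        )

    frac_missing = np.isnan(values).mean(axis=1)
    keep = frac_missing <= MAX_MISSING_FRACTION
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = [g for g, k in zip(genes, keep) if not k]
        logger.info(
            "read_expression: dropped %d gene(s) with >%.0f%% missing values: %s",
            n_dropped,
            100 * MAX_MISSING_FRACTION,
            dropped,
        )
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(genes, keep) if k],
        sample_ids=samples,
        values=values[keep],
        metadata=meta,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path, metadata_path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")
    expr.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>...`` per line.

    File order is preserved.  Duplicate genes within a set are deduplicated
    with a warning; a duplicate set name or a line with fewer than three
    fields is an error.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            name, desc = fields[0].strip(), fields[1]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene set name {name!r} at line {lineno}")
            genes: list[str] = []
            seen: set[str] = set()
            dups: list[str] = []
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    dups.append(g)
                    continue
                seen.add(g)
                genes.append(g)
            if dups:
                logger.warning(
                    "read_gene_sets: set %r line %d: deduplicated genes %s",
                    name,
                    lineno,
                    sorted(set(dups)),
                )
            sets[name] = (desc, genes)
    return GeneSetCollection(sets=sets)


def read_evidence(path: str | Path) -> EvidenceEdgeList:
    """Read a TF->target binding-evidence TSV (columns tf, target[, source])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return EvidenceEdgeList(records=df)


def read_ppi(path: str | Path) -> pd.DataFrame:
    """Read a PPI edge-list TSV (columns a, b); deduplicates undirected pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"a", "b"} <= set(df.columns):
        raise ValueError(f"{path}: PPI table requires columns 'a' and 'b'")
    pairs = sorted(
        {canonical_pair(a.strip(), b.strip()) for a, b in zip(df["a"], df["b"]) if a.strip() != b.strip()}
    )
    return pd.DataFrame(pairs, columns=["a", "b"])


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression TSV (columns gene, logFC, pvalue)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "logFC", "pvalue"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: DE table requires columns {sorted(required)}")
    df["gene"] = df["gene"].astype(str).str.strip()
    return df


# ---------------------------------------------------------------------------
# network serialization


def _sif_label(sign: int) -> str:
    return "activates" if sign > 0 else "represses"


def write_network(net, path: str | Path, format: str = "graphml") -> None:
    """Serialize a network.

    SIF uses interaction labels ``activates``/``represses``/``undirected``;
    GraphML and TSV carry mi/sign/consensus/evidence/stratum attributes and
    round-trip losslessly via :func:`read_network`.
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(
            f"unknown network format {format!r}; supported: {', '.join(NETWORK_FORMATS)}"
        )
    path = Path(path)
    if format == "sif":
        _write_sif(net, path)
    elif format == "tsv":
        _write_tsv(net, path)
    else:
        _write_graphml(net, path)


def _iter_edge_rows(net):
    if isinstance(net, SignedNetwork):
        for (a, b), e in sorted(net.edges.items()):
            yield {
                "a": a,
                "b": b,
                "mi": e.mi,
                "sign": e.sign,
                "consensus": e.consensus,
                "kind": "undirected",
            }
    else:
        dnet = net.network if isinstance(net, LayeredNetwork) else net
        for (u, v), e in sorted(dnet.edges.items()):
            yield {
                "a": u,
                "b": v,
                "mi": e.mi,
                "sign": e.sign,
                "evidence": e.evidence,
                "kind": "directed",
            }
        for (a, b), e in sorted(dnet.residual_edges.items()):
            yield {
                "a": a,
                "b": b,
                "mi": e.mi,
                "sign": e.sign,
                "consensus": e.consensus,
                "kind": "residual",
            }


def _write_sif(net, path: Path) -> None:
    with open(path, "w") as fh:
        written: set[str] = set()
        for row in _iter_edge_rows(net):
            label = _sif_label(row["sign"]) if row["kind"] != "residual" else "undirected"
            fh.write(f"{row['a']}\t{label}\t{row['b']}\n")
            written.update((row["a"], row["b"]))
        nodes = net.network.nodes if isinstance(net, LayeredNetwork) else net.nodes
        for n in nodes:
            if n not in written:
                fh.write(f"{n}\n")


def _write_tsv(net, path: Path) -> None:
    rows = list(_iter_edge_rows(net))
    df = pd.DataFrame(
        rows, columns=["a", "b", "kind", "mi", "sign", "consensus", "evidence"]
    )
    df.to_csv(path, sep="\t", index=False)


def _net_kind(net) -> str:
    if isinstance(net, SignedNetwork):
        return "signed"
    if isinstance(net, LayeredNetwork):
        return "layered"
    if isinstance(net, DirectedNetwork):
        return "directed"
    raise TypeError(f"unsupported network type {type(net).__name__}")


def _write_graphml(net, path: Path) -> None:
    kind = _net_kind(net)
    if kind == "signed":
        g: nx.Graph | nx.DiGraph = net.to_graph()
    else:
        dnet = net.network if kind == "layered" else net
        g = dnet.to_graph()
        for (a, b), e in dnet.residual_edges.items():
            g.add_edge(a, b, mi=e.mi, sign=e.sign, consensus=e.consensus, residual=True)
        if kind == "layered":
            for n, (stratum, (lo, hi)) in net.levels.items():
                g.nodes[n]["stratum"] = stratum
                g.nodes[n]["level_lo"] = int(lo)
                g.nodes[n]["level_hi"] = int(hi)
                g.nodes[n]["scc"] = int(net.supernode[n])
            g.graph["depth"] = int(net.depth)
    g.graph["network_type"] = kind
    params = net.network.params if kind == "layered" else net.params
    g.graph["params"] = json.dumps(params, sort_keys=True, default=str)
    nx.write_graphml(g, path)


def read_network(path: str | Path):
    """Read a GraphML network written by :func:`write_network`."""
    g = nx.read_graphml(path)
    kind = g.graph.get("network_type")
    params = json.loads(g.graph.get("params", "{}"))
    if kind == "signed":
        net = SignedNetwork(nodes=sorted(g.nodes), edges={}, params=params)
        for a, b, d in g.edges(data=True):
            net.add_edge(a, b, mi=d["mi"], sign=int(d["sign"]), consensus=d["consensus"])
        return net
    if kind in ("directed", "layered"):
        edges: dict[tuple[str, str], DirectedEdge] = {}
        residual: dict[tuple[str, str], SignedEdge] = {}
        for u, v, d in g.edges(data=True):
            if d.get("residual", False):
                a, b = canonical_pair(u, v)
                residual[(a, b)] = SignedEdge(a, b, d["mi"], int(d["sign"]), d["consensus"])
            else:
                edges[(u, v)] = DirectedEdge(
                    u, v, d["mi"], int(d["sign"]), bool(d.get("evidence", True))
                )
        dnet = DirectedNetwork(
            nodes=sorted(g.nodes), edges=edges, residual_edges=residual, params=params
        )
        if kind == "directed":
            return dnet
        levels = {
            n: (d["stratum"], (int(d["level_lo"]), int(d["level_hi"])))
            for n, d in g.nodes(data=True)
        }
        supernode = {n: int(d["scc"]) for n, d in g.nodes(data=True)}
        return LayeredNetwork(
            network=dnet, levels=levels, supernode=supernode, depth=int(g.graph["depth"])
        )
    raise ValueError(f"{path}: not a tfnet GraphML file (missing network_type)")
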