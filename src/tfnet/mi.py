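"""Signed MI network inference with permutation, bootstrap and DPI stages.

Mutual information is estimated on equal-frequency binned profiles (bins =
max(3, floor(sqrt(n))) by default) and reported in nats.  Edge significance
comes from a per-regulator permutation test with BH FDR control; stability
from bootstrap consensus; indirect edges are pruned with the data-processing
inequality (DPI): in every triangle the weakest edge is removed when its MI
falls below (1 - eps) times the smaller of the other two.

The permutation scan is the hot loop.  All profiles are reduced to integer
bin labels once per bootstrap, after which the joint-entropy term of every
(permutation, target) pair is a contingency count over at most bins^2 cells;
a numba kernel (with an equivalent pure-numpy fallback) accumulates these
counts and looks the c*ln(c) terms up in a precomputed table.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as _scipy_stats

from tfnet.datatypes import (
    ExpressionMatrix,
    MIParams,
    SignedNetwork,
    canonical_pair,
)

__all__ = [
    "mutual_information",
    "permutation_significance",
    "bootstrap_consensus",
    "dpi_prune",
    "infer_network",
]

MIN_PAIR_SAMPLES = 8
MIN_BOOTSTRAP_SAMPLES = 15

try:  # pragma: no cover - exercised implicitly
    import numba

    @numba.njit(cache=True)
    def _sjoint_kernel(t_rows, labels, n_bins, table, out):  # pragma: no cover
        n_rows, n = t_rows.shape
        n_genes = labels.shape[0]
        counts = np.zeros(n_bins * n_bins, dtype=np.int64)
        for r in range(n_rows):
            for g in range(n_genes):
                for s in range(n):
                    counts[t_rows[r, s] * n_bins + labels[g, s]] += 1
                acc = 0.0
                for k in range(n_bins * n_bins):
                    c = counts[k]
                    if c > 0:
                        acc += table[c]
                        counts[k] = 0
                out[r, g] = acc

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def _sjoint_numpy(t_rows: np.ndarray, labels: np.ndarray, n_bins: int, table: np.ndarray) -> np.ndarray:
    n_rows, n = t_rows.shape
    n_genes = labels.shape[0]
    out = np.empty((n_rows, n_genes))
    gene_off = (np.arange(n_genes, dtype=np.int64) * (n_bins * n_bins))[:, None]
    for r in range(n_rows):
        idx = (gene_off + t_rows[r][None, :].astype(np.int64) * n_bins + labels).ravel()
        counts = np.bincount(idx, minlength=n_genes * n_bins * n_bins)
        out[r] = table[counts].reshape(n_genes, n_bins * n_bins).sum(axis=1)
    return out


def _sjoint(t_rows: np.ndarray, labels: np.ndarray, n_bins: int, table: np.ndarray) -> np.ndarray:
    """Sum of c*ln(c) over the joint contingency of every (row, gene) pair."""
    if HAVE_NUMBA:
        out = np.empty((t_rows.shape[0], labels.shape[0]))
        _sjoint_kernel(
            np.ascontiguousarray(t_rows, dtype=np.int32),
            np.ascontiguousarray(labels, dtype=np.int32),
            n_bins,
            table,
            out,
        )
        return out
    return _sjoint_numpy(t_rows, labels, n_bins, table)


def _plogp_table(n: int) -> np.ndarray:
    c = np.arange(n + 1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = c * np.log(c)
    t[0] = 0.0
    return t


def _bin_labels(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin labels per row (ties broken by sample order)."""
    values = np.atleast_2d(values)
    n_genes, n = values.shape
    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    ranks[np.arange(n_genes)[:, None], order] = np.arange(n)[None, :]
    return ((ranks * n_bins) // n).astype(np.int32)


def mutual_information(x, y, n_bins: int | str = "auto") -> float:
    """Binned mutual information of two profiles, in nats.

    Profiles are reduced to equal-frequency bins (``n_bins`` = "auto" gives
    max(3, floor(sqrt(n)))) and MI of the joint bin distribution is
    returned.  Missing entries are removed pairwise; at least 8 complete
    pairs are required.  A constant vector carries no measurable dependence
    and returns 0 with a warning.  Exactly symmetric in its arguments.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < MIN_PAIR_SAMPLES:
        raise ValueError(
            f"need >= {MIN_PAIR_SAMPLES} complete sample pairs, got {n}"
        )
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: no dependence measurable, MI = 0")
        return 0.0
    if n_bins == "auto":
        n_bins = max(3, int(np.floor(np.sqrt(n))))
    n_bins = int(n_bins)
    lx = _bin_labels(x, n_bins)[0]
    ly = _bin_labels(y, n_bins)[0]
    joint = np.bincount(lx.astype(np.int64) * n_bins + ly, minlength=n_bins * n_bins)
    table = _plogp_table(n)
    # summing the joint plogp terms in sorted order makes the result
    # bitwise-invariant under argument swap (transposed contingency)
    s_joint = float(np.sort(table[joint[joint > 0]]).sum())
    s_x = float(table[np.bincount(lx, minlength=n_bins)].sum())
    s_y = float(table[np.bincount(ly, minlength=n_bins)].sum())
    mi = np.log(n) + (s_joint - s_x - s_y) / n
    return max(0.0, float(mi))


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    return _scipy_stats.false_discovery_control(pvals, method="bh")


def _scan_tf(
    labels: np.ndarray,
    tf_idx: int,
    target_idx: np.ndarray,
    n_bins: int,
    n_perm: int,
    rng: np.random.Generator,
    table: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed MI and permutation-null MI of one TF against targets.

    Returns (obs (T,), null (n_perm, T)) in nats.
    """
    n = labels.shape[1]
    t = labels[tf_idx]
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    t_rows = np.vstack([t[None, :], t[perm_idx]])
    tgt_labels = labels[target_idx]
    s_joint = _sjoint(t_rows, tgt_labels, n_bins, table)
    s_t = float(table[np.bincount(t, minlength=n_bins)].sum())
    s_g = table[
        np.apply_along_axis(np.bincount, 1, tgt_labels, minlength=n_bins)
    ].sum(axis=1)
    mi = np.log(n) + (s_joint - s_t - s_g[None, :]) / n
    np.maximum(mi, 0.0, out=mi)
    return mi[0], mi[1:]


def permutation_significance(
    expr: ExpressionMatrix,
    tf: str,
    params: MIParams | None = None,
    seed: int = 0,
):
    """Permutation-test MI of one TF against every other gene.

    The null is built by permuting the TF profile ``n_permutations`` times
    and recomputing MI against all targets; p = (1 + #{null >= obs}) /
    (1 + n_permutations) (add-one estimator, never exactly 0).  BH FDR is
    applied across targets; targets with adjusted p < fdr_alpha are flagged
    retained.  Returns a DataFrame (target, mi, pvalue, adjusted_pvalue,
    retained).
    """
    import pandas as pd

    params = params or MIParams()
    if tf not in expr.gene_ids:
        raise KeyError(f"TF {tf!r} not in expression matrix")
    rng = np.random.default_rng(seed)
    n = expr.n_samples
    n_bins = params.resolve_bins(n)
    tf_idx = expr.gene_ids.index(tf)
    target_idx = np.array([i for i in range(expr.n_genes) if i != tf_idx])
    targets = [expr.gene_ids[i] for i in target_idx]

    if np.isnan(expr.values).any():
        obs, null = _scan_tf_pairwise(
            expr.values, tf_idx, target_idx, params, n_bins, rng
        )
    else:
        labels = _bin_labels(expr.values, n_bins)
        table = _plogp_table(n)
        obs, null = _scan_tf(
            labels, tf_idx, target_idx, n_bins, params.n_permutations, rng, table
        )
    pvals = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (1.0 + params.n_permutations)
    adj = _bh_adjust(pvals)
    return pd.DataFrame(
        {
            "target": targets,
            "mi": obs,
            "pvalue": pvals,
            "adjusted_pvalue": adj,
            "retained": adj < params.fdr_alpha,
        }
    )


def _scan_tf_pairwise(
    values: np.ndarray,
    tf_idx: int,
    target_idx: np.ndarray,
    params: MIParams,
    n_bins: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Missing-data path: pairwise-complete MI, one pair at a time."""
    x = values[tf_idx]
    n_perm = params.n_permutations
    obs = np.empty(len(target_idx))
    null = np.empty((n_perm, len(target_idx)))
    perms = [rng.permutation(len(x)) for _ in range(n_perm)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, gi in enumerate(target_idx):
            y = values[gi]
            obs[j] = mutual_information(x, y, n_bins)
            for k, pi in enumerate(perms):
                null[k, j] = mutual_information(x[pi], y, n_bins)
    return obs, null


def bootstrap_consensus(
    expr: ExpressionMatrix,
    tf_list: list[str],
    params: MIParams | None = None,
    seed: int = 0,
) -> SignedNetwork:
    """Bootstrap-consensus signed MI network over TF-gene pairs (pre-DPI).

    Samples are resampled with replacement ``n_bootstraps`` times; within
    each bootstrap every TF is permutation-tested against all other genes
    (per-TF BH).  An undirected pair is kept when it is retained -- from
    either endpoint's regulon scan -- in at least ``consensus`` of the
    bootstraps.  Edge MI is the median over retaining bootstraps; the edge
    sign is the sign of the full-data Pearson correlation.
    """
    params = params or MIParams()
    tf_list = list(dict.fromkeys(tf_list))
    if len(tf_list) < 2:
        raise ValueError("need at least 2 TFs")
    missing = [t for t in tf_list if t not in expr.gene_ids]
    if missing:
        raise KeyError(f"TFs not in expression matrix: {missing}")
    n = expr.n_samples
    if n < MIN_BOOTSTRAP_SAMPLES:
        raise ValueError(
            f"bootstrap unreliable below {MIN_BOOTSTRAP_SAMPLES} samples (got {n})"
        )
    if np.isnan(expr.values).any():
        raise ValueError(
            "bootstrap_consensus requires a complete matrix; drop or impute "
            "missing values first (read_expression already drops genes with "
            ">50% missing)"
        )

    rng = np.random.default_rng(seed)
    n_bins = params.resolve_bins(n)
    table = _plogp_table(n)
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    tf_indices = [gene_index[t] for t in tf_list]

    pair_hits: dict[tuple[str, str], int] = {}
    pair_mis: dict[tuple[str, str], list[float]] = {}

    for _b in range(params.n_bootstraps):
        cols = rng.integers(0, n, size=n)
        labels = _bin_labels(expr.values[:, cols], n_bins)
        seen: dict[tuple[str, str], float] = {}
        for tf, tf_idx in zip(tf_list, tf_indices):
            target_idx = np.array([i for i in range(expr.n_genes) if i != tf_idx])
            obs, null = _scan_tf(
                labels, tf_idx, target_idx, n_bins, params.n_permutations, rng, table
            )
            pvals = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (
                1.0 + params.n_permutations
            )
            adj = _bh_adjust(pvals)
            for j in np.flatnonzero(adj < params.fdr_alpha):
                pair = canonical_pair(tf, expr.gene_ids[target_idx[j]])
                if pair not in seen:
                    seen[pair] = float(obs[j])
        for pair, mi in seen.items():
            pair_hits[pair] = pair_hits.get(pair, 0) + 1
            pair_mis.setdefault(pair, []).append(mi)

    net = SignedNetwork(
        nodes=list(expr.gene_ids),
        edges={},
        params={**params.snapshot(), "seed": int(seed), "stage": "bootstrap_consensus"},
    )
    for pair, hits in sorted(pair_hits.items()):
        frac = hits / params.n_bootstraps
        if frac < params.consensus:
            continue
        a, b = pair
        xa = expr.values[gene_index[a]]
        xb = expr.values[gene_index[b]]
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(xa, xb)[0, 1]
        sign = 1 if (np.isnan(r) or r >= 0) else -1
        net.add_edge(a, b, mi=float(np.median(pair_mis[pair])), sign=sign, consensus=frac)
    return net


def dpi_prune(net: SignedNetwork, tolerance: float = 0.0) -> SignedNetwork:
    """Remove likely-indirect edges via the data-processing inequality.

    For every triangle the weakest edge is marked for removal when its MI is
    strictly below (1 - tolerance) times the smaller of the other two MIs.
    All decisions are evaluated on the original edge set, then applied, so
    the result does not depend on traversal order.  With tolerance 0 an
    exact three-way tie removes nothing (strict inequality).
    """
    if not 0.0 <= tolerance < 1.0:
        raise ValueError("tolerance must be in [0, 1)")
    adj: dict[str, set[str]] = {}
    for a, b in net.edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    to_remove: set[tuple[str, str]] = set()
    for a, b in net.edges:
        common = adj.get(a, set()) & adj.get(b, set())
        for c in common:
            if c <= b:  # each triangle visited once, from its two smallest nodes
                continue
            e_ab = net.edges[canonical_pair(a, b)]
            e_ac = net.edges[canonical_pair(a, c)]
            e_bc = net.edges[canonical_pair(b, c)]
            trio = [(e_ab.mi, canonical_pair(a, b)), (e_ac.mi, canonical_pair(a, c)), (e_bc.mi, canonical_pair(b, c))]
            for mi, pair in trio:
                others = min(m for m, p in trio if p != pair)
                if mi < (1.0 - tolerance) * others:
                    to_remove.add(pair)

    pruned = SignedNetwork(
        nodes=list(net.nodes),
        edges={k: v for k, v in net.edges.items() if k not in to_remove},
        params={**net.params, "dpi_tolerance": tolerance, "stage": "dpi_prune"},
    )
    return pruned


def infer_network(
    expr: ExpressionMatrix,
    tf_list: list[str],
    params: MIParams | None = None,
    seed: int = 0,
) -> SignedNetwork:
    """Full inference stage: bootstrap consensus followed by DPI pruning."""
    params = params or MIParams()
    if not tf_list:
        raise ValueError("tf_list must not be empty")
    net = bootstrap_consensus(expr, tf_list, params, seed)
    pruned = dpi_prune(net, params.dpi_tolerance)
    pruned.params = {**params.snapshot(), "seed": int(seed), "stage": "infer_network"}
    return pruned
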