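"""Weighted co-expression modules, eigengenes and overlap enrichment.

Pairwise Pearson correlations are transformed to a signed adjacency
a_ij = ((1 + cor_ij) / 2)^beta (power 10 by default, the smallest power
reaching a scale-free fit of 0.8 in the source analyses), converted to a
topological-overlap dissimilarity, and clustered by average linkage.
Modules are cut statically at a fixed fraction of the dendrogram height
and merged when their eigengenes are nearly collinear; the module
eigengene is the first principal component of the standardized module
expression, sign-oriented to correlate positively with the module mean.
Module membership kME is a gene's correlation with its own module
eigengene (hubs: kME > 0.7).  Module/gene-set overlap uses the upper
hypergeometric tail with a cross-product odds ratio.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from tfnet.datatypes import (
    CoexpressionModules,
    ExpressionMatrix,
    ModuleEigengenes,
    OverlapResult,
)

__all__ = [
    "regress_covariates",
    "signed_adjacency",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom_dissimilarity",
    "detect_modules",
    "module_eigengenes",
    "module_trait_association",
    "module_overlap",
]

DEFAULT_BETA = 10
HUB_KME = 0.7


def _gene_correlations(expr: ExpressionMatrix) -> pd.DataFrame:
    """Gene x gene Pearson correlations (pairwise-complete); constant genes
    get correlation 0 with a warning."""
    values = expr.values
    if np.isnan(values).any():
        cor = expr.to_frame().T.corr().to_numpy()
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            cor = np.corrcoef(values)
    const = np.flatnonzero(np.isnan(cor).all(axis=1))
    bad = np.isnan(cor)
    if bad.any():
        warnings.warn(
            f"{len(const)} constant gene(s): correlations set to 0"
            if len(const)
            else "undefined correlations set to 0"
        )
        cor[bad] = 0.0
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(np.clip(cor, -1.0, 1.0), index=expr.gene_ids, columns=expr.gene_ids)


def regress_covariates(expr: ExpressionMatrix, covariates: pd.DataFrame) -> ExpressionMatrix:
    """Residualize each gene on per-sample covariates (OLS with intercept).

    Optional pre-step before module detection when technical covariates
    should not drive co-expression.
    """
    cov = covariates.loc[expr.sample_ids].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(cov)), cov])
    if np.isnan(expr.values).any():
        raise ValueError("covariate regression requires a complete matrix")
    beta, *_ = np.linalg.lstsq(design, expr.values.T, rcond=None)
    resid = expr.values - (design @ beta).T
    return ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids),
        values=resid,
        metadata=expr.metadata,
    )


def signed_adjacency(expr: ExpressionMatrix, beta: float = DEFAULT_BETA) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + cor_ij) / 2)^beta, diagonal 1."""
    if expr.n_samples < 4:
        raise ValueError("need at least 4 samples")
    cor = _gene_correlations(expr)
    adj = ((1.0 + cor.to_numpy()) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=cor.index, columns=cor.columns)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity vector.

    Bins k into ``n_bins`` equal-occupancy bins, regresses log10 density on
    log10 mean connectivity, and returns (-sign(slope) * R^2, slope).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return float("nan"), float("nan")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    xs, ys = [], []
    total = len(k)
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        if i < n_bins - 1:
            sel = (k >= lo) & (k < hi)
        else:
            sel = (k >= lo) & (k <= hi)
        width = hi - lo
        if sel.sum() == 0 or width <= 0:
            continue
        density = (sel.sum() / total) / width
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(density))
    if len(xs) < 3:
        return float("nan"), float("nan")
    res = stats.linregress(xs, ys)
    return float(-np.sign(res.slope) * res.rvalue**2), float(res.slope)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    betas: tuple[int, ...] = tuple(range(1, 21)),
    target_r2: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose connectivity distribution fits a scale-free law.

    For each candidate beta the signed fit of log10 p(k) vs log10 k is
    computed over 10 equal-occupancy connectivity bins; the smallest beta
    with fit >= target_r2 is returned together with the full fit table.
    If no beta reaches the target, the argmax is returned with a warning.
    """
    if expr.n_genes < 30:
        raise ValueError("need at least 30 genes to assess scale-free fit")
    cor = _gene_correlations(expr).to_numpy()
    base = (1.0 + cor) / 2.0
    rows = []
    for beta in betas:
        adj = base**beta
        k = adj.sum(axis=1) - 1.0  # exclude self
        fit, slope = scale_free_fit(k)
        rows.append({"beta": beta, "fit": fit, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table.loc[table["fit"] >= target_r2]
    if len(ok):
        chosen = int(ok["beta"].iloc[0])
    else:
        chosen = int(table.loc[table["fit"].idxmax(), "beta"])
        warnings.warn(
            f"no candidate power reached a scale-free fit of {target_r2}; "
            f"returning the best (beta={chosen}, fit={table['fit'].max():.3f})"
        )
    return chosen, table


def tom_dissimilarity(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Topological-overlap dissimilarity 1 - TOM.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with the
    shared-neighbor sum over u != i, j and connectivity k excluding self.
    Diagonal 0; symmetric; entries in [0, 1].
    """
    if isinstance(adjacency, pd.DataFrame):
        names = list(adjacency.index)
        a = adjacency.to_numpy(dtype=float)
    else:
        a = np.asarray(adjacency, dtype=float)
        names = [f"g{i}" for i in range(a.shape[0])]
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    diag = np.diag(a).copy()
    shared = a @ a - diag[:, None] * a - a * diag[None, :]
    k = a.sum(axis=1) - diag
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.clip(np.nan_to_num(tom, nan=0.0), 0.0, 1.0)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    return pd.DataFrame(dissim, index=names, columns=names)


def detect_modules(
    dissim: pd.DataFrame,
    min_module_size: int = 30,
    cut_quantile: float = 0.98,
    merge_threshold: float = 0.25,
    expr: ExpressionMatrix | None = None,
    beta: float = DEFAULT_BETA,
) -> CoexpressionModules:
    """Average-linkage clustering of a TOM dissimilarity into modules.

    The dendrogram is cut statically at ``cut_quantile`` x (maximum merge
    height); clusters below ``min_module_size`` go to module 0
    (unassigned).  When ``expr`` is given, modules whose eigengenes
    correlate above (1 - merge_threshold) are merged iteratively.  Module
    ids are assigned 1, 2, ... by decreasing size, so the labeling is
    invariant (up to the guaranteed renumbering) under gene-order
    permutations.  Deterministic.
    """
    genes = list(dissim.index)
    d = dissim.to_numpy(dtype=float)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    z = linkage(squareform(d, checks=False), method="average")
    heights = z[:, 2]
    cut_height = float(cut_quantile * heights.max())
    raw = fcluster(z, t=cut_height, criterion="distance")

    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_module_size]
    labels[labels.isin(small)] = 0
    if (labels == 0).all():
        warnings.warn("all genes unassigned (every cluster below min_module_size)")

    labels = _renumber(labels)
    if expr is not None and labels.max() > 1:
        labels = _merge_correlated(labels, expr, merge_threshold)
        labels = _renumber(labels)

    return CoexpressionModules(
        labels=labels,
        beta=beta,
        merge_heights=heights,
        cut_height=cut_height,
        params={
            "min_module_size": min_module_size,
            "cut_quantile": cut_quantile,
            "merge_threshold": merge_threshold,
        },
    )


def _renumber(labels: pd.Series) -> pd.Series:
    """Relabel modules 1..m by decreasing size (ties by first member name)."""
    ids = [m for m in labels.unique() if m != 0]
    keyed = sorted(
        ids,
        key=lambda m: (-int((labels == m).sum()), min(labels.index[labels == m])),
    )
    mapping = {m: i + 1 for i, m in enumerate(keyed)}
    mapping[0] = 0
    return labels.map(mapping)


def _merge_correlated(
    labels: pd.Series, expr: ExpressionMatrix, merge_threshold: float
) -> pd.Series:
    labels = labels.copy()
    while True:
        ids = [m for m in sorted(labels.unique()) if m != 0]
        if len(ids) < 2:
            return labels
        eig = module_eigengenes(expr, _as_modules(labels)).eigengenes
        cor = np.corrcoef(eig.to_numpy().T)
        best, pair = -np.inf, None
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if cor[i, j] > best:
                    best, pair = cor[i, j], (ids[i], ids[j])
        if best <= 1.0 - merge_threshold:
            return labels
        keep, drop = pair
        labels[labels == drop] = keep


def _as_modules(labels: pd.Series) -> CoexpressionModules:
    return CoexpressionModules(
        labels=labels, beta=DEFAULT_BETA, merge_heights=np.array([]), cut_height=0.0,
        params={},
    )


def module_eigengenes(
    expr: ExpressionMatrix, modules: CoexpressionModules
) -> ModuleEigengenes:
    """First principal component per module, with per-gene kME and hub flags.

    The eigengene is the leading right singular vector of the standardized
    (per-gene z-scored) module expression, unit-norm over samples and
    sign-oriented to correlate positively with the module's mean
    standardized profile.  kME is each gene's correlation with its own
    module eigengene; genes in module 0 get kME = NaN.
    """
    ids = modules.module_ids
    if not ids:
        raise ValueError("no modules to summarize")
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    eig_cols = {}
    kme = pd.Series(np.nan, index=modules.labels.index, dtype=float)
    for m in ids:
        members = modules.module_genes(m)
        rows = [gene_index[g] for g in members if g in gene_index]
        if not rows:
            raise KeyError(f"module {m} has no genes in the expression matrix")
        x = expr.values[rows]
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        xz = (x - mu) / sd
        _u, _s, vt = np.linalg.svd(xz, full_matrices=False)
        v = vt[0]
        mean_profile = xz.mean(axis=0)
        if np.dot(v, mean_profile) < 0:
            v = -v
        eig_cols[m] = v
        for g, row in zip(members, rows):
            gene = expr.values[row]
            if gene.std() == 0 or v.std() == 0:
                kme[g] = np.nan
            else:
                kme[g] = float(np.corrcoef(gene, v)[0, 1])
    eigengenes = pd.DataFrame(eig_cols, index=expr.sample_ids)
    hub = kme > HUB_KME
    return ModuleEigengenes(eigengenes=eigengenes, kme=kme, hub=hub)


def module_trait_association(
    eigengenes: ModuleEigengenes | pd.DataFrame, trait: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Correlation of every module eigengene with a per-sample trait.

    Returns per module: Pearson r, two-sided p, the display statistic
    -sign(r) * log10(p), Bonferroni-adjusted p across modules, and a
    significance flag at adjusted p < 0.05.
    """
    eig = eigengenes.eigengenes if isinstance(eigengenes, ModuleEigengenes) else eigengenes
    t = np.asarray(trait, dtype=float).ravel()
    if len(t) != len(eig):
        raise ValueError("trait length must equal sample count")
    if np.all(t == t[0]):
        raise ValueError("constant trait: association undefined")
    rows = []
    n_modules = eig.shape[1]
    for m in eig.columns:
        r, p = stats.pearsonr(eig[m].to_numpy(), t)
        p_disp = max(p, 1e-300)
        rows.append(
            {
                "module": m,
                "r": float(r),
                "pvalue": float(p),
                "display_stat": float(-np.sign(r) * np.log10(p_disp)),
                "bonferroni_p": float(min(1.0, p * n_modules)),
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["bonferroni_p"] < 0.05
    return out


def module_overlap(
    setA, setB, universe, n_comparisons: int = 1
) -> OverlapResult:
    """Hypergeometric overlap of two gene sets within a universe.

    p is the upper tail P(X >= |A intersect B|); the odds ratio is the
    cross-product of the 2x2 table, with 0.5 added to every cell only when
    some cell is 0 (Haldane correction).  The Bonferroni-adjusted p uses
    ``n_comparisons`` (e.g. the number of module/set pairs examined).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    sa, sb = set(setA), set(setB)
    if not sa <= universe or not sb <= universe:
        raise ValueError("both gene sets must be subsets of the universe")
    inter = sorted(sa & sb)
    a = len(inter)
    m_tot = len(universe)
    p = float(stats.hypergeom.sf(a - 1, m_tot, len(sa), len(sb)))
    p = min(1.0, max(p, np.finfo(float).tiny))
    b = len(sa) - a
    c = len(sb) - a
    d = m_tot - len(sa) - len(sb) + a
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    odds = (cells[0] * cells[3]) / (cells[1] * cells[2])
    return OverlapResult(
        odds_ratio=float(odds),
        pvalue=p,
        adjusted_pvalue=float(min(1.0, p * n_comparisons)),
        overlap=inter,
        universe_size=m_tot,
        size_a=len(sa),
        size_b=len(sb),
    )
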