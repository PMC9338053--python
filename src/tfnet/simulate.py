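"""Synthetic ground-truth regulatory networks and expression data.

The generator emulates the statistical structure the inference pipeline
assumes: a 3-level pyramid of TFs (top-level "master" regulators, a middle
layer, and bottom-level TFs) driving non-TF effector genes, with
condition/time effects entering at the top-level TFs only, linear-Gaussian
propagation down the hierarchy, and a partially observed, noisy
binding-evidence list standing in for a ChIP compendium.

A linear structural model is used (rather than a sigmoidal one) because
every downstream statistic -- correlation sign, binned MI, differential
expression -- then has closed-form expectations usable as test oracles.
Declared regulatory cycles are generated with a shared latent driver plus
independent noise instead of solving simultaneous equations, which keeps
generation non-iterative and exactly reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from tfnet.datatypes import (
    EvidenceEdgeList,
    ExpressionMatrix,
    GeneSetCollection,
    GroundTruthModel,
)

__all__ = [
    "simulate_network",
    "simulate_expression",
    "simulate_evidence",
    "simulate_de_table",
    "simulate_module_expression",
    "simulate_ppi",
    "simulate_screen_dataset",
]

LEVEL_NAMES = {3: "TOP", 2: "MID", 1: "BOT"}
DEFAULT_CONDITIONS = ("control", "injury")
#: a high-density post-injury time course (days); the emulated datasets are
#: dense time series, and the temporal gradation is what makes direct vs
#: indirect regulation distinguishable
DEFAULT_TIMEPOINTS = (0, 1, 3, 7, 14)
#: injury-induced shift scale on top-level TFs; a package convention
DEFAULT_EFFECT_SIZE = 2.0
DEFAULT_NOISE_SD = 0.25


def simulate_network(
    n_top: int,
    n_mid: int,
    n_bottom: int,
    n_targets: int,
    density: float,
    frac_repressive: float,
    cycle_groups: int = 0,
    seed: int = 0,
    *,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS,
    effect_size: float = DEFAULT_EFFECT_SIZE,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> GroundTruthModel:
    """Draw a ground-truth 3-level TF network with effector targets.

    TF->TF edges connect adjacent levels only (top->mid, mid->bottom); a
    round-robin spanning pass gives every mid TF exactly one top parent and
    every bottom TF exactly one mid parent (and every upper TF at least one
    child), so the designed levels coincide with the vertex-sort strata of
    the true directed graph.  Additional adjacent-level edges appear with
    probability ``density``; each effector target gets exactly one uniform
    TF regulator.  Edge weights have magnitude U(0.5, 0.9) -- regulatory
    influence attenuates down the cascade -- and are negative with
    probability ``frac_repressive``.  Condition effects (additive shifts on
    top-level TFs) are zero for the first (baseline) condition and
    N(0, effect_size^2) otherwise.  Deterministic given ``seed``.
    """
    if min(n_top, n_mid, n_bottom, n_targets) < 1:
        raise ValueError("all node counts must be >= 1")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    if not 0.0 <= frac_repressive <= 1.0:
        raise ValueError("frac_repressive must be in [0, 1]")
    if cycle_groups < 0:
        raise ValueError("cycle_groups must be >= 0")
    if len(conditions) < 1:
        raise ValueError("at least one condition required")

    rng = np.random.default_rng(seed)
    tops = [f"TOP{i + 1}" for i in range(n_top)]
    mids = [f"MID{i + 1}" for i in range(n_mid)]
    bots = [f"BOT{i + 1}" for i in range(n_bottom)]
    tf_levels = {**{t: 3 for t in tops}, **{m: 2 for m in mids}, **{b: 1 for b in bots}}
    targets = [f"G{i + 1:04d}" for i in range(n_targets)]

    def draw_weight() -> float:
        # sub-unit magnitudes: regulatory influence attenuates down the
        # cascade, so each extra hop measurably decorrelates a profile
        mag = rng.uniform(0.5, 0.9)
        neg = rng.random() < frac_repressive
        return -mag if neg else mag

    edges: dict[tuple[str, str], float] = {}

    def add_edge(u: str, v: str) -> None:
        if (u, v) not in edges:
            edges[(u, v)] = draw_weight()

    # spanning pass: hierarchy identifiable by construction.  Round-robin
    # over shuffled nodes gives every mid exactly one top parent and every
    # bottom exactly one mid parent (no spanning collisions: convergent
    # parents sharing an ancestor are what breaks DPI ordering), while
    # every upper node keeps at least one child when the lower level is at
    # least as large.
    shuffled_mids = list(rng.permutation(mids))
    for i, m in enumerate(shuffled_mids):
        add_edge(tops[i % n_top], m)
    shuffled_bots = list(rng.permutation(bots))
    for i, b in enumerate(shuffled_bots):
        add_edge(mids[i % n_mid], b)
    for t in tops:  # degenerate shapes (fewer mids than tops)
        if not any((t, m) in edges for m in mids):
            add_edge(t, shuffled_mids[int(rng.integers(0, n_mid))])
    for m in mids:
        if not any((m, b) in edges for b in bots):
            add_edge(m, shuffled_bots[int(rng.integers(0, n_bottom))])
    # density-driven extra adjacent-level edges
    for u, vs in ((t, mids) for t in tops):
        for v in vs:
            if (u, v) not in edges and rng.random() < density:
                add_edge(u, v)
    for u, vs in ((m, bots) for m in mids):
        for v in vs:
            if (u, v) not in edges and rng.random() < density:
                add_edge(u, v)

    # declared 2-node cycles within a single level, to exercise SCC handling
    cycle_members: dict[int, list[str]] = {}
    if cycle_groups > 0:
        pool: list[list[str]] = []
        for level_nodes in (mids, bots, tops):
            for i in range(0, len(level_nodes) - 1, 2):
                pool.append([level_nodes[i], level_nodes[i + 1]])
        if len(pool) < cycle_groups:
            raise ValueError(
                f"cannot place {cycle_groups} cycle group(s): only {len(pool)} "
                "disjoint same-level pairs available"
            )
        for gid in range(cycle_groups):
            u, v = pool[gid]
            cycle_members[gid] = [u, v]
    # register members before adding equal-level edges (validated in the model)
    in_cycle = {tf for grp in cycle_members.values() for tf in grp}
    for gid, (u, v) in ((g, tuple(m)) for g, m in cycle_members.items()):
        edges[(u, v)] = draw_weight()
        edges[(v, u)] = draw_weight()

    # effector targets: one uniform TF regulator each.  Multi-regulator
    # targets would create co-regulation triangles whose weakest edge is
    # the TF-TF dependence, which the DPI stage removes by construction;
    # single regulators keep edge recovery identifiable.
    all_tfs = tops + mids + bots
    for g in targets:
        add_edge(all_tfs[rng.integers(0, len(all_tfs))], g)

    condition_effects: dict[tuple[str, int], np.ndarray] = {}
    baseline = conditions[0]
    for cond in conditions:
        for tp in timepoints:
            if cond == baseline:
                condition_effects[(cond, int(tp))] = np.zeros(n_top)
            else:
                condition_effects[(cond, int(tp))] = rng.normal(0.0, effect_size, n_top)

    return GroundTruthModel(
        tf_levels=tf_levels,
        edges=edges,
        targets=targets,
        condition_effects=condition_effects,
        noise_sd=float(noise_sd),
        seed=int(seed),
        cycle_members=cycle_members,
    )


def _gene_order(model: GroundTruthModel) -> list[str]:
    tfs = sorted(model.tf_levels, key=lambda t: (-model.tf_levels[t], t))
    return tfs + list(model.targets)


def simulate_expression(
    model: GroundTruthModel,
    n_per_group: int,
    conditions: tuple[str, ...] | None = None,
    timepoints: tuple[int, ...] | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Evaluate the linear structural model over a condition x time design.

    Top-level TF value = condition effect + noise; every downstream gene is
    the weighted sum of its regulators plus noise, evaluated in level order.
    Members of a declared cycle group receive their external (out-of-group)
    parental input plus a shared standard-normal latent driver plus
    independent noise; within-group edge weights are not used numerically.
    Deterministic given ``seed``.
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    known_conditions = {c for c, _ in model.condition_effects}
    known_tps = {tp for _, tp in model.condition_effects}
    if conditions is None:
        conditions = tuple(dict.fromkeys(c for c, _ in model.condition_effects))
    if timepoints is None:
        timepoints = tuple(sorted(known_tps))
    for c in conditions:
        if c not in known_conditions:
            raise ValueError(f"unknown condition label {c!r}")
    for tp in timepoints:
        if int(tp) not in known_tps:
            raise ValueError(f"unknown timepoint {tp!r}")

    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    meta_rows = []
    for cond in conditions:
        for tp in timepoints:
            for rep in range(1, n_per_group + 1):
                sample_ids.append(f"{cond}_t{tp}_r{rep}")
                meta_rows.append({"condition": cond, "timepoint": int(tp), "replicate": rep})
    n = len(sample_ids)
    metadata = pd.DataFrame(meta_rows, index=sample_ids)

    tops = model.top_tfs
    top_index = {t: i for i, t in enumerate(sorted(tops))}
    effect_per_sample = np.zeros((len(tops), n))
    for j, row in enumerate(meta_rows):
        shifts = model.condition_effects[(row["condition"], row["timepoint"])]
        effect_per_sample[:, j] = shifts

    # shared latent drivers for cycle groups, drawn before gene noise
    drivers = {
        gid: rng.standard_normal(n) for gid in sorted(model.cycle_members)
    }
    group_of = {
        tf: gid for gid, members in model.cycle_members.items() for tf in members
    }

    parents: dict[str, list[tuple[str, float]]] = {}
    for (reg, tgt), w in model.edges.items():
        parents.setdefault(tgt, []).append((reg, w))
    for g in parents:
        parents[g].sort()

    order = _gene_order(model)
    values = np.empty((len(order), n))
    row_of = {g: i for i, g in enumerate(order)}
    top_level = max(model.tf_levels.values())
    for g in order:
        eps = rng.normal(0.0, model.noise_sd, n) if model.noise_sd > 0 else np.zeros(n)
        if g in model.tf_levels and model.tf_levels[g] == top_level:
            base = effect_per_sample[top_index[g]].copy()
        else:
            base = np.zeros(n)
            gid = group_of.get(g)
            for reg, w in parents.get(g, []):
                if gid is not None and group_of.get(reg) == gid:
                    continue  # within-cycle edges are represented by the driver
                base += w * values[row_of[reg]]
            if gid is not None:
                base += drivers[gid]
        values[row_of[g]] = base + eps

    return ExpressionMatrix(
        gene_ids=order, sample_ids=sample_ids, values=values, metadata=metadata
    )


def simulate_evidence(
    model: GroundTruthModel, tpr: float, fpr: float, seed: int = 0
) -> EvidenceEdgeList:
    """Noisy binding-evidence list over ordered TF pairs.

    Each true TF->TF edge is reported with probability ``tpr``; each false
    ordered TF pair (including reversals of true edges) with probability
    ``fpr``.  Deterministic given ``seed``.
    """
    if not 0.0 <= tpr <= 1.0 or not 0.0 <= fpr <= 1.0:
        raise ValueError("tpr and fpr must be in [0, 1]")
    rng = np.random.default_rng(seed)
    true_edges = model.tf_tf_edges()
    tfs = sorted(model.tf_levels)
    rows = []
    for u, v in sorted(true_edges):
        if rng.random() < tpr:
            rows.append({"tf": u, "target": v, "source": "chip-sim"})
    for u in tfs:
        for v in tfs:
            if u == v or (u, v) in true_edges:
                continue
            if rng.random() < fpr:
                rows.append({"tf": u, "target": v, "source": "chip-sim"})
    records = pd.DataFrame(rows, columns=["tf", "target", "source"])
    return EvidenceEdgeList(records=records)


def _de_table(expr: ExpressionMatrix, contrast: tuple[str, str]) -> pd.DataFrame:
    cond_a, cond_b = contrast
    meta = expr.metadata
    idx_a = np.flatnonzero((meta["condition"] == cond_a).to_numpy())
    idx_b = np.flatnonzero((meta["condition"] == cond_b).to_numpy())
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"contrast conditions {contrast} not both present")
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each contrast group needs at least 2 replicates")
    a = expr.values[:, idx_a]
    b = expr.values[:, idx_b]
    logfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1)
    pvals = np.asarray(res.pvalue, dtype=float)
    # zero-variance genes: no evidence against the null
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    return pd.DataFrame({"gene": expr.gene_ids, "logFC": logfc, "pvalue": pvals})


def simulate_de_table(
    model: GroundTruthModel, expr: ExpressionMatrix, contrast: tuple[str, str]
) -> pd.DataFrame:
    """Two-sample DE table (gene, logFC, pvalue) for a condition contrast.

    logFC is the mean difference (values are log-scale) of conditionA minus
    conditionB pooled over time points; the p-value is a two-sided pooled-
    variance t-test.  Genes with zero variance in both groups report p = 1.
    """
    del model  # the table is a function of the expression data alone
    return _de_table(expr, contrast)


def simulate_module_expression(
    module_sizes: tuple[int, ...] = (50, 40, 35),
    within_r: float = 0.7,
    n_noise_genes: int = 60,
    n_per_group: int = 40,
    seed: int = 0,
    trait_effects: dict[int, float] | None = None,
) -> tuple[ExpressionMatrix, pd.Series, pd.Series]:
    """Planted co-expression modules for the WGCNA-stage tests.

    Module m's genes are ``sqrt(r) * latent_m + sqrt(1-r) * noise`` so every
    within-module pair has expected correlation ``within_r``; noise genes
    are iid standard normal.  ``trait_effects[m]`` adds an additive genotype
    shift (condition "ko" vs "wt") to module m's latent, making it
    trait-associated.  Returns (expression, gene->module labels with 0 for
    noise genes, per-sample 0/1 trait).
    """
    if not 0.0 < within_r < 1.0:
        raise ValueError("within_r must be in (0, 1)")
    rng = np.random.default_rng(seed)
    trait_effects = trait_effects or {}
    conditions = ("wt", "ko")
    sample_ids, meta_rows, trait_vals = [], [], []
    for cond in conditions:
        for rep in range(1, n_per_group + 1):
            sample_ids.append(f"{cond}_r{rep}")
            meta_rows.append({"condition": cond, "timepoint": 1, "replicate": rep})
            trait_vals.append(1.0 if cond == "ko" else 0.0)
    n = len(sample_ids)
    trait = pd.Series(trait_vals, index=sample_ids, name="genotype")

    genes, labels, rows = [], [], []
    for m, size in enumerate(module_sizes, start=1):
        latent = rng.standard_normal(n) + trait_effects.get(m, 0.0) * trait.to_numpy()
        for i in range(size):
            g = f"M{m}_{i + 1:03d}"
            genes.append(g)
            labels.append(m)
            rows.append(
                np.sqrt(within_r) * latent
                + np.sqrt(1.0 - within_r) * rng.standard_normal(n)
            )
    for i in range(n_noise_genes):
        g = f"NOISE_{i + 1:03d}"
        genes.append(g)
        labels.append(0)
        rows.append(rng.standard_normal(n))

    expr = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=sample_ids,
        values=np.vstack(rows),
        metadata=pd.DataFrame(meta_rows, index=sample_ids),
    )
    return expr, pd.Series(labels, index=genes, name="module"), trait


def simulate_ppi(
    genes: list[str],
    module_genes: list[str] | None = None,
    p_within: float = 0.6,
    p_background: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic PPI edge list: ER background plus a dense module core."""
    rng = np.random.default_rng(seed)
    module = set(module_genes or [])
    rows = []
    genes = list(genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            p = p_within if (a in module and b in module) else p_background
            if rng.random() < p:
                rows.append((a, b) if a <= b else (b, a))
    return pd.DataFrame(sorted(set(rows)), columns=["a", "b"])


def simulate_screen_dataset(
    n_null_genes: int = 1900,
    n_target_genes: int = 40,
    n_decoys: int = 100,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    n_per_group: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, GeneSetCollection, str]:
    """DE table + gene-set collection with one planted repressor-target set.

    The planted set's genes are shifted down by ``effect`` under treatment
    (a repressor active in the treated state); all other genes are null.
    The collection holds the planted set plus ``n_decoys`` random decoy sets
    of matched size.  Returns (de_table, collection, planted_set_name).
    """
    rng = np.random.default_rng(seed)
    genes = [f"T{i + 1:04d}" for i in range(n_target_genes)] + [
        f"N{i + 1:04d}" for i in range(n_null_genes)
    ]
    n_genes = len(genes)
    n = 2 * n_per_group
    values = rng.normal(0.0, noise_sd, (n_genes, n))
    values[:n_target_genes, n_per_group:] -= effect  # treated columns
    sample_ids = [f"ctl_r{i + 1}" for i in range(n_per_group)] + [
        f"trt_r{i + 1}" for i in range(n_per_group)
    ]
    meta = pd.DataFrame(
        {
            "condition": ["control"] * n_per_group + ["treated"] * n_per_group,
            "timepoint": 1,
            "replicate": list(range(1, n_per_group + 1)) * 2,
        },
        index=sample_ids,
    )
    expr = ExpressionMatrix(genes, sample_ids, values, meta)
    de = _de_table(expr, ("treated", "control"))

    planted_name = "PLANTED_REPRESSOR_TARGETS"
    sets: dict[str, tuple[str, list[str]]] = {
        planted_name: ("targets of the planted repressor", genes[:n_target_genes])
    }
    for d in range(n_decoys):
        members = rng.choice(genes, size=n_target_genes, replace=False)
        sets[f"DECOY_{d + 1:03d}"] = ("random decoy set", sorted(members))
    return de, GeneSetCollection(sets=sets), planted_name
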