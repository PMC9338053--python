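"""End-to-end recovery studies on synthetic data with known ground truth.

Each study wires the full pipeline over the generator's study conditions
and measures recovery against the hidden model: edge F1 and sign accuracy
for the MI stage, stratum accuracy for the hierarchy stage, module ARI and
trait/overlap statistics for the co-expression stage, and the rank of a
planted repressor in the TF screen.  The analysis drivers, the test suite
and the acceptance script all run these same functions.

Study conditions
----------------
Edge recovery uses a (2, 3, 4) TF pyramid with 200 effector targets at
TF-TF density 0.3, 200 samples (2 conditions x 5 time points x 20
replicates) and observation noise 0.25.  Hierarchy recovery uses a sparser
(3, 4, 5) pyramid (density 0.1, 150 targets): leaf-removal stratification
presumes a predominantly tree-like regulatory pyramid, and convergent
multi-parent wiring is exactly the regime where the data-processing
inequality misattributes chain edges.  Module recovery plants three
modules (50/40/35 genes, within-correlation 0.7) plus 60 unassigned noise
genes over 80 samples.
"""

from __future__ import annotations

import numpy as np

from tfnet.coexpress import (
    detect_modules,
    module_eigengenes,
    module_overlap,
    module_trait_association,
    signed_adjacency,
    tom_dissimilarity,
)
from tfnet.datatypes import GroundTruthModel, MIParams, SignedNetwork
from tfnet.hierarchy import orient_edges, vertex_sort
from tfnet.mi import infer_network
from tfnet.screen import rank_genes, screen_collection
from tfnet.simulate import (
    simulate_evidence,
    simulate_expression,
    simulate_module_expression,
    simulate_network,
    simulate_screen_dataset,
)

__all__ = [
    "EDGE_STUDY",
    "HIERARCHY_STUDY",
    "edge_recovery",
    "hierarchy_recovery",
    "module_recovery",
    "repressor_screen",
]

EDGE_STUDY = dict(
    n_top=2, n_mid=3, n_bottom=4, n_targets=200, density=0.3, frac_repressive=0.3
)
HIERARCHY_STUDY = dict(
    n_top=3, n_mid=4, n_bottom=5, n_targets=150, density=0.1, frac_repressive=0.3
)
N_PER_GROUP = 20  # x 2 conditions x 5 time points = 200 samples


def _study_network(seed: int, study: dict, n_per_group: int, params: MIParams | None):
    model = simulate_network(cycle_groups=0, seed=seed, **study)
    expr = simulate_expression(model, n_per_group, seed=100 + seed)
    net = infer_network(expr, model.tfs, params or MIParams(), seed=10 + seed)
    return model, expr, net


def _edge_metrics(model: GroundTruthModel, net: SignedNetwork) -> dict:
    truth = model.undirected_true_pairs()
    pred = set(net.edges)
    tp = len(truth & pred)
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(truth)
    f1 = 2 * precision * recall / (precision + recall) if tp else 0.0
    correct = total = 0
    for pair in truth & pred:
        w = model.edges.get(pair, model.edges.get((pair[1], pair[0])))
        total += 1
        correct += int(np.sign(w) == net.edges[pair].sign)
    return {
        "f1": f1,
        "precision": precision,
        "recall": recall,
        "sign_accuracy": correct / total if total else float("nan"),
        "n_true_edges": len(truth),
        "n_predicted_edges": len(pred),
    }


def edge_recovery(
    seed: int,
    n_per_group: int = N_PER_GROUP,
    params: MIParams | None = None,
) -> dict:
    """Infer the network for one seed and score edges against ground truth."""
    model, _expr, net = _study_network(seed, EDGE_STUDY, n_per_group, params)
    return {**_edge_metrics(model, net), "model": model, "network": net}


def hierarchy_recovery(
    seed: int,
    n_per_group: int = N_PER_GROUP,
    params: MIParams | None = None,
) -> dict:
    """Full pipeline through vertex-sort with perfect binding evidence."""
    model, _expr, net = _study_network(seed, HIERARCHY_STUDY, n_per_group, params)
    evidence = simulate_evidence(model, tpr=1.0, fpr=0.0, seed=200 + seed)
    layered = vertex_sort(orient_edges(net, evidence))
    correct = sum(
        layered.stratum(tf) == model.true_stratum(tf) for tf in model.tfs
    )
    return {
        "stratum_accuracy": correct / len(model.tfs),
        "n_tfs": len(model.tfs),
        "n_correct": correct,
        "layered": layered,
        "model": model,
    }


def module_recovery(seed: int, trait_effect: float = 2.0) -> dict:
    """Detect planted modules; score ARI, trait association and RAG overlap.

    The planted regeneration-associated gene (RAG) reference set is 30
    genes of the trait-carrying module plus 10 background genes, so a
    correct detection overlaps it with an odds ratio well above 1.
    """
    expr, labels, trait = simulate_module_expression(
        seed=seed, trait_effects={1: trait_effect}
    )
    dissim = tom_dissimilarity(signed_adjacency(expr, beta=10))
    modules = detect_modules(dissim, min_module_size=30, expr=expr)

    from sklearn.metrics import adjusted_rand_score

    planted = labels[labels != 0]
    ari = float(
        adjusted_rand_score(planted.values, modules.labels[planted.index].values)
    )

    eigengenes = module_eigengenes(expr, modules)
    assoc = module_trait_association(eigengenes, trait)

    # detected module carrying the planted trait-associated genes
    m1_genes = set(labels.index[labels == 1])
    detected = max(
        modules.module_ids,
        key=lambda m: len(m1_genes & set(modules.module_genes(m))),
        default=None,
    )
    rag_set = sorted(m1_genes)[:30] + sorted(labels.index[labels == 0])[:10]
    overlap = module_overlap(
        modules.module_genes(detected), rag_set, list(labels.index)
    )
    trait_p = float(
        assoc.set_index("module").loc[detected, "bonferroni_p"]
    )
    return {
        "ari": ari,
        "trait_module": detected,
        "trait_bonferroni_p": trait_p,
        "overlap_odds_ratio": overlap.odds_ratio,
        "overlap_p": overlap.pvalue,
        "association": assoc,
        "modules": modules,
    }


def repressor_screen(seed: int, n_perm: int = 200) -> dict:
    """Screen the planted repressor-target set against 100 decoys."""
    de, collection, planted = simulate_screen_dataset(seed=seed)
    ranked = rank_genes(de)
    result = screen_collection(ranked, collection, n_perm=n_perm, seed=seed)
    ordered = result.ranked(ascending=True)
    rank = int(ordered.index[ordered["set"] == planted][0]) + 1
    row = ordered.loc[ordered["set"] == planted].iloc[0]
    return {
        "rank": rank,
        "nes": float(row["nes"]),
        "es": float(row["es"]),
        "pvalue": float(row["pvalue"]),
        "table": ordered,
    }
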