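# tfnet

Hierarchical transcription-factor regulatory network inference from
expression data, with downstream screens for upstream repressors of a
phenotype-associated gene program.

## The problem

Coordinated gene programs — such as the regeneration-associated gene
(RAG) program that peripheral neurons activate after axonal injury — are
driven by tiers of transcription factors (TFs): a few master regulators
at the top driving mid- and bottom-level TFs that in turn control
effector genes. Identifying which TF sits *upstream* in that pyramid,
and whether it activates or represses the program, is the question this
package addresses for computational biologists working from expression
time courses, binding evidence, and gene-set resources.

`tfnet` implements the full analysis chain as a tested library:

1. **Signed MI network inference.** Pairwise mutual information
   MI(X, Y) = Σ p(i,j) ln[p(i,j)/(p(i)p(j))] on equal-frequency-binned
   profiles; permutation significance (add-one p, BH FDR < 0.05 per
   regulator), bootstrap consensus (≥ 95% of 100 bootstraps), edge signs
   from Pearson correlation, and indirect-edge removal via the
   data-processing inequality: in every triangle the weakest edge is
   dropped when MI_weak < (1 − ε)·min(other two).
2. **Evidence orientation + vertex-sort.** Edges become directed only
   where physical TF→target binding evidence supports the orientation;
   strongly connected components are condensed, and iterative leaf
   removal on the condensation DAG and its transpose assigns each TF a
   level interval [L↑, D+1−L↓] and a TOP / MIDDLE / BOTTOM stratum.
3. **Network statistics.** Clustering coefficients (local and
   transitivity), directed betweenness, in/out-degree, a 13-class census
   of connected 3-node motifs with degree-preserving-null z-scores, and
   signed regulon similarity across networks.
4. **TF-regulator screen.** Genes ranked by the directional p-value
   −sign(logFC)·log10(p); each TF-target set scored by the GSEA running
   sum (ES, NES, gene-set-permutation p, BH FDR). Negative ES flags a
   candidate repressor of the program.
5. **Co-expression modules.** Signed adjacency ((1+r)/2)^β (β = 10),
   topological-overlap dissimilarity, average-linkage clustering with a
   static height cut, module eigengenes (first PC) and kME hubs,
   eigengene–trait association with Bonferroni control, and
   hypergeometric module overlap with odds ratios.
6. **PPI overlay.** Induced-subgraph connectivity scored against a
   degree-binned within-node permutation null.

A first-class synthetic-data module generates layered ground-truth
networks, expression time courses, noisy binding evidence, DE tables,
planted co-expression modules and PPI backgrounds, so every stage is
validated end-to-end against known truth — no downloads involved.

## Worked example

```python
from tfnet import (
    simulate_network, simulate_expression, simulate_evidence,
    infer_network, orient_edges, vertex_sort,
)

model = simulate_network(n_top=3, n_mid=4, n_bottom=5, n_targets=150,
                         density=0.1, frac_repressive=0.3, seed=1)
expr = simulate_expression(model, n_per_group=20, seed=101)   # 200 samples
net = infer_network(expr, model.tfs, seed=11)                 # signed MI network
evidence = simulate_evidence(model, tpr=1.0, fpr=0.0, seed=201)
layered = vertex_sort(orient_edges(net, evidence))
print(len(net.edges), layered.stratum("TOP1"), layered.stratum("MID1"),
      layered.stratum("BOT1"))
```

prints `167 TOP MIDDLE BOTTOM`: 167 edges recovered (161 true edges in
the hidden model), with a master regulator, a mid-level and a bottom-level
TF each placed in its true stratum. Scored against the hidden models
(`analysis/02_infer_networks.py`, `analysis/03_sort_hierarchy.py`), seeds
1–5 give edge F1 0.941–0.988 with sign accuracy 1.0 on the dense
edge-recovery study, and 56/60 TFs (93.3%) in their true stratum on the
sparser hierarchy study.

The screen driver (`analysis/05_screen_regulators.py`) plants a repressor
whose 40 targets are suppressed under treatment and screens its target
set against 100 decoys:

```
Planted repressor set: rank 1 of 101, ES=-0.998, NES=-2.76, p=0.000999
```

i.e. the planted repressor's target set is maximally enriched at the
bottom of the treatment ranking (ES ≈ −1) and is the screen's top
candidate negative regulator. The co-expression driver recovers the three
planted modules perfectly (ARI = 1.0), flags the genotype-driven module at
Bonferroni p = 4.8e-15, and finds its overlap with the planted RAG set at
OR = 13.1 (p = 9.4e-11).

Each numbered script under `analysis/` is a thin driver over the library
that prints what it found and writes its table under `results/`. A `tfnet`
command-line interface exposes the same stages
(`tfnet simulate | infer-net | orient | vertex-sort | net-stats | motifs |
tf-screen | coexpress | module-overlap | ppi-sig`); every stochastic
subcommand requires an explicit `--seed` and each run writes a provenance
JSON.

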