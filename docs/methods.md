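# Methods

`tfnet` reconstructs hierarchical transcription-factor (TF) regulatory
networks from expression data and screens for upstream regulators of a
phenotype-associated gene program. This note documents the models and
procedures each stage implements, the parameters that matter, the
synthetic data the pipeline is validated on, and the numerical choices
made where the design was genuinely open.

## 1. Signed MI network inference

### Mutual information estimator

Dependence between two expression profiles is measured as the mutual
information (MI) of their equal-frequency-binned joint distribution,

    MI(X, Y) = sum_ij p(i, j) ln [ p(i, j) / (p(i) p(j)) ]   (nats),

with `n_bins = max(3, floor(sqrt(n)))` by default. Profiles are reduced to
bin labels by ordinal ranking (ties broken by sample position), so every
marginal is uniform up to integer rounding. Binned MI admits an exact
brute-force oracle (an explicit contingency table), which is why it was
chosen over kernel or adaptive-partitioning estimators. Two consequences
are worth knowing:

- MI saturates at `ln(n_bins)` for any strictly monotone relationship;
  the estimator resolves *degrees* of dependence only below saturation.
- The null expectation of binned MI is positive, roughly
  `(n_bins - 1)^2 / (2n)` nats; raw MI values are therefore only
  interpreted relative to permutation nulls, never against zero.

A constant profile carries no measurable dependence and returns MI = 0
with a warning. Missing entries are removed pairwise (both here and for
the correlation that signs an edge). The implementation sums the
`c ln c` terms of the contingency table in sorted order, which makes
`MI(x, y)` and `MI(y, x)` bitwise identical.

### Permutation significance, bootstrap consensus, edge sign

For each candidate regulator the null is built by permuting the TF profile
`n_permutations` times (default 100) and recomputing MI against every
other gene; the p-value uses the add-one estimator
`p = (1 + #{null >= obs}) / (1 + n_permutations)`, so the smallest
attainable p is 1/101 at the default. Benjamini–Hochberg FDR is applied
across targets *within each regulator's scan* (regulon-centric, matching
how regulator-centered inference is normally run); targets with adjusted
p < 0.05 are retained.

Stability filtering resamples the samples with replacement
`n_bootstraps = 100` times and keeps an edge only if it is retained — from
either endpoint's scan — in at least 95% of bootstraps (`consensus =
0.95`). The edge MI is the median over retaining bootstraps, which
suppresses most of the resampling noise in the MI estimate; the edge sign
(predicted mode of action: activation vs repression) is the sign of the
full-data Pearson correlation.

### DPI pruning

The data-processing inequality states that for a regulatory chain
X → Y → Z, `MI(X, Z) <= min(MI(X, Y), MI(Y, Z))`. For every triangle in
the consensus network the weakest edge is marked for removal when its MI
is strictly below `(1 - eps) * min(other two)` (default `eps = 0`); all
decisions are evaluated on the frozen input edge set and then applied, so
traversal order cannot affect the result, and an exact three-way tie
removes nothing. Two caveats are inherent to DPI and documented rather
than patched:

- at exactly zero observation noise a monotone chain gives *equal*
  (saturated) MI on all three edges, the tie contract keeps all of them,
  and the indirect edge survives; any non-zero noise breaks the tie in
  the right direction;
- in a co-regulation triangle (two TFs driving one target) the TF–TF
  dependence is often genuinely the weakest edge, so DPI removes a true
  edge; and for convergent multi-parent wiring whose parents share an
  ancestor, the grandparent–child dependence can genuinely exceed the
  parent–child one. These are failure modes of the method itself, and
  the synthetic study conditions (below) are designed so that the
  assumptions the method needs actually hold.

### Performance

The permutation scan is the hot loop: every (bootstrap, regulator,
permutation, target) cell needs a joint-histogram statistic. Since
equal-frequency marginals are fixed, only `sum c ln c` of the joint table
varies; a numba kernel accumulates the counts into a reused
`n_bins^2` buffer and looks `c ln c` up in a precomputed table (a pure
numpy `bincount` fallback produces identical values). A full inference
run at 209 genes x 200 samples with default parameters takes well under a
minute on one CPU.

## 2. Evidence orientation and vertex-sort stratification

MI edges are undirected. An edge {a, b} becomes directed a → b only when
a physical binding record (TF, target) = (a, b) exists; both directions
give a reciprocal pair, and pairs without any evidence are kept as
undirected residuals. Residuals are excluded from hierarchy sorting —
symmetrizing them would fabricate cycles unsupported by evidence — but
remain in undirected statistics.

The directed network is condensed by strongly connected components
(cyclic regulation collapses into supernodes), then stratified by
iterative leaf removal. On the condensation DAG, removing out-degree-0
nodes repeatedly yields each node's level-from-bottom L↑ (sinks = 1);
the same procedure on the transpose yields L↓. With D the maximum level,
a node's level interval is `[L↑, D + 1 - L↓]`, and strata are assigned
as TOP if lo = hi = D, BOTTOM if lo = hi = 1, MIDDLE otherwise
(interval-straddling nodes are MIDDLE). Self-loops are ignored in all
degree counts, so a TF that only regulates itself is bottom-level. The
interval-combination rule and three-stratum labeling are this package's
concretization of leaf-removal sorting; the underlying algorithm assigns
levels without attaching probabilities to them. When the condensation has
depth 1 (a single cycle and nothing else) every node is simultaneously
top- and bottom-level; such networks have no hierarchy reading and all
nodes are labeled MIDDLE, which also keeps the exact symmetry
"reversing every edge swaps TOP and BOTTOM".

## 3. Network statistics

- Clustering: local coefficient = triangles through v / C(k_v, 2)
  (0 when k_v < 2) on the undirected projection; the global coefficient is
  the transitivity, 3 x triangles / connected triples (the mean local
  coefficient is reported alongside).
- Centrality: betweenness on directed unweighted shortest paths,
  normalized by (n-1)(n-2); degrees exclude self-loops.
- Motifs: an exhaustive triad census classifies every connected 3-node
  induced subgraph into the 13 directed isomorphism classes (self-loops
  ignored); z-scores come from 1000 degree-preserving double-edge-swap
  randomizations (10|E| swap attempts each; a swap is rejected if it would
  create a self-loop or duplicate arc). A null sd of 0 reports the
  z-score as undefined rather than infinite. The choice of
  swap-randomization (vs stub-matching) nulls is a package decision.
- Regulon similarity across two networks is the Pearson correlation of a
  TF's signed-MI weight vectors over the union of its partners, absent
  partners filled with 0 — capturing both shared membership and agreement
  in mode of action. It is undefined (NaN) when either regulon is empty.
  The metric itself is a package choice; no standard statistic exists.

## 4. TF-regulator screen (GSEA-style)

Genes are ranked by the directional p-value
`-sign(logFC) * log10(p)` (up-regulated and significant at the head,
down-regulated and significant at the tail). A p-value of exactly 0 is
refused with instructions to apply an explicit floor — silent clamping
would hide an upstream problem.

The enrichment score of a TF-target set walks down the ranked list,
adding `|stat|^w / N_R` at each set member (`N_R` normalizes the hit
increments to total 1; `w = 1` by default, `w = 0` available for exact
hand checks) and subtracting `1/(N - N_hits)` otherwise; ES is the signed
extremum of the running sum. Leading-edge genes are the members at or
before the peak (ES >= 0) or at or after the trough (ES < 0).

Because the screen starts from a fixed ranked list, sample-label
permutation is impossible; the null is gene-set resampling (random sets
of matched size). The permutation p is the two-sided add-one tail on
|ES| against all `n_perm` nulls — this keeps null p-values uniform, which
sign-conditional tails do not, while the direction of regulation is
carried by ES and NES. NES divides ES by the mean |null ES| of matching
sign. BH FDR is computed across tested sets; sets smaller than
`min_size` after intersection are dropped, sets with an empty
intersection are kept as untestable rows excluded from FDR.

## 5. Co-expression modules

Pairwise Pearson correlations are transformed to a signed adjacency
`a_ij = ((1 + cor_ij)/2)^beta` with `beta = 10` by default; the helper
`pick_soft_threshold` returns the smallest power whose connectivity
distribution reaches a signed scale-free fit of 0.8 (log-density vs
log-connectivity regression over 10 equal-occupancy bins; if no power
reaches the target, the argmax is returned with a warning and the full
fit table is always emitted). The topological overlap
`TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`
smooths the adjacency by shared neighborhoods; `1 - TOM` is the
clustering dissimilarity.

Modules come from average-linkage hierarchical clustering with a *static*
cut at `cut_quantile x (maximum merge height)` (default 0.98), clusters
below `min_module_size = 30` going to module 0 (unassigned), followed by
iterative merging of modules whose eigengenes correlate above
`1 - merge_threshold` (default 0.75). The static fraction-of-max cut
replaces the dynamic hybrid tree cut: the dynamic algorithm's parameters
are numerous and its output has no exactly testable contract, whereas the
static cut is deterministic and its behavior on planted-block fixtures
can be verified by hand. This is a deliberate simplification; very
unevenly sized or nested modules that dynamic cutting resolves may merge
or drop out here. Module ids are assigned by decreasing size, making
labels invariant (up to renaming) under gene-order permutations.

The module eigengene is the first principal component of the per-gene
standardized module expression, unit-norm over samples and sign-oriented
to correlate positively with the module's mean profile (PCA's sign
ambiguity must be pinned for trait associations to have a direction).
kME is each gene's correlation with its own module eigengene; hubs are
kME > 0.7. Module–trait association reports the eigengene–trait Pearson
r, its two-sided p, the display statistic `-sign(r) * log10(p)`, and
Bonferroni-adjusted p across modules (significant below 0.05); a plain
correlation test is used, with optional per-gene OLS residualization of
covariates (`regress_covariates`) as a pre-step. Module overlap uses the
upper hypergeometric tail P(X >= overlap) and the cross-product odds
ratio of the 2x2 table, adding 0.5 to every cell only when some cell is
zero; the universe is the full set of expression-filtered genes.

## 6. PPI connectivity significance

A module projected onto a protein-interaction background is scored by its
induced edge count. The null replaces each module gene with a uniformly
chosen non-module protein from the same log2-spaced degree bin
(1, 2, 3–4, 5–8, ...); genes sharing a candidate pool receive distinct
replacements, like the observed module, and a bin with no candidates is
widened stepwise with a warning. p is the add-one upper tail over
`n_perm` draws (default 1000). Per-node hub p-values are computed
analogously from within-module degrees. Only direct induced edges are
scored; indirect (common-neighbor) connectivity is a possible extension.
The interaction background is supplied by the user; the synthetic
generator can emit one for testing.

## 7. Synthetic data: what it emulates and what it does not

The generator draws a 3-level TF pyramid — top-level "master" regulators,
a middle layer, bottom-level TFs — plus non-TF effector targets, and
propagates condition/time effects through a linear-Gaussian structural
model evaluated in topological order: top TF = condition effect + noise,
every downstream gene = sum(weight x regulator) + noise. The linear
model was chosen over a sigmoidal one because correlation signs, MI
orderings and differential expression then have closed-form expectations
usable as test oracles. Key structural choices:

- **Adjacent-level TF edges with a round-robin spanning pass.** Each mid
  TF gets exactly one top parent and each bottom TF one mid parent, plus
  extra adjacent-level edges with probability `density`. The spanning
  pass avoids convergent parents that share an ancestor, the regime where
  the data-processing inequality genuinely misorders chain edges; the
  density parameter controls how much convergence re-enters.
- **One regulator per effector target.** Multi-regulator targets create
  co-regulation triangles whose weakest edge is usually the true TF–TF
  dependence, which DPI then removes by construction.
- **Attenuating weights** (magnitude U(0.5, 0.9), negative with
  probability `frac_repressive`): influence weakens down the cascade, so
  each extra regulatory hop measurably decorrelates a profile. Master
  regulators showing the largest responses and downstream effectors
  progressively damped ones is also the pattern seen in injury
  time-course data.
- **Condition effects enter only at top-level TFs** (zero for the
  baseline condition, N(0, effect_size^2) per condition x time point
  otherwise; effect_size = 2.0, noise_sd = 0.25 are package conventions),
  making hierarchy recovery identifiable by design. The default design is
  a dense post-injury time course (control/injury x days 0, 1, 3, 7, 14):
  the temporal gradation of the top-TF profiles is what gives MI the
  resolution to order direct vs indirect dependencies.
- **Declared cycles** are generated by a shared latent driver plus
  independent per-member noise rather than solving simultaneous
  equations, keeping generation non-iterative and bit-reproducible;
  within-cycle edge weights are structural annotations, not numeric
  inputs.
- The binding-evidence generator reports each true TF→TF edge with
  probability `tpr` and each false ordered TF pair with probability
  `fpr`. The DE-table generator is a pooled-variance two-sample t-test
  on the (log-scale) expression with the mean difference as logFC;
  zero-variance genes report p = 1.

Not emulated: count-level noise (negative binomial), library-size or
batch artifacts, nonlinear or combinatorial regulation, feedback from
targets to TFs, and identifier-mapping issues across platforms. Passing
the recovery tests therefore shows the pipeline's stages are correct and
well-calibrated under the model's assumptions — not that real tissue
data meets those assumptions.

### Study conditions used by the drivers, tests and acceptance script

- *Edge recovery*: (2, 3, 4) pyramid, 200 targets, TF-TF density 0.3,
  noise 0.25, 200 samples (2 conditions x 5 time points x 20
  replicates); expected edge F1 >= 0.8 and sign accuracy >= 0.9
  (observed ~0.94–0.99 and 1.0 across seeds).
- *Hierarchy recovery*: (3, 4, 5) pyramid, 150 targets, density 0.1,
  perfect evidence (tpr = 1, fpr = 0); >= 90% of TFs in their true
  stratum pooled over seeds. The sparser, more tree-like pyramid is the
  regime in which leaf-removal stratification is meaningful; dense
  convergent wiring degrades TF–TF edge recovery through the DPI caveats
  above.
- *Module recovery*: planted modules of 50/40/35 genes at
  within-correlation 0.7 plus 60 noise genes, 80 samples (40 per
  genotype); ARI >= 0.9 over planted genes, planted trait module
  Bonferroni-significant with RAG-set overlap OR > 1.
- *Repressor screen*: 40 planted targets suppressed by 2 (sd 0.5) under
  treatment among 1900 null genes, 5 replicates per arm, screened against
  100 size-matched decoys; the planted set should rank first with
  NES < 0.
- The acceptance script runs 3 replicates per stage with seeds derived
  from `--seed`; the test suite uses seeds 1–5.

## 8. Numerical choices and degenerate inputs

- All p-value estimators are add-one (never exactly 0); BH via
  `scipy.stats.false_discovery_control`.
- MI is clamped at 0 against floating-point underrun; symmetry is exact
  by sorted summation.
- Readers reject malformed input (duplicate ids, non-numeric cells,
  metadata mismatches) rather than coercing; genes missing in more than
  half the samples are dropped at load with a logged count.
- Edges with correlation exactly 0 sign as +1; an undefined correlation
  (constant gene) also signs +1 after a warning.
- `GraphML` round-trips networks losslessly including attributes and
  residual edges; `SIF` encodes signs as `activates`/`represses` and
  residuals as `undirected`.
- Gene symbols are case-sensitive and whitespace-stripped; no alias
  resolution is attempted.

## 9. Known limitations

- Per-regulator (not network-wide) FDR means the global false-edge rate
  grows with the number of regulators scanned.
- DPI removes one edge of every genuine co-regulation triangle and can
  misorder convergent multi-parent chains (see §1); both are properties
  of the method, visible in the synthetic studies when density rises.
- The static dendrogram cut can split or merge modules that dynamic
  tree-cutting would resolve.
- The vertex-sort hierarchy is purely topological; it attaches no
  uncertainty to a node's stratum.
- Betweenness and motif censuses are exact but not optimized for
  networks beyond a few thousand nodes; gene counts beyond ~20k are out
  of contract for the co-expression stage.
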