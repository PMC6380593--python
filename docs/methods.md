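# Methods

## Problem setting

Gene-expression classifiers of cancer survival generalize poorly across
cohorts, and network-based outcome predictors (NOPs) — which aggregate
genes into meta-genes along the edges of a gene network before
classification — have shown inconsistent benefits, with shuffled networks
sometimes performing as well as curated ones. This package turns the
question around: instead of assuming a biological network helps, it infers
from the labelled expression data itself the network of gene pairs whose
*combination* predicts outcome better than either gene alone, and then
asks whether that network improves prediction under a validation scheme
that mimics deployment on an unseen cohort.

## Pair scoring

Outcome is overall survival (or recurrence-free survival when available)
dichotomized at 5 years: *poor* if the event occurred before 5 years,
*good* if follow-up reached 5 years, *excluded* if censored earlier
(the class is unknowable; these samples take no part in training or
evaluation). Expression is quantile-normalized within each study; batch
correction beyond that is a pluggable hook, and the synthetic generator
emits data that is already correction-equivalent.

For genes *i*, *j* the scan computes, under leave-one-study-out
cross-validation with 5 repeats of a 70% with-replacement subsample of the
training studies:

- `A_i`, `A_j` — median holdout AUC of each gene alone ("higher expression
  ⇒ poor" oriented by the sign of the training regression slope; the AUC
  is *not* folded upward around 0.5, which would be optimistically biased
  on test data);
- `A_ij` — median holdout AUC of the pair meta-gene, an ordinary least
  squares combination of the two z-scored genes fitted on the training
  subsample (OLS and logistic regression rank identically for two
  features, and OLS is closed-form at ~10⁷–10⁸ fits);
- synergy `S = A_ij / max(A_i, A_j)` (> 1 iff the pair beats its best
  member);
- `M = (A_i + A_j) / 2` and `C` = absolute Spearman correlation on the
  full training partition (computed once per fold — cheaper and
  lower-variance than per subsample).

Each measure is min–max normalized to [0, 1] over the scored pair
collection and combined into the fitness

```
F = -sqrt((1 - S̄)² + (1 - M̄)² + (1 - C̄)²) ∈ [-√3, 0],
```

the negative Euclidean distance to the ideal point (1, 1, 1). The network
("SyNet") is the top-*n* pairs by fitness (50,000 at transcriptome scale;
proportionally fewer at simulation scale). Because `F ≤ 0` while group
construction needs positive neighbor-priority weights, edges carry the
rank score (rank from worst to best)/n ∈ (0, 1], which preserves fitness
order. Where several fold-wise fitness tables exist, each fold is
normalized within itself first and the per-pair median F is ranked
(normalize-then-median).

### Determinism and chunking

The subsample drawn for a given (seed, fold, repeat) comes from a
counter-based RNG keyed only by those three integers, so every gene and
pair sees identical samples no matter how the 69-million-pair enumeration
is chunked across workers; concatenated chunks are bit-identical to a
single scan. Pair enumeration is canonical: genes sorted, (i, j) with
i < j in lexicographic order.

## Classifiers

All models are penalized logistic classifiers scored by AUC on the
held-out study; training touches only the outer training partition
(a leakage guard checks sample-id intersections and aborts the run).

- **Lasso** (baseline): L1 logistic regression on all genes
  (scikit-learn saga; objective (1/n)·logloss + λ‖w‖₁, intercept
  unpenalized, features z-scored with training statistics).
- **Group Lasso**: every network gene seeds a group of itself plus its K
  strongest neighbors (edge-weight priority, lexicographic tie-break).
  Overlap is handled by variable duplication (latent group lasso): each
  group receives a private copy of its member columns and the penalty is
  λ·Σ_g √|g|·‖w_g‖₂ (the √group-size factor controls for unequal group
  sizes at the network boundary). Solved by FISTA with group
  soft-thresholding; the Lipschitz constant is ‖X_dup‖₂²/(4n). With
  singleton non-overlapping groups the objective coincides with the
  Lasso's, which the tests verify to 1e-6 against both scikit-learn and a
  hand-written coordinate-descent oracle. Default tolerance 1e-7 on the
  max coefficient step (20,000 iteration cap) is sufficient for stable
  AUCs; reduction tests tighten it.
- **Park**: average-linkage hierarchical clustering on correlation
  distance 1 − |ρ|; each cluster becomes its raw columnwise-mean
  meta-gene; the cut height is chosen by inner cross-validation of a
  Lasso on the meta-genes. Cut height 0 reduces to plain Lasso.
- **Chuang**: greedy subnetwork growth from every seed gene, adding the
  neighbor that most improves the training AUC of the averaged z-scored
  meta-gene, halting at the first non-improving step.
- **Taylor**: hubs are genes of network degree > 5; each hub is scored by
  the mean over neighbors of |ρ_good − ρ_poor| (Pearson within outcome
  class, requiring ≥3 samples per class); the top 50% of hubs (with their
  neighbors) become averaged meta-genes (the fraction is exposed in
  config, as no canonical value exists).

Hyperparameters are resolved by exhaustive grid search on inner
leave-one-study-out folds; ties prefer the smaller model (larger λ, then
smaller K). Reference grids: λ over 12 log-spaced points in [1e-3, 1],
K ∈ {1, 3, 5, 7, 10}, network size ∈ {100, 300, 500, 1000} genes.

## Cross-study validation

A `FoldPlan` freezes the leave-one-study-out assignments (outer folds and,
inside each outer training set, inner leave-one-study-out folds) plus the
repeat and subsample settings, and is serialized to JSON; every compared
method consumes the identical plan, so performance differences cannot come
from fold composition. Per repeat, the model is refit on a fresh 70%
with-replacement draw of the outer training samples; the correlation
network, when used, is inferred from that same draw, and the synergy
network from the outer training studies only. AUC is always computed per
held-out study, never pooled across studies. Repeats re-draw the training
subsample with the fold plan fixed; inner-fold order is not
re-randomized.

Reported metrics: mean and (sample) SD of the AUC over fold × repeat
cells; signature stability as the mean pairwise Jaccard index of
selected-gene sets (two empty signatures count as identical); per-sample
prognosis by majority vote over repeats with seeded random tie-breaks,
compared between predicted groups by a log-rank test (lifelines).

## Network analysis

Two null models serve different questions. *Node-label shuffling*
preserves the unlabeled topology exactly (degree distribution, clustering,
components) and is the default null for overlap z-scores — observed
gene/link overlap between a reference network and the top fraction of a
target, standardized against the shuffle distribution. *Degree-preserving
rewiring* (double edge swaps, up to 10·|E| successful swaps, weights
reassigned in shuffled order) keeps every node's degree and the gene set
fixed, and is the null for "do the links matter" comparisons; rigid graphs
(e.g. a triangle) are returned unchanged with the achieved swap count
logged.

Topological pair features per network: direct-link indicator, shortest
path (unreachable or absent pairs coded as the network's finite diameter
plus one — bounded and rank-preserving), neighbor Jaccard, and the pair
mean and absolute difference of degree, pagerank at four dampings
(default 0.1, 0.3, 0.5, 0.85; no canonical values exist), closeness,
clustering coefficient and eigenvector centrality. Link prediction trains
an L1 logistic classifier to separate reference links from an equal
number of uniformly sampled non-links over the reference genes, under a
cross-validation scheme that removes from the training side every pair
sharing a gene with any test pair (otherwise node identity leaks);
AUC is reported per source network and for all networks combined, with
feature selection frequencies.

## Synthetic data

The generator emulates a multi-study compendium after batch correction:

- latent outcome y ~ Bernoulli(1/2) per sample;
- *marginal* genes: mean shift `effect_size · y` on N(0, 1) noise;
- *synergistic pairs*: both genes share a dominant factor (weight 6) plus
  private N(0, 0.5²) noise, and receive ±effect_size/2 · y — each gene's
  marginal AUC is ≈ 0.52 at effect 1 while the contrast g_i − g_j carries
  the full effect against sd ≈ 0.7 (pair AUC ≈ 0.84). This regime —
  high pair correlation, near-chance marginal AUC, high pair AUC — is
  precisely what the fitness rewards. An XOR mechanism is available as an
  option but is not the default: linear meta-genes cannot capture XOR,
  and the pair aggregation here is linear by design;
- *co-expression blocks* share a unit-weight factor with no outcome
  signal;
- each study adds a per-gene shift ~ N(0, batch_shift_sd²), default 0.3;
- survival: poor-class times ~ Exp(mean 1.2 y) (P(T > 5) ≈ 1.5%),
  good-class times 5 + Exp(mean 5 y), so class and 5-year status agree
  for ≥95% of uncensored samples; an independent Uniform(0, 10) censoring
  time applies to a `censor_rate` fraction of samples (default 0.2), and
  samples censored before 5 years become *excluded*.

Default scale: 4 studies × 250 samples, 300 genes, 20 marginal genes, 10
synergistic pairs, 5 blocks of 10. What the generator does **not**
emulate: platform-specific probe effects, heavy-tailed microarray noise,
non-linear batch distortions, correlated censoring. Passing tests
therefore demonstrate correctness of the inference machinery and its
statistical calibration under the stated model, not performance on real
microarray compendia.

### Study conditions for the headline properties

- *Planted-pair recovery*: default scale, effect size 1, 10 seeds; the
  full scan must place a median of ≥8 of 10 planted pairs inside the top
  1% of fitness ranks.
- *Links-matter comparison*: 4 studies × 100 samples, 100 genes, 10
  planted pairs, no marginal genes, effect size 0.7, Group Lasso with
  K = 1 and λ = 0.01, truth network spanning all genes (planted pairs
  plus a matching over noise genes) versus its degree-preserving shuffle.
  The effect size and λ sit in the regime where sparse *group selection*
  binds: with strong effects or loose penalties the duplicated-variable
  Group Lasso degenerates to logistic regression on the union of genes
  and the wiring cannot matter; with λ beyond the group-entry threshold
  nothing is selected at all (group screening sees only marginal
  covariances, which the contrast construction makes deliberately tiny).
- *Null calibration*: effect size 0, all five methods, mean cross-study
  AUC required in [0.45, 0.55]; overlap z-scores of a network against a
  relabeled copy required |z| < 3 in ≥95 of 100 seeds.

Problem sizes throughout were chosen so the full suite runs on a single
CPU in minutes while keeping every statistical property comfortably
resolvable.

## Numerical choices

- AUC is the Mann–Whitney statistic with ties counted ½; the column-wise
  scan implementation ranks by double argsort and falls back to exact
  average ranks for tied columns, so it agrees exactly with the O(n²)
  pair-counting definition.
- The 2×2 OLS solve for pair meta-genes carries a 1e-8 ridge so exactly
  collinear pairs (duplicated genes) degrade gracefully to the
  minimum-norm combination; rankings are unaffected.
- Constant genes get zero weight (logged) wherever they appear; constant
  measures min–max normalize to 1 (degenerate, logged).
- Edge-weight and fitness ties break lexicographically on gene symbols;
  gene symbols are uppercased at ingestion and matched exactly across
  compendium and networks, with unmatched network genes dropped and
  counted.
- Scan arithmetic is float32 for memory locality; reported AUC medians
  are float64.

## Known limitations

- The Chuang and Taylor reimplementations follow the published
  descriptions at the granularity the package needs for comparison;
  their original score criteria are underspecified, and the training-AUC
  expansion criterion (Chuang) and top-50% hub cut (Taylor) are this
  package's documented choices.
- Averaging meta-genes cannot express contrast (difference) signals, so
  averaging-based NOPs are structurally blind to the synthetic synergy
  pairs — which is the phenomenon motivating regression-based pair
  aggregation in the first place.
- Combat-style batch correction is not reimplemented; the hook accepts
  any external implementation.
- At transcriptome scale the scan is embarrassingly parallel via
  `--chunk k/m` but this package provides no scheduler.
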