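# Methods

## Pipeline model and assumptions

The package assumes two-class labels and three numeric feature-by-sample
matrices measured on (a superset of) the same samples: mRNA expression,
miRNA expression and CpG methylation beta values. Layers are harmonized
to their common samples before anything else runs; rows containing
missing values are refused at ingest (dropped with a logged count)
rather than imputed, because no imputation scheme is part of the method
and silently inventing values would contaminate the correlation step.

The unit of inference is the *pro-group*. The method assumes that a
miRNA or CpG site regulating a set of genes leaves a correlation
footprint on those genes' expression, so association is purely
correlation-driven — no external target databases or genomic
annotation. A consequence worth keeping in mind: any strongly
co-expressed gene set will be "associated", causal or not; the
S-component score, not the association step, carries the discriminative
evidence.

All randomness descends from one `master_seed`. Iteration *i* uses seed
`master_seed + i (mod 2^31)`; within an iteration, each pro-group's
forest and shuffle-split seeds are derived as `crc32(name) XOR
iteration_seed`, so results are independent of the order in which
pro-groups happen to be enumerated and any single pro-group's score can
be replayed in isolation.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `correlation_method` | spearman | rank correlation is robust to expression outliers and invariant to the logistic squashing of beta values |
| `correlation_threshold` | 0.5 | \|r\| cutoff for association; at n ≈ 180 training samples the null SD of Spearman's r is ≈ 0.075, so 0.5 admits essentially no chance associations |
| `require_negative_mirna` | off | optionally keep only negative miRNA–mRNA correlations (repression); off because positive indirect couplings are informative too |
| `merge_mode` | identical | merge pair-groups with exactly equal gene lists; `jaccard` (single-linkage at ≥ `jaccard_threshold`) is a documented extension |
| `k_top_features` | 10 | FIS filter cap; equalizes pro-group sizes |
| `n_internal_splits` / `internal_test_fraction` | 10 / 0.1 | internal Monte-Carlo CV of the S component |
| `n_outer_iterations` / `outer_test_fraction` | 10 / 0.1 | outer loop; per-class test count is `round(n·fraction)`, minimum 1 |
| `n_trees` | 100 | forest size everywhere (FIS, S, final model). 100 trees already give stable Gini rankings and scores at these problem sizes (tens of features, ~200 samples); doubling it changed no selected feature set in development runs, so the smaller forest is the default |
| `n_top_progroups` | 10 | pro-groups fed to the final model, the report truncation depth, and the network scope |

The outer split is stratified. Stratification is a design choice, not
part of the method's definition; it keeps both classes present in every
test set and makes the balanced-data null score exactly 0.5.

## Numerical and tie-break choices

- **FIS** is the raw mean decrease in Gini impurity per feature,
  averaged over trees (per-tree values via
  `tree_.compute_feature_importances(normalize=False)`). Raw rather
  than sum-to-one-normalized values are used for selection — the top-k
  set is identical either way, and raw values keep a constant feature
  at exactly 0, which guarantees that adding constant features can
  never displace an informative one.
- Ties at the k-th FIS rank and equal S-component scores are broken by
  lexicographic feature/pro-group id; greedy community merges inherit
  networkx's deterministic ordering over the sorted node insertion this
  package uses. Every output is byte-reproducible given the config.
- **RRA**: an item missing from an iteration's (truncated) list gets
  normalized rank 1.0 — the standard convention, stated here because it
  materially penalizes infrequent pro-groups. The rank universe N is
  the set of pro-groups appearing in any truncated list; with very few
  distinct pro-groups the normalized ranks are coarse and the score
  saturates (a single ever-ranked pro-group always scores 1.0 — its
  rank evidence is vacuous, not weak).
- **Frequency** counts appearances in each iteration's top
  `n_top_progroups` ranked list, not among all groups formed; the
  truncation depth is configurable.
- Pro-group scores from degenerate internal test sets cannot occur:
  splits are stratified, and fewer than 10 training samples is a hard
  error.
- Metric conventions: the positive class defaults to the
  lexicographically first label (configurable); ratios with zero
  denominators are reported as 0.0; AUC comes from the positive-class
  probability (trapezoidal ROC) and is `null` when the test set is
  single-class.

## Community detection

The co-occurrence graph connects features that share a pro-group, so
every pro-group induces a clique; node weight is the unweighted mean of
the average scores of the pro-groups containing the feature
(multi-membership rule chosen here), node size its total cross-iteration
appearance count. Communities come from agglomerative
(Clauset–Newman–Moore) greedy modularity maximization. Greedy merging
is a heuristic: it provably matches the exhaustive maximum-modularity
partition on the small benchmark graphs in the test suite (cliques,
triangles, stars), but can be suboptimal on elongated structures such
as paths — reported modularity is the achieved Q, not a global optimum.

## What the synthetic generator does and does not emulate

`SyntheticSpec` plants regulatory modules inside independent Gaussian
background noise: module genes share a latent factor (pairwise
correlation ρ), miRNA rows are negative linear transforms of the
module-gene mean, CpG rows positive transforms, and discriminative
modules shift gene means by δ SD between classes (±δ/2). Methylation
values are logistically squashed into (0,1) to mimic beta values.
Defaults — 100 samples/class, one module (3 genes, 1 miRNA, 1 CpG,
ρ = 0.9, δ = 2), 200/30/30 background features, coupling noise
SD 0.5 — give a planted effect that is strong but not trivial
(per-gene Bayes error ≈ 16%).

It does **not** emulate heavy-tailed count-like expression marginals,
bimodal beta-value distributions, batch effects, correlated background
blocks, or class imbalance at real cohort scale (the balancing step is
still exercised, on synthetic imbalance, in unit tests). Passing tests
therefore demonstrate that the machinery recovers correlation-planted,
class-separating structure — not that it would rank any particular real
biomarker highly.

## Problem sizes used in validation

The acceptance script and end-to-end tests run the full pipeline at 100
samples/class with the default 10 outer iterations, repeated over 10
master seeds for the recovery measurement; null calibration uses 50
seeds at 30 samples/class; RRA and community partitions are verified
against exhaustive/brute-force oracles at m ≤ 6 lists × N ≤ 20 items
and ≤ 8 nodes respectively — sizes at which exhaustive enumeration is
exact.

## Known limitations

- Association ignores correlation sign by default; biologically a miRNA
  is expected to repress its targets (`require_negative_mirna` exists
  for that reading).
- `identical` merging is brittle to single-gene differences between
  gene lists; the `jaccard` mode trades that brittleness for a
  threshold choice.
- RRA is computed over truncated per-iteration lists; pro-groups
  hovering just below the truncation depth are invisible to it.
- With few distinct pro-groups the RRA score loses resolution (see
  above); frequency and average rank remain informative there.
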