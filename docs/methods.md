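# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Trait table and units

Substitution rates are stored in natural units, substitutions per
lineage per million years; fixture columns printed as `×10⁻³` are
rescaled at load so no downstream code handles mixed units. Ages and
credibility intervals are in Ma. Missing values are encoded `-` in the
TSV dialect (configurable). A censored rate-heterogeneity entry `>x`
keeps the bound `x` plus a censoring flag; such genes came from
inconclusive lognormal relaxed-clock runs and are never classified
clocklike.

## Clock categorization

A gene is rate heterogeneous iff `ucld.stdev >= 0.6`. The threshold is
configurable; `>=` (rather than `>`) on the heterogeneous side makes the
partition exhaustive at the boundary. On the packaged amino-acid table
this yields 18 clocklike / 23 heterogeneous genes; on the beetle
nucleotide table, 23 / 18.

## Sex-bias classification

Biased iff the summary score of one sex is at least `fold` (default 2)
times the other's, applied symmetrically; a ratio of exactly `fold`
counts as biased. A pseudocount (default 0) handles zero scores;
both-zero profiles are unbiased. Multi-stage profiles are reduced per
sex by a configurable aggregator (mean by default) before the rule is
applied — the choice of aggregator is a genuine free parameter since no
per-stage rule is canonical.

## Alignment curation

The filters replace manual curation with reproducible surrogates, and
every report records the thresholds in effect:

- *Short fragments*: a sequence is dropped when its residue count is
  below `min_span` (default 0.5) times the **median** residue count.
  The median, not the alignment width, defines "the gene": width
  inflates with indels, the median is robust to a minority of
  fragments. The filter is idempotent.
- *Private insertions*: maximal runs of at least `min_run` (default 10)
  consecutive columns where exactly one sequence has residues are
  deleted. Non-focal sequences lose only gap columns. Reported spans
  are 0-based half-open in input coordinates.
- *Fragment merging*: disjoint fragments of one protein are placed at
  their offsets and gaps filled with the missing character; overlapping
  fragments must agree on the overlap or the merge fails.
- *Divergent sequences*: each sequence's mean pairwise p-distance
  (gapped positions excluded pairwise) is compared leave-one-out with
  the mean and SD of the other sequences' means; flag when above
  `mean + k_sd × SD` (default k = 3). The candidate is excluded from
  the reference spread because a single extreme outlier in a small
  alignment otherwise inflates the SD it is judged against and escapes
  detection. Zero-variance alignments flag nothing.
- *Conspecific redundancy*: same-taxon sequences with pairwise identity
  at or above 99% are grouped transitively and only the longest member
  kept. Monophyly checks against a tree are out of scope.

## Calibration

The concordant overlap of closed intervals is `[max(lows), min(highs)]`;
boundary-touching intervals intersect in a point, which is returned.
Calibration-set membership is driven by the recorded paraphyly flag and
an explicit exclusion list (default `nsr`, whose age estimate is
incompatible with the beetle fossil record), not by re-detecting
monophyly — trees are not inputs to this package. On the packaged table
19 intervals remain and intersect in [277.4, 314.2] Ma. Group rate
summaries use the sample SD (n − 1).

## Statistical tests

All tests are implemented in the package; SciPy supplies only reference
distributions (normal, t, chi-squared) and serves as an independent
oracle in the test suite.

- *Mann-Whitney U*: `U_x` counts pairs with `x > y` plus 0.5 per
  cross-group tie; `U_y = n₁n₂ − U_x`. Both statistics and their
  minimum are always reported, because published accounts quote either
  member of the pair. The p-value is exact — by enumerating the null U
  distribution through its generating function — when the pooled data
  are tie-free and `n₁n₂ <= 2500`, otherwise a normal approximation
  with tie correction and continuity correction (the convention of R's
  `wilcox.test`). Two-sided throughout.
- *Kruskal-Wallis*: midrank H with the standard tie correction;
  all-identical data give H = 0, p = 1.
- *Spearman*: rho is the Pearson correlation of midranks; S is derived
  from rho through `S = (1 − rho)(n³ − n)/6` so any reported (S, rho,
  n) triple is internally consistent to 1e−9. p from the t
  approximation with n − 2 df.
- *Permutation chi-squared*: Pearson chi-squared without continuity
  correction on the observed cross-tabulation; the second labelling is
  shuffled `reps` times (default 9999) with a seeded generator, and
  `p = (1 + #{χ²_perm >= χ²_obs}) / (reps + 1)`. The add-one estimator
  is mildly conservative and can never return 0; results are bit-
  reproducible given (inputs, reps, seed). For small binary tables
  (n ≈ 40) the conditional permutation distribution is strongly
  discrete and the realized type-I error at the 0.05 level is ~0.02–
  0.03 — conservative, not anticonservative; at n >= 100 the rejection
  rate is close to nominal. No multiple-testing correction is applied
  anywhere (raw p-values are reported, matching standard practice for
  this analysis); a Holm step is available to users via statsmodels if
  desired.

## Network analyses

All edges — physical and genetic/regulatory — are treated as one
undirected simple graph; direction and sign are annotations only. The
graph must be connected for centrality and community analyses.

- *Closeness* is normalized by (n − 1), so scores lie in (0, 1].
- *Eigenvector centrality* is computed by power iteration on A + I (the
  shift leaves the Perron vector unchanged but removes the ±λ
  oscillation of bipartite spectra) and scaled to a maximum entry of 1.
  Convergence tolerance 1e−10; non-convergence is an error.
- *Corrected importance* is `log10(centrality × total_interactions)`,
  base 10 by convention; downstream tests are rank-based, hence
  base-invariant. `total_interactions` is the gene's genome-wide
  interaction count and must be at least its degree in this graph.
- *Modularity* is Newman's Q on unweighted edges.
- *Communities*: greedy agglomerative merging and seeded Louvain are
  delegated to networkx; edge-betweenness partitioning removes
  max-betweenness edges iteratively and cuts the dendrogram at the
  maximum-Q level; exact maximization is an in-house branch-and-bound
  over set partitions (nodes assigned in sorted order to an existing or
  fresh block, pruned with the admissible bound "remaining edges all
  become intra-community, degree penalties frozen"), refused above 14
  nodes without an explicit override because Bell-number growth makes
  larger instances impractical.
- *Bipartition scan*: communities are collapsed to a quotient graph; an
  inter-community edge qualifies as a cut only when it is the sole edge
  between its two communities and a bridge of the quotient. Each
  qualifying cut splits the communities into two sides whose pooled
  node rates (nodes without rates dropped; at least two rated nodes
  per side required) are compared with the Mann-Whitney test above.

## Synthetic generators

All generators are pure functions of (parameters, seed) using numpy's
`default_rng`, and each returns a truth record consumed by recovery
tests. Defaults mirror the real study's scale:

- *Trait tables*: 41 genes; biased/duplicated/network proportions
  7/41, 15/41, 19/41; rates lognormal with sigma 0.8 (reproducing the
  roughly two-orders-of-magnitude spread of the real rates) and median
  near 1.7×10⁻³; a twofold multiplicative rate effect on biased genes
  (1.0 gives the null); `ucld.stdev` from a two-component mixture
  straddling 0.6 (truncated normal below, lognormal above). Trait
  labels are independent Bernoulli draws, mirroring the observed
  pairwise independence of the real annotations.
- *Networks*: planted-partition graphs, default five communities of
  sizes (5, 4, 4, 4, 4) with p_in = 0.7 and p_out = 0.025 so the
  expected edge count matches the 21-node/28-edge study graph;
  `paper_scale_network` additionally conditions on exactly 28 edges and
  connectivity. Node rates are lognormal with per-community
  multiplicative shifts.
- *Expression*: lognormal baseline scores; a planted biased gene's
  score in the relevant sex is multiplied by `fold`; both sexes then
  receive independent multiplicative noise `exp(N(0, noise_sd))`. Note
  the log *ratio* noise therefore has SD `noise_sd × √2`, which sets
  the achievable label-recovery rate (≈90% at noise 0.3 with a fold-4
  effect and the twofold rule; the closed form is in the test suite).
- *Alignments*: conserved consensus with 5% per-site substitutions,
  plus planted short fragments (30% span), private insertion runs of
  specified lengths, and fully randomized divergent rows — hosts are
  chosen disjointly so every artifact is attributable.
- *Age intervals*: lognormal CI half-widths (median 90 Ma, matching the
  broad real intervals); centers drawn so each interval covers the true
  age independently with the nominal probability.

What the generators do **not** emulate: phylogenetic correlation among
genes, sequence evolution along trees, relaxed-clock posterior shape,
non-independence of trait labels (available only through an explicit
knob), and the real interaction topology. Passing recovery tests
therefore demonstrates the correctness of the implementations under
the stated statistical structure, not the biological conclusions on
real data.

## Problem sizes in the test suite

Oracle and calibration properties run at sizes chosen to make the
checks sharp while keeping the suite fast on one CPU: 1000 random
Mann-Whitney instances against the pair-counting oracle; exact
modularity against full partition enumeration on twelve random
connected graphs of 4–8 nodes; type-I calibration of the permutation
test on 1000 null tables of 200 binary labels at 999 replicates; power
comparison over 500 simulated tables per condition; planted-partition
recovery at two communities of eight nodes. The full suite completes in
well under a minute.

## Known limitations

- The published upper calibration bound (315.2 Ma) is not exactly
  recoverable: the original 18-gene monophyletic set is not fully
  identifiable from the printed table, whose non-paraphyletic rows
  give an upper bound of 314.2 (from Dark). The lower bound 277.4 is
  robust to this ambiguity.
- Printed group rate means (e.g. 0.00314 ± 0.000533 for clocklike
  beetle genes) are reproduced from rounded table values to within 2%,
  not exactly; the unrounded posteriors are not available.
- The real interaction network exists only as a figure; all
  network-stage results on the packaged surrogate exercise the
  machinery and are not comparable to the published network statistics.
- The multicopy flag (> 119 sequences) is advisory: the underlying rule
  held "in most cases" only, and final duplication status is a curated
  input column.
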