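# Methods

## Expression calls

Input matrices are feature-by-sample microarray intensities. Files may be
linear or log2-encoded (`scale_tag`); internally everything is linear, so
log-ratios are always taken between raw intensity values. The expression
cutoff of a dataset is the median over *all* entries of its matrix (even
counts: mean of the two central order statistics), and a feature is called
expressed in a sample only when strictly above that cutoff — ties at the
median are not expressed. The median rule means roughly half of all cells
are "off" by construction, which matches the intuition that many mature
miRNAs sit barely above array background.

## Sister-pair log-ratios and classification

For a hairpin with both arms measured, the per-sample statistic is
`log2(x5′/x3′)`: positive when the 5′ arm dominates, negative when the 3′
arm does. Arms are assigned from genomic geometry: on the + strand the
mature with the smaller start is 5p; on the − strand the one with the
larger start; a single mature takes the arm implied by its position
relative to the hairpin midpoint. Identical (5p, 3p) identifier couples
produced by hairpins at different loci are counted once.

In the thresholded matrix, a cell where only the 5′ arm is expressed is
set to (max finite log-ratio + 0.1) and only-3′ cells to (min finite −
0.1). These sentinels deliberately sit just outside the observed range:
they encode "maximal bias" without dominating distances. Cells where
neither arm is expressed carry no information about bias direction and are
excluded from standardization and from all distances.

Pair classes follow directly from the per-sample calls: `A` (never
concurrent), `C` (never alternative while expressed), `AC` (both kinds of
sample occur), `NOT_EXPRESSED`. Concurrent pairs additionally get a
*comparable* flag: the per-sample criterion is |log2 ratio| ≤ 1 (within
two-fold, inclusive); the per-pair aggregation over concurrent samples is
the median by default and is configurable (`mean`, `all`, `any`) because a
per-pair rule is genuinely underdetermined — the per-sample criterion is
well defined but several defensible aggregations exist. Summary tables
report per-dataset counts and percentages over the full pair set, and
cross-dataset unweighted means with sample standard deviations (ddof = 1)
of those percentages.

## Clustering

Standardization is per pair row (z-score over non-missing cells, ddof = 1,
sentinels included as ordinary values); rows with fewer than two observed
cells or zero spread are dropped with a warning. Row-wise scaling is the
default because the heatmap-style display compares the direction and
strength of bias per pair across samples; global scaling is available by
standardizing outside the helper.

Clustering is UPGMA (unweighted average linkage) on Euclidean distances.
With missing cells, the squared distance over the jointly observed
dimensions is rescaled by (total dims / observed dims) before the square
root — the pairwise-complete convention. Two items with no jointly
observed dimension are an error rather than an imputation. Items are
sorted lexically before linkage so ties and leaf order are deterministic.
The linkage itself is scipy's average-linkage implementation; tests verify
it against a naive independent UPGMA (merge height = mean of all original
cross-cluster distances) to 1e-12 on randomized small problems.

## Host-gene analyses

Intragenic status requires *full* containment of the hairpin interval in a
gene span (intron-inclusive genomic extent), on the same strand by default
— intragenic miRNAs are candidates for co-transcription from the host
promoter, but the requirement can be relaxed (`require_same_strand=False`).
Coordinates are 0-based half-open internally; GFF3 (1-based closed) is
converted at the boundary. If several genes contain a hairpin, the
shortest container wins, with lexical gene-id tie-break, and the ambiguity
is logged.

Host-versus-rest gene-length comparison uses the two-sided Wilcoxon
rank-sum test: exact when both groups have ≤ 12 observations (tie-aware —
the null distribution of the doubled-midrank sum is enumerated by a
subset-sum count over equally likely group assignments; two-sided p =
2·min(tails), capped at 1), otherwise the normal approximation with tie
and continuity corrections.

miRNA–host correlation is Pearson's r over matched samples with the exact
t-transform p (n − 2 df); a permutation variant exists for very small n.
Correlations are computed on linear intensities by default with a log2
switch. Records with n < 3 or a zero-variance profile are skipped, never
imputed. FDR control is Benjamini–Hochberg per dataset (Benjamini–
Yekutieli available). When a host carries both matures of one hairpin,
`collapse_best_of_pair` keeps the record with the higher r (ties → 5p
arm); since it keeps per-host maxima it can only raise the summary
percentages, and it is therefore an optional, clearly-labelled step.

## Target-prediction integration

Regulator profiles are filtered before scoring: the ⌈n·q⌉ features with
the lowest Shannon entropy (profiles normalized to sum 1; q = 0.25) and
the ⌈n·q⌉ with the lowest mean expression are removed as a union. Entropy
is computed on the normalized profile directly (not on binned values); a
spiky profile concentrated in few samples has low entropy, a flat one high
entropy, so the two criteria capture "almost invariable after
normalization" and "weak" respectively.

Each surviving predicted relation gets the Pearson correlation between its
regulator and target profiles, on log2 intensities by default (standard
for array data, and scale-free planting of correlations makes them
directly recoverable); linear is available. The *background* is the set of
relations with r < 0; the c% cutoff selects ⌈c/100·|background|⌉ most
negative relations with deterministic (r, id) ordering. Enrichment at a
cutoff is observed/expected validated relations with expected allocated
proportionally from the background, so c = 100 gives score 1 identically
and expected counts are additive over any partition of the background.

In PROXY mode, each intragenic mature with a measured host gene is
replaced by its host profile; filtering applies to the proxy profiles
themselves; predictions whose target is the regulator's own host gene are
excluded (they would contribute a trivial self-correlation) — this
exclusion is logged and configurable. The overlap report gives, per
cutoff, the intersection and Jaccard index of validated relations
detected by REAL and PROXY.

## Synthetic-study generator

The generator emulates the structure of matched miRNA/gene microarray
studies. All intensities are log-normal: levels are laid out on the log2
scale, Gaussian noise (`noise_sd`, default 0.1 log2 units) is added, and
values are exponentiated. The default design has 2 tissues × 20 samples
and 50 sister pairs per behaviour mode; the enrichment benchmark raises
this to 2 × 25 samples. The defaults below are the standard study design
used throughout the tests; problem sizes were chosen to exercise every
code path at desk scale.

Key parameters (log2 units unless noted): `baseline_mean` 8 (matrix
midpoint), `level_separation` 3 (distance of the planted low/high clusters
from the midpoint), `bias_magnitude` 2 (arm offset of biased modes),
`noise_sd` 0.1, `n_genes` 2000, `frac_intragenic` 0.5,
`frac_multi_mirna_hosts` 0.1 (fraction of host genes carrying two
hairpins), `host_length_factor` 6 (hosts are drawn from a length
distribution six-fold longer — arithmetic-mean ratio — than other genes),
`host_coupling_rho` 0.2, `n_true_targets` 500 at `true_target_r` −0.7
among `n_decoy_predictions` 10 000, `n_validated` 50.

Pair modes and the class they plant:

| mode | construction | planted label |
|---|---|---|
| `alternative` | favoured arm high, other low, all samples | A |
| `silent` | both arms low | NOT_EXPRESSED |
| `concurrent_comparable` | both high, fixed offset drawn in (0.2, 0.9) | C |
| `tissue_flip` | both high, ±bias/2 offset flipping sign between tissues | C |
| `fixed_bias` | favoured arm high everywhere; other arm high−bias in one tissue, low in the others | AC |

The `fixed_bias` mode intentionally drops the disfavoured arm below the
cutoff outside its concurrent tissue: with every mode either always-
concurrent or always-alternative no pair would plant the mixed AC class,
and AC recovery is a required property of the classifier. Both
`tissue_flip` and `fixed_bias` make the log-ratio pattern tissue-dependent,
which is what lets sample clustering recover the tissue partition.

Because the expression cutoff is the *emergent* median of the generated
matrix rather than a planted constant, the generator balances the counts
of high and low cells by adding single-mature "filler" hairpins at
background level (plus at most one mixed filler): the median then falls in
the wide gap between the planted clusters and every planted call is
recovered despite noise. Filler counts are derived deterministically from
the configuration.

Host genes receive a profile coupled to the log2 profile of one of their
matures (the 5p of their first hairpin) through a Gaussian copula with
correlation `host_coupling_rho`; the host profile's log2 spread matches the
mature's, so `rho = 1` with zero noise is an exact affine relation (r = 1
on both scales). True-target genes are drawn the same way at
`true_target_r` against regulators sampled from the *retained* (post-
filter) intragenic matures, so the planted signal survives the pipeline's
own filtering; decoys link independent profiles and never a regulator's
own host. Randomness is organised as three deterministically spawned
streams (annotation, miRNA expression, genes/targets), so identical
configurations yield byte-identical output files.

What the generator does **not** emulate: platform- or probe-specific noise
and batch effects, correlated gene co-expression structure beyond the
planted couplings, isomiR/offset-RNA complexity, and multi-locus mature
identifiers. Passing tests therefore demonstrate correctness of the
pipeline's logic and statistics under a controlled generative model, not
performance on any particular array platform.

## Numerical and degenerate-input conventions

- Medians of even counts: mean of central order statistics.
- Pearson r clipped to [−1, 1]; |r| = 1 reports p = 0.
- Zero or negative intensities are rejected by the raw log-ratio path and
  handled by the thresholded path (they can only be "not expressed").
- A thresholded matrix with no concurrent cell at all has undefined
  sentinels and is an error.
- Percentile cutoffs use ceiling selection sizes; boundary ties resolve by
  (r, regulator id, target id).
- All stochastic components accept explicit seeds; clustering and
  selection tie-breaks are lexical, making every output reproducible.

## Known limitations

- The per-pair "comparable" aggregation is a convention (median by
  default); published per-pair comparability fractions depend on an
  unstated aggregation and are not used as check targets.
- The exact rank-sum path enumerates groups up to 12 + 12; beyond that the
  normal approximation is used (with tie/continuity corrections), which is
  standard but approximate.
- The enrichment benchmark's null (PROXY) score at very stringent cutoffs
  divides by expected counts of order one; such ratios are Poisson-noisy,
  and the test suite evaluates the null band on counts pooled across
  replicates for that reason.
- PROXY analyses are restricted to intragenic miRNAs with a measured host
  gene; REAL and PROXY curves are therefore computed on overlapping but
  not identical relation sets, as in any real study.
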