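# Methods

## The problem

Overrepresentation analysis (ORA) asks whether a selected *foreground*
gene list (typically the significant genes of a differential-expression
contrast) overlaps a gene set more than expected given a *background* of
all genes detected in the assay. With a universe of `N` background genes,
`K` of them in the set, and a foreground of `n` genes of which `k` fall in
the set, the test is the upper tail of the hypergeometric distribution,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

identical to the one-sided ("greater") Fisher exact test on the 2×2
table, with fold enrichment `(k/n)/(K/N)` as the effect size. Per-set
p-values are corrected with Benjamini–Hochberg (BH) over the tested sets.

Two silent deviations from this recipe are widespread in popular tools,
and this package implements both *deliberately*, next to the correct
analysis, so their cost can be measured:

- **The background problem** (`background_handling="annotated_only"`):
  background genes not annotated to any set in the library are dropped
  from the universe. `N` shrinks to `N' = |background ∩ annotated|`, which
  multiplies every fold enrichment by exactly `N'/N ≤ 1` and deflates
  significance. The published workaround — appending the entire background
  as one extra gene set — makes every background gene annotated and is
  implemented in `append_universe_set`; the engine never tests or reports
  the reserved `__UNIVERSE__` set, and does not count it toward the BH
  test number, so the workaround reproduces the correct analysis
  *exactly* (a tool that also counts the appended set as a test agrees
  only to a few significant figures).
- **The FDR problem** (`fdr_scope="overlapping_only"`): sets with zero
  foreground overlap are discarded *before* BH, understating the number
  of tests `m` and deflating every FDR value (provably: BH adjusted values
  are monotone in `m`). The published workaround pads the observed
  p-value vector with `expected − observed` ones — where `expected` counts
  the sets with at least `detection_min = 2` background members — and
  re-runs BH; this too recovers the correct FDRs exactly.

## The differential-expression stand-in

The benchmark needs a gene ranking and a significance call, not any
particular DE tool. `nb_wald_test` is a compact negative-binomial GLM
Wald test:

- median-of-ratios size factors (total-count fallback when no gene is
  positive everywhere);
- per-gene method-of-moments dispersion from the pooled within-group
  variance of normalised counts. A log-linear mean–dispersion trend is
  fitted to *binned means* of the raw moment estimates (fitting only the
  positive per-gene estimates selects for overestimates at n = 3 and
  biases the trend up); per-gene estimates are then shrunk 50/50 toward
  the trend on the log scale, with the chi-square log-bias of the moment
  estimate removed before averaging, floored at 1e-8;
- IRLS fit of the log-link NB GLM (intercept + group, plus subject
  indicators in paired mode) with size factors as offsets; the Wald
  statistic is the group coefficient over its standard error, and log2
  fold changes are the group coefficient divided by ln 2;
- the statistic is referred to a *moderated t*: the degrees of freedom
  solve a trigamma matching for the variance of the shrunken
  log-dispersion (≈13.4 at 3v3), interpolated per gene toward the normal
  as the dispersion's share of the variance vanishes (Poisson-limited
  genes have effectively known variance). Under a negative-binomial null
  (dispersion 0.05, 3v3) the measured type-I error at nominal 0.05 is
  0.049–0.058; under the thinning null the p-values are uniform.

Foreground selection follows the benchmark's rule: genes with FDR < 0.05
of the requested sign; if fewer than 200 qualify, the 200 smallest-p
genes of that sign instead. A fixed-size variant (`select_foreground_topk`)
supports the foreground-size sweep (125–2000 genes).

Samples are sorted by name internally so results are invariant to input
column order. `reference=` names the control group explicitly; the
default (lexicographically first label) is a trap with `{case, ctrl}`
labels, where it silently flips all signs.

## The FCS comparator

`run_fcs` is a preranked GSEA-style functional-class-scoring method: genes
are ranked by the DE statistic (descending, ties by gene id) and each set
is scored by the classic running sum — hits advance by `|score|^w`
normalised over hits (`w = 1` by default, `w = 0` for the unweighted
statistic), misses retreat by `1/(n − n_hits)` — with the enrichment score
(ES) the signed maximum deviation. Significance uses a gene-sampling
null: ES recomputed for random same-size sets, `p = (1 + #{same-sign
nulls at least as extreme}) / (1 + #{same-sign nulls})`. The null depends
only on the ranking and the set size, so it is shared between equal-size
sets. BH always runs over *all* tested sets — the FCS path is
structurally immune to the FDR problem.

The permutation p-value has a floor of `1/(n_same_sign + 1)`. With 1000
permutations the floor (≈2e-3) collides with BH over 200 sets whenever
fewer than ~8 sets reach it, capping sensitivity; the benchmark therefore
runs the comparator at 4000 permutations (the referenced preranked
implementations use analytic p-values and have no floor). This is a
property of the permutation scheme, not of functional class scoring.

## The simulator

`make_pseudosamples` emulates a pseudosample benchmark with pathway-level
ground truth:

1. a deep single-sample baseline profile — either supplied or generated by
   `synthetic_baseline` (log-normal expression, meanlog 4 / sdlog 2 on
   the natural-log scale, rounded, rescaled to ≥50M reads), which spans
   >4 orders of magnitude like a real deeply sequenced library;
2. a library of `n_sets = 200` random sets of `set_size = 30` genes drawn
   uniformly without replacement (overlap between sets allowed);
   `frac_de = 5%` of sets are chosen as truth, half up and half down;
3. per pseudosample (3 control + 3 case): one multinomial draw thins the
   baseline to exactly `target_depth` (20M by default) reads, then every
   count is multiplied by an independent Normal(1, `noise_sd`) factor
   truncated at zero and rounded (`noise_mode="per_gene"` instead draws
   each gene's SD uniformly from [0, `noise_sd`]);
4. case samples multiply the member genes of up-truth sets by `2^0.5` and
   of down-truth sets by `2^-0.5` ("log fold change of ±0.5" in the log2
   convention); genes in both an up- and a down-set are left unchanged;
5. the background is defined by the low-count filter (mean < 10 reads per
   sample removed), exactly as for real data.

The default `noise_sd` is 0.3, the midpoint of the 0–0.6 range the
benchmark sweeps. All randomness flows through `numpy.random.SeedSequence`
child streams, so a single seed reproduces the entire experiment
bit-for-bit.

What the generator does **not** emulate: gene length/GC/library-prep
biases, correlated gene modules, outlier samples, and annotation errors.
Passing benchmarks here show how the *enrichment mechanics* behave under
controlled signal and noise, not how any tool performs on a specific real
dataset.

## Scoring and the benchmark

A prediction is a signed `(set_id, direction)` pair; an up-truth set
reported only as down counts as both a false positive and a false
negative. Precision, recall and F1 are computed per replicate;
`summarize_study` averages precision over the replicates where at least
one call was made (replicates with zero calls are reported in
`n_no_calls`, not averaged in as zeros, which would penalise a method for
correctly staying silent) and reports Monte-Carlo standard errors for
everything.

The six benchmark methods map onto the failure modes as: `ora_default`
(both bugs), `ora_bgfix` (default + background append), `ora_fdrfix`
(default + p = 1 padding), `ora_bothfix` (both workarounds — provably
identical to correct), `ora_correct`, and `fcs`.

### Scaled-down study conditions

The shipped tests and `scripts/acceptance.py` run the benchmark at a
desk-scale operating point chosen once by a power analysis of the scaled
design: a 10,000-gene synthetic baseline thinned to 10M reads (≈5,200
genes pass the detection filter; each 30-gene set keeps ≈15 detected
members), 100 replicates per noise level over the grid {0, 0.2, 0.4,
0.6}, FCS at 4000 permutations. At this point the per-gene power moves
from saturating (noise 0) through marginal (0.4) to near-null (0.6),
which is the regime where the methods separate. Equivalence and
calibration checks use smaller instances (4,000 genes, 1M reads) since
their conclusions are exact or distributional, not power-dependent.

One caveat is intrinsic to the noiseless endpoint: with no added
variance the DE step recovers essentially every detected injected gene,
every method finds every truth set, and all recall means saturate at
exactly 1.0 — so at added noise 0 the FCS recall advantage is a tie, not
a strict exceedance. It is strict at every positive noise level.

## Down-sampling consistency

`downsample_consistency` measures call stability on paired (e.g.
tumour/normal per subject) data: significant signed sets are computed on
the full cohort once per method; then, per subsample size and replicate,
subjects are drawn without replacement, the paired DE + enrichment
pipeline is re-run, and each call is classed as consistent (same set,
same direction as the full-cohort result) or inconsistent. The
inconsistent proportion estimates the realised false discovery rate; a
call must match in direction to count as consistent.

## Numerical choices

- p-values are floored at 1e-300 (BH input must be in (0, 1]) and never
  rounded in intermediate computation; FDR values are capped at 1.
- Ties are broken by identifier everywhere results are ordered (records
  by `(p, set_id)`, gene rankings by `(−stat, gene_id)`).
- `significant_sets` uses strict `fdr < alpha`; `alpha ≥ 1` selects every
  reported set (FDRs are capped at 1).
- Empty-vs-empty significant-set comparisons have Jaccard 1 by convention
  (identical outcomes), logged when it happens.
- The IRLS adds a 1e-6 ridge for rank safety and clamps the linear
  predictor to ±30; genes with all-zero counts report `p = 1`, statistic 0.
- Gene identifiers are exact case-sensitive strings; no symbol
  normalisation is attempted anywhere.

## Known limitations

- The DE engine is a documented stand-in: no outlier detection, no
  posterior fold-change shrinkage, dispersion by moments rather than
  maximum likelihood. Externally computed DE tables can be substituted
  via TSV (`read_de_results`).
- The FCS comparator's permutation p-values are floor-limited (above);
  numeric agreement with analytic preranked implementations is
  approximate by design.
- Benchmark effect sizes (the precision/recall gaps between variants)
  scale with library size, foreground size and sequencing depth; at desk
  scale the *directions* are stable but the magnitudes are smaller than
  with a 367M-read baseline and 1000 replicates.
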