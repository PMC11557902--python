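# orabench

Overrepresentation analysis (ORA) done right, done wrong on purpose, and
benchmarked.

ORA is the workhorse of functional enrichment: given a *foreground* of
interesting genes and a *background* of all genes detected in the assay,
each gene set in a library is tested for excess overlap with the upper
tail of the hypergeometric distribution,

```
p = P(X >= k),   X ~ Hypergeometric(N, K, n)
fold enrichment = (k/n) / (K/N)
```

where `N` is the universe size, `K` the set's detected members, `n` the
foreground size and `k` the overlap, followed by Benjamini–Hochberg (BH)
correction over the tested sets.

Many popular tools silently deviate from this recipe in two ways, and
both deviations bias results in a fixed direction:

- **the background problem** — background genes not annotated to any set
  are dropped from the universe, shrinking `N` to `N'` and multiplying
  every fold enrichment by exactly `N'/N ≤ 1` (significance deflates
  with it);
- **the FDR problem** — sets with zero foreground overlap are discarded
  *before* BH, understating the number of tests and deflating every FDR
  value, which inflates false positives for short foreground lists.

`orabench` implements the correct test, faithful emulations of both
failure modes, the two published workarounds (appending the whole
background as a gene set; padding the p-value vector with ones before
re-running BH) — each of which provably recovers the correct analysis —
plus a negative-binomial differential-expression engine, a preranked
GSEA-style functional-class-scoring (FCS) comparator, and an RNA-seq
count simulator with pathway-level ground truth, so the cost of each
failure mode can be measured in precision and recall. It is aimed at
method developers, tool auditors, and anyone deciding whether a published
enrichment result survives a corrected reanalysis.

## Worked example

Write the self-contained toy workspace and analyse it in correct mode:

```
$ orabench fixture --out demo --seed 1
$ orabench ora --foreground demo/foreground.txt --background demo/background.txt \
      --gmt demo/toy.gmt --mode correct
# orabench v0.1.0
# command: ora
# config_hash: a2fd679b4e0e
set_id  k  n  K  N   p_value               fold_enrichment  fdr                  overlap
S1      3  3  5  20  0.008771929824561403  4.0              0.017543859649122806 g1,g2,g3
S2      0  3  5  20  1.0                   0.0              1.0
```

The foreground (g1–g3) sits entirely inside the five-gene set S1, so with
a 20-gene universe the overlap probability is C(5,3)/C(20,3) = 10/1140 ≈
0.0088 and the fold enrichment is (3/3)/(5/20) = 4. S2 shares no genes
with the foreground but *was still tested* (k = 0 gives p = 1 from the
test itself), so BH runs over m = 2 tests and S1's FDR is 2 × 0.0088.
The off-background set S3 is not a test at all.

The same lists under both failure modes:

```
$ orabench ora ... --mode bug-both
set_id  k  n  K  N   p_value              fold_enrichment  fdr
S1      3  3  5  10  0.08333333333333333  2.0              0.08333333333333333
```

Half the background (g11–g20) is unannotated and vanished from the
universe: `N` dropped from 20 to 10, fold enrichment halved (× N'/N =
10/20), the p-value rose tenfold, and S2 was silently removed from the
test count. A significant, correctly-computed result (FDR 0.018) became a
non-significant one (FDR 0.083) without any warning — which is the point.

Other entry points: `orabench de` (NB Wald differential expression),
`orabench fcs` (preranked comparator), `orabench simulate` (pseudosample
generator with truth), `orabench benchmark --config sim.yaml` (the full
precision/recall study), `orabench sweep` (foreground-size sweep),
`orabench downsample` (paired-cohort consistency), and `orabench compare`
(Jaccard and per-set deltas between two result tables — the counterpart
of the interactive comparison tool). Every command is a thin wrapper over
the `orabench` Python API (`run_ora`, `run_fcs`, `nb_wald_test`,
`make_pseudosamples`, `run_simulation_study`, ...).

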