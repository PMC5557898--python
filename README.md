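# twinconcord

Concordance analysis of monozygotic (MZ) twin mouse embryos produced by
separating the two blastomeres of two-cell embryos.

When the sister blastomeres of a two-cell mouse embryo are split and
cultured individually, the resulting twin blastocysts fall into two
classes: pairs in which both members build a functional epiblast
(concordant) and pairs in which only one does (discordant).
`twinconcord` implements the quantitative machinery for studying this
partition in lineage-count, transcriptome, tracing and outcome data:

- **Lineage concordance (the 9-2-2 criterion).** Background variation is
  estimated from dizygotic (DZ) pairs — unrelated embryos of the same
  mother paired at random — as the median per-lineage absolute cell-count
  difference `m_l` for trophectoderm (TE), epiblast (EPI) and primitive
  endoderm (pEnd). Because an MZ blastocyst carries about half the cells
  of an intact embryo, the concordance threshold is `m_l / 2`; DZ medians
  of (18, 4, 4) cells give thresholds of (9, 2, 2). An MZ pair is
  concordant iff |ΔTE| ≤ 9 and |ΔEPI| ≤ 2 and |ΔpEnd| ≤ 2.
- **Unordered-pair transcriptome ratios.** Twin members carry no
  intrinsic order, so each gene's within-pair comparison is the ratio
  `E_higher / E_lower ≥ 1`. Genes are summarized across pairs by the
  mean and SD of their ratios and the coefficient of variation
  `CV = SD / mean`, which ranks genes for enrichment-tool export.
- **Co-twin matching.** Samples are clustered hierarchically on
  correlation distance `d(i,j) = 1 − r(i,j)`; a true pair merged as
  sibling leaves (a first-order connection) counts as correctly
  matched. The observed count `k` of `n` pairs is interpreted against
  the exact null of a uniformly random perfect matching of the `2n`
  samples, `P(K=k) = C(n,k)·D(n−k)/(2n−1)!!` with mean `n/(2n−1)`.
- **Epiblast contribution skew.** In lineage-traced intact embryos the
  dominant fraction `max(a,b)/(a+b)` of NANOG⁺ cells per blastomere
  progeny classifies embryos as balanced (≤ 0.6), intermediate or
  skewed (> 0.8).
- **Exact statistics.** Fisher's exact 2×2 test and the Wilcoxon
  signed-rank test are computed with exact integer / enumeration
  arithmetic appropriate for small embryo cohorts.
- **Synthetic-study generator.** A seeded generator reproduces the
  statistical structure all of the above assume (latent two-class
  pairs, half-sized MZ blastocysts, pair-correlated transcriptomes with
  a quiet housekeeping panel and class-divergent EPI-program genes,
  balanced/skewed tracing mixtures, paired outcomes), so the whole
  pipeline is testable without downloads.

The core operations are exposed as scikit-learn-style estimators
(`ConcordanceClassifier`, `PairRatioTransformer`, `CoTwinMatcher`) with
plain functions (`derive_thresholds`, `ratio_table`,
`null_match_distribution`, ...) as thin wrappers.

## Worked example

Run the consolidated synthetic-study report:

```sh
twinconcord report --seed 1 --outdir demo_report
```

which prints `report written to demo_report/report.txt`; the report
(abridged) reads:

```
== Lineage concordance ==
DZ-derived thresholds (TE, EPI, pEnd): ('6', '2.5', '2')
MZ pairs: 8; concordant: 4 (0.5)
per-lineage symmetrized Pearson r: te=0.944954, epi=-0.264489, pend=0.981811

== Paired transcriptome ratios ==
genes: 26597; pairs: 8
housekeeping panel mean ratio (E_higher/E_lower):
  Actb: 1.0392 +/- 0.0279345
  ...
Nanog mean ratio: 3.06131
genes with mean ratio exceeding cutoffs: >2: 36, >5: 0, >10: 0

== Co-twin matching ==
matched 8 of 8 pairs; chance expectation 0.533333; P(K >= observed) = 4.93334e-07
```

Reading: the thresholds derived from the 38 simulated DZ pairs are close
to half of the MZ-scale background; the EPI compartment has by far the
lowest within-pair correlation (it carries the injected class
divergence); housekeeping transcripts sit near ratio 1 while the
EPI-program gene *Nanog* is strongly imbalanced; and with the default
within-pair expression correlation of 0.9 the dendrogram recovers every
co-twin pair, far above the chance expectation of 0.53 pairs.

Individual stages are available as subcommands
(`simulate`, `concordance`, `ratios`, `match`, `trace`, `stats`,
`validate-geo`); run `twinconcord --help` for the full interface.
`validate-geo` compares locally stored deposited series-matrix files
against the published reference values under every linkage and scale
mode; it never accesses the network.

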