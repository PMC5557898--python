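# Methods

This note documents the models, conventions and design choices behind
`twinconcord`, in the spirit of a statistical methods appendix.

## Lineage concordance

Each blastocyst is summarized by its TE / EPI / pEnd cell counts
(CDX2⁺, NANOG⁺, SOX17⁺ compartments). Background variation between
unrelated embryos is estimated from dizygotic (DZ) pairs as the median
per-lineage absolute within-pair difference; medians of even-sized
cohorts average the two central order statistics. Because MZ twin
blastocysts carry roughly half the cells of intact embryos, the
concordance threshold is **half** the DZ median, kept unrounded (an odd
median gives a half-integer threshold). Classification is conjunctive:
a pair is *concordant* iff every lineage difference is at most its
threshold, *discordant* iff any lineage strictly exceeds it; boundary
equality counts as concordant. All operations are invariant to swapping
the two members of a pair, which carry no intrinsic order; the
per-lineage Pearson correlation is therefore computed on the doubled
set {(a,b)} ∪ {(b,a)} (a symmetrization decision — the ordering used for
published scatter plots of this kind is typically unstated). Error bars
on class proportions are the binomial SD √(p(1−p)/n); condition groups
with fewer than 5 pairs are flagged low-n rather than dropped.

Note the halving rule's intent is a scale correction, not a coverage
statement: only ~26% of a half-normal distribution lies below half its
median, so DZ pairs re-classified against halved thresholds are mostly
"discordant" by construction. The sanity test therefore checks the
definitional property (about half the DZ pairs fall within the
*unhalved* median).

## Unordered-pair ratio statistics

For a gene with expression (e_a, e_b) in a pair, the ratio is
(max+ε)/(min+ε) with ε = 0 by default (microarray-normalized input is
strictly positive; ε is available for count-like data). Per-gene
summaries across pairs use the sample SD (n−1) and CV = SD/mean.
Ranked-list export orders by the key descending with deterministic
tie-breaks (mean ratio descending, then symbol ascending). Exceedance
counts use strict inequality (ratio > cutoff), which makes them
monotone non-increasing in the cutoff.

Group differential expression uses the pooled-variance two-sample
t-test by default (classic microarray practice; Welch is available),
with raw p < α as the headline count and optional Benjamini–Hochberg
q-values. Genes constant in both groups are flagged and assigned p = 1.
Note that on twin cohorts the within-pair correlation violates the
independence assumption, so the raw significant fraction can exceed α
even without true group differences. Group similarity is the squared
Pearson correlation of the per-gene group-mean profiles, computed on
the values as stored; the published definition of such R² values is
usually not explicit, so both linear and log2 inputs are supported and
the deposited-data validation reports both.

Sex is called from Xist (expressed from the inactive X of females) by
an exact 1-D two-means split (scan of all sorted splits minimizing
within-cluster SSE — deterministic, scale-invariant); the low cluster
is male. Constant input is degenerate and yields a single class with a
warning.

## Co-twin matching and its null

Samples are clustered on correlation distance (1 − Pearson r over
genes) with average linkage by default (complete and single are
selectable; the linkage behind published constellation maps of this
kind is typically unstated, so the deposited-data validation runs all
three). Agglomeration delegates to scipy; on continuous expression
data merge ties have measure zero, and an O(n³) naive UPGMA oracle
confirms the merge sequence in the tests.

A pair counts as *matched* (first-order connection) when its two
members merge as sibling leaves. The interpretive null is the uniform
random perfect matching of the 2n samples into n unordered pairs:
P(K=k) = C(n,k)·D(n−k)/(2n−1)!! where D(m) = Σ_j (−1)^j C(m,j)(2(m−j)−1)!!
counts matchings avoiding all original pairs; E[K] = n/(2n−1).

An important calibration subtlety: the sibling-leaf count is **not**
exactly distributed as this null even for signal-free data, because a
dendrogram is not a full pairing — on average only ~¾ of leaves receive
a leaf-leaf merge, making the sibling count conservative (its mean sits
below n/(2n−1)·n... per-pair below 1/(2n−1)). Any full perfect matching
produced by a sample-symmetric rule *is* exactly uniform under
exchangeable samples (the symmetric group acts transitively on
matchings). The matcher therefore offers three definitions: `sibling`
(default, the first-order-connection reading), `mnn` (mutual nearest
neighbours) and `greedy` (iteratively pair the two closest unpaired
samples — a full matching, used for null-calibration tests). Chance
comparisons of the sibling count are conservative and are reported as
such.

## Exact tests

**Fisher's exact test** (2×2) computes the conditional hypergeometric
point probabilities with exact integer arithmetic (`math.comb`
numerators over a common binomial denominator); the two-sided p sums
all tables with the observed margins whose probability does not exceed
the observed table's (probability ties are exact integer comparisons,
so no floating-point tie tolerance is needed). A doubling-one-tail
variant is available since the convention behind any given published
value can differ. Degenerate tables (zero row/column margin) return
p = 1 with a flag.

**Wilcoxon signed-rank** drops zero differences, averages tied ranks,
and enumerates the exact conditional sign-flip distribution by dynamic
programming for up to 25 informative pairs (doubled ranks keep
half-integer tie-averaged ranks integral); beyond that, a normal
approximation with tie and continuity corrections is used. Because
twin members are unordered, the sign of each difference depends on the
input ordering; the package takes the ordering as given and reports an
ordering-sensitivity analysis (p-value range over 200 random
re-orderings). Ordering members by outcome first would make all
differences one-signed and degenerate the test, so it is deliberately
not done. Stages are encoded ordinally: one-cell=1, two-cell=2,
four-cell=3, eight-cell=4, morula=5, blastocyst=6.

Percentages round half-up (174/192 → 90.6), matching how published
rates are printed.

## Synthetic-study generator

The generator emulates the study conditions the analyses assume; one
RNG stream per component (labels, lineage, expression, tracing,
outcomes), all derived from the master seed, so components are
independently reproducible and a fixed seed fixes the full study.

**Lineage counts.** MZ member A draws its total from a normal
truncated at zero (mean 32.1, SD 15.0 cells — half-embryo scale) and
splits it by a multinomial on the expected lineage shares; member B
repeats member A's counts with small per-lineage integer jitter
(SD 2.5/0.7/0.7 cells for TE/EPI/pEnd), modelling the shared zygote
origin of the pair — fully independent member draws would bury the
concordance signal under between-embryo variation and no threshold
could separate the classes. A latent fraction p_discordant = 0.64 of
pairs is discordant: one member's EPI count is shrunk to a fraction
(default 0.2) of its value, with the reduction floored at 3 cells so
the EPI difference exceeds the 2-cell background threshold with
probability > 0.9. Divergence can additionally be applied to TE/pEnd
via config. DZ pairs are random pairings of independent intact-embryo
draws (mean 70.8, SD 13.6 cells). The lineage shares (0.60, 0.25,
0.15) are an assumption — a plausible allocation for an expanded mouse
blastocyst — not a reported value.

**Expression.** log2 expression of gene g in sample s is
μ_g + s_g(√ρ·u_{g,pair} + √(1−ρ)·v_{g,s}) plus sex and divergence
terms, with ρ = pair_corr (default 0.9) and s_g = noise_sd (default
1.0 log2 units), scaled by 0.1 for the 7-gene housekeeping panel
(Actb, Eef1e1, Gapdh, H2afz, Hprt, Ppia, Ubc). EPI-program genes
(Nanog, Bmp4, Bmp8b, Dazl, Prdm14, ...) receive a log2 downshift
(mean 1.5) in one member of each discordant pair. Xist separates
female pairs (log2 9) from male (log2 3); co-twins share sex
(P(female) = 0.25, emulating a male-skewed cohort). Output is 2^x,
hence strictly positive; 26,597 genes by default. With noise_sd = 0
and divergence off, members are identical and all pair ratios are
exactly 1.

**Tracing.** Total EPI per labeled embryo is truncated-normal
(mean 15, SD 5); the dominant fraction comes from a two-component
mixture: balanced 0.5+0.5·Beta(1,6), skewed 1−0.5·Beta(1,3), weights
0.35/0.65 — chosen so that the balanced (≤0.6) and skewed (>0.8)
observed bands occur at roughly the reported relative frequencies,
with the gap an explicit intermediate class. Zero-EPI embryos are
excluded from fractions and reported on a QC line.

**Outcomes.** Pair outcomes are drawn exchangeably from
{both blastocyst, one, neither} with probabilities (pr, 2p(1−r),
1−2p+pr) where p = 0.85 is the marginal blastocyst rate and r = 0.92
the conditional co-blastocyst rate; arrested members draw a
pre-blastocyst stage from a configurable categorical (defaults favour
two-/four-cell arrest). The symmetric construction makes member labels
exchangeable by design.

**What the generator does not emulate.** Probe-level microarray
artifacts, batch effects, non-Gaussian expression tails, cell-count
measurement error from manual counting, and any uterine biology.
Passing tests demonstrate the pipeline's correctness and calibration
under this model, not agreement with any particular deposited dataset
(that is what the optional `validate-geo` pathway is for).

## Problem sizes and test design

Tests use compact studies (8–20 pairs, 120–400 genes) where the
property under test allows, and larger sizes where sampling error must
be small: 300–2000 pairs for rate recovery (3 binomial SE bands),
500 replicate simulations for the match-count calibration (χ²
goodness of fit with sparse-bin pooling, α = 0.01), 2000 replicates
for test-size checks, and the full ≤20-margin table sweep for the
Fisher oracle comparison. Oracles are independent of the code paths
they check: full enumeration for Fisher and the matching null,
2^n sign-flip enumeration for the signed-rank test, and a naive O(n³)
agglomeration for the clustering.

## Known limitations

- The sibling-leaf match count is conservative against the uniform
  matching null (see above); p-values reported for it understate
  significance slightly.
- The exact signed-rank enumeration conditions on the observed
  tie pattern, which is the standard convention but differs from
  unconditional treatments of ties.
- The deposited-data validation compares point values at fixed
  tolerances and discloses per-mode agreement; it cannot adjudicate
  which processing mode produced a published value when none matches.
- Duplicate gene symbols in input matrices are resolved by keeping the
  maximum-variance row (or averaging, by option); any such aggregation
  is logged.
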