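# Methods

## The two null hypotheses

For a geneset *g* tested against a survival endpoint there are two
distinct claims a screen can make, and they need different nulls:

* **First (self-contained) null** — *g* carries no association with
  survival.  Tested per geneset: patients are stratified by unsupervised
  clustering on *g*'s probes and the two groups compared with a log-rank
  test, giving p₁.
* **Second (competitive) null** — *g* is no more associated with
  survival than random sets of unrelated genes.  Tested by running the
  identical stratify-and-test pipeline on *B* random genesets and
  locating p₁ within that empirical distribution, giving
  p₂ = #{p₁′ ≤ p₁}/B (ties counted inclusively).

If the empirical distribution were Uniform(0,1), p₂ ≈ p₁ and the second
test would be redundant.  Bulk tumour transcriptomes violate this:
dominant survival-correlated expression programs are visible to *any*
geneset, so random genesets yield an excess of small p₁.  A theme-level
biological claim therefore requires the second test.

## First-test pipeline

**Preprocessing.** Probes measured in fewer than a configurable fraction
of samples are dropped (`min_complete_fraction`; 0.60 suits multi-batch
cDNA designs with partially disjoint probe sets, 0.80 single-design
arrays — "at least" is inclusive, so exactly 60% survives a 0.60
threshold).  Replicate rows sharing a probe id are collapsed to their
per-sample mean over non-missing values.  Each probe is then
median-centred on its non-missing entries (correcting per-probe
reference-channel bias).  Order is fixed as filter → average → centre so
centring acts on the final rows; the composite is idempotent.

**Geneset → probes.** The union of the member genes' mapped probes is
intersected with the matrix, preserving matrix row order.  Size filters
are strict on both ends: < 5 or > 1,000 genes, or < 5 or > 2,500 mapped
probes, exclude the set (as a value carrying the reason, not an error).

**Distance.** Sample-pair Pearson correlation over the geneset's probes,
pairwise-complete in the presence of missing values; d = 1 − ρ ∈ [0, 2].
A pair with fewer than 3 complete probe pairs, or zero variance over
them, has no defined correlation; any such pair discards the geneset
(`undefined_distance`) — clustering needs the full matrix.

**Clustering and split.** UPGMA (scipy average linkage) on the condensed
distances; the two subtrees of the final merge define the groups,
extracted by traversing the linkage matrix so the "first bifurcation" is
exact.  Label 1 is the subtree containing the first sample, a pure
determinism convention.  Ties inside the agglomeration follow scipy's
deterministic ordering.

**Evenness discard.** If the smaller cluster holds < 10% of the
clustered samples (strictly), the geneset is discarded
(`uneven_clusters`): the log-rank test is unreliable when one group is
tiny, and such splits are usually outlier-driven.

**Log-rank.** At each distinct event time the observed minus expected
event count in group 1 accumulates with the hypergeometric variance
d·(n₁/n)·(1 − n₁/n)·(n − d)/(n − 1); the statistic (ΣO−E)²/ΣV is
referred to χ²₁ (asymptotic p-value; the evenness discard guards the
small-group regime).  No events at all gives statistic 0, p = 1 with a
warning.  The implementation is vectorised and matches lifelines to
1e-10 on random datasets in the test suite.

## Empirical null

Random genesets are drawn uniformly without replacement from the
collection's **gene universe** (the genes annotated in that collection —
sampling from a wider or narrower pool biases the null), with sizes
drawn from the multiset of the *tested* (post-filter) sets' gene counts,
so the null inherits the collection's size profile ("pooled" mode).  A
single-signature comparison uses "exact" mode: every draw has the
signature's size.  Draws that the pipeline discards are counted and
redrawn, so the null holds exactly *B* assessed random genesets; a
window discard rate above 99% aborts with a diagnostic.  All sampling
consumes one seeded stream, which makes nulls at different *B* nested
prefixes of one another — the stability analysis is exact, and every run
is bit-reproducible from its seed.

p₂ = b/B with no pseudo-count (the worked-example convention: 4 of
1,000 → 0.004); a (b+1)/(B+1) variant is available behind a flag for
workflows that cannot tolerate p₂ = 0.  FDR control is
Benjamini–Hochberg step-up on each p-vector over the ok genesets;
adjusted values are order-aligned, ≥ their p, and monotone in p-rank.

**Defaults.** α = 0.01, FDR threshold 0.30 (screening studies benefit
from permissive FDR; both configurable), B = 100,000 — the stability
analysis shows p₂ concordance between 50k/100k/200k nulls; desk-scale
runs in the tests use B in the hundreds to low thousands, which the
stability table quantifies (max |Δp₂| shrinks as ~1/√B).

## Diagnostics

* **Uniformity** — one-sample KS against Uniform(0,1); histogram density
  over [0,1] at bandwidth 0.01; QQ table of sorted p₁ vs i/(B+1), also
  on −log₁₀ scale for the tail.
* **Size effect** — random genesets of sizes (20, 75, 150, 300, 500) ×
  reps through the first test (sizes exceeding the universe are skipped
  with a warning); output carries −log₁₀ p₁ for plotting significance
  against size.
* **Stability** — p₂ for each tested geneset under nested-prefix nulls
  of increasing B, reported as Pearson r of −log₁₀ p₂ (p₂ clamped to
  1/(2B) before the log) and max |Δp₂| against the reference B.

## Synthetic data

The generator targets the method's assumptions, not any particular
cohort.  Expression entries are i.i.d. standard normal (log-ratio
scale); survival is exponential with rate λ_e and independent
exponential censoring λ_c, so the event fraction is λ_e/(λ_e+λ_c).
Missing entries and replicate probe rows (same probe id, independent
noise) are injected at configurable rates.  Defaults — 2,000 genes, 60
samples, 10% missing, 5% replicates, λ_e = 1.0, λ_c = 0.5 (event
fraction ⅔) — model the 50–70-patient cDNA-style cohorts this class of
screen is applied to.

The **confounded** regime adds a balanced latent group *z*: a fraction
*f* of genes is shifted by ±δ along *z* (random sign per gene) and the
event hazard is multiplied by HR for *z* = 1.  This is the global
prognostic axis: with f = 0.5, δ = 1.5, HR = 4, over 95% of random
genesets score p₁ < 0.05 while the KS test overwhelmingly rejects
uniformity; with δ = 0 and HR > 1 (survival signal invisible in
expression) the p₁ distribution stays uniform — clustering cannot see a
survival-only effect.

An optional **planted theme** geneset receives an extra shift δ_t along
*z* on its own genes.  The recovery experiment uses a mild axis
(f = 0.2, δ = 0.2, HR = 4) and a 30-gene theme at δ_t = 1.5.  Two
identifiability constraints drove these choices, and they are informative
about real data:

* If the global axis is strongly expression-visible (δ ≳ 1), random
  genesets recover *z* too; the theme's best achievable p₁ is the
  *z*-partition's p₁, which random near-*z* partitions occasionally beat
  by chance, so no theme aligned with a strong visible axis can
  dominate the competitive ranking.  This is a property of the method,
  not a defect: such a theme genuinely is no better than random genes.
* If δ_t is very large (≈ 3), single theme genes leaking into random
  draws (the universe contains the theme genes) make those draws
  prognostic and inflate the null's tail.  δ_t = 1.5 is recoverable
  jointly by 30 genes but negligible through one or two leaked genes.

What the simulations do **not** emulate: two-channel array physics,
print-batch structure, correlated co-expression modules unrelated to
survival, non-exponential hazards, informative censoring, and real
annotation topology (nested GO terms, overlapping pathways).  Passing
tests show the machinery is correct and calibrated under the stated
generative model; they do not certify behaviour under every real-data
pathology.

## Numerical conventions and degenerate inputs

Missing tokens on disk: empty cell or `NA`; written as `NA`.  All-missing
probe rows stay uncentred (warning).  Correlations are clipped to
[−1, 1] against float error.  Log-rank with zero total variance returns
(0, 1).  −log₁₀ transforms clamp p at the smallest positive double.
Seeds: a single `numpy.random.default_rng` stream per null/scan;
everything re-runs bit-identically from (config, seed).

## Problem sizes used in the shipped tests

Unit tests run on 400–600-gene, 40–60-sample simulations with nulls of
50–300 draws.  The acceptance-style tests use 2,000 genes × 60 samples
with B = 2,000 nulls and 2,000 Monte-Carlo replicates for calibration,
B = 1,000 × 40 seeds for uniformity, B = 100,000 for the uniform-null
equivalence check, and 20 end-to-end replicates for planted-theme
recovery — sizes at which the whole suite completes in about a minute
on one CPU while keeping binomial error bands tight enough to be
meaningful.
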