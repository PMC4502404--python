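# Methods

This note documents the statistical procedures implemented in
`crossreg`, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the numerical choices that matter
for reproducing results.

## Moderated linear models (`crossreg.linmod`)

Both differential expression and differential methylation use the same
machinery: per feature, an ordinary least-squares fit of the response on
a cell-means design for a categorical factor (two species, or the six
species × cell-type groups of the combined-tissue model), with the
tested effect expressed as a contrast between two levels. The contrast
convention throughout is chimpanzee − human: positive log₂ fold changes
and positive Δβ mean higher values in chimpanzee.

Residual variances are moderated by empirical Bayes: a scaled
inverse-χ² prior (df d₀, scale s₀²) is fitted to the observed variances
by moment matching on log s² — the mean and variance of log s² are
closed-form in digamma/trigamma functions of the residual df and d₀,
and the trigamma equation is inverted by Newton iteration. Posterior
variances `(d₀·s₀² + df·s²)/(d₀ + df)` give a t statistic with
`df + d₀` degrees of freedom. This reproduces the reference
Bioconductor implementation to machine precision on shared fixtures
(see `tests/test_linmod.py`), with one deliberate difference: the
estimated prior df is capped at 50, so that near-constant variance
distributions (where the moment estimator diverges to infinity) keep a
finite, proper reference distribution. Setting `prior_df=0` disables
moderation and recovers the classical equal-variance t-test exactly.

Features with zero residual variance and zero effect are reported as
t = 0, p = 1 (no evidence) rather than NaN.

## Expression pipeline (`crossreg.expression`)

Fixed order: blacklist removal → CPM → expression filter → cyclic
MA normalisation (within species) → species-specific RPKM → moderated
DE test → BH-FDR. Defaults:

| parameter | default | meaning |
|---|---|---|
| `min_samples` | 4 | samples of one species that must pass the expression filter |
| `log2_cpm_min` | 1.0 | strict log₂ CPM cutoff for "expressed" |
| `fdr_threshold` | 0.01 | strict BH q cutoff for the DE flag |
| `LOG_OFFSET` | 0.25 | pseudo-count before log₂ of CPM/RPKM, avoids log 0 |
| `df` (MA smoother) | 8 | spline degrees of freedom of the MA detrend |

RPKM uses the gene length of the sample's own species, because
orthologous genes are not constrained to be the same length in both
genomes; comparing CPM across species would otherwise fold length
divergence into expression differences.

**MA normalisation.** The pairwise cyclic normalisation fits a smooth
trend of M = x_i − x_j on A = (x_i + x_j)/2 within each sample group
and splits it symmetrically between the pair. The smoother is a cubic
truncated-power regression spline (quantile-spaced knots, least
squares) rather than a local-regression (lowess) smoother. The choice
is deliberate: a least-squares basis fit is an orthogonal projection,
so detrending a sample pair is exactly idempotent — re-running the
normalisation on its own output changes nothing — whereas iterating a
lowess smoother is not a contraction and drifts slowly at the support
edges. The practical effect on the trend estimate is negligible at
these sample sizes; the fixed-point property is what the spline buys.

**BH-FDR** is implemented directly (step-up, `q_(i) = min_{j≥i}
p_(j)·n/j`, capped at 1, mapped back to input order) and checked in the
tests against both an O(n²) brute force and statsmodels.

## Probe orthology filtering (`crossreg.probes`)

A probe is retained iff (in this order, first failure reported):
unique mapping (exactly 1 hit) → at most 2 mismatches → no mismatch in
the 3′ 5 bp closest to the CpG (for a 50-mer: offsets ≤ 45) → no human
SNP with MAF ≥ 0.05 within the CpG-proximal 5 bp → no chimpanzee SNP
with MAF ≥ 0.15 there → detection p ≤ 0.01 in **every** sample.

Two documented interpretations:

* *Detection scope.* Detection failures are removed globally (a probe
  failing in any sample leaves the shared probe universe), so all
  downstream analyses see one common probe set.
* *"First 45 bp".* Encoded as offset ≤ probe_length − 5, so non-50-mer
  probes behave consistently with the 50-bp case.

The rule order is cheap-to-expensive and makes the single reported
reason deterministic; reason counts therefore partition the input.

## Methylation (`crossreg.methylation`)

Quantile normalisation replaces each sample's sorted values with the
rank-wise mean across samples (ties share the mean of their rank
range); autosomes are normalised across all samples, X-chromosome
probes within each sex separately. The two Infinium probe chemistries
are harmonised by a monotone quantile map of each sample's type-II
values onto that sample's type-I empirical distribution; this is a
simplified stand-in for a full beta-mixture calibration — it matches
the distributions without modelling the three methylation states
explicitly, which is sufficient for the rank-based analyses downstream.
The type-II map is applied to autosomal data only.

DM testing fits the moderated model on β directly (an M-value mode,
logit β with a 0.01 clamp, is available for heteroscedasticity-sensitive
uses); Δβ is always computed from group means of the final normalised β
matrix. Probes pass the effect filter when flagged at FDR 1% **and**
|Δβ| ≥ 0.1 (boundary included).

DMR calling is greedy left-to-right over coordinate-sorted filtered
probes: extend the current run while the next probe is on the same
chromosome, strictly less than 1 kb from the previous **member probe**
(gap measured probe-to-probe, not region span), and changes in the same
direction; emit runs of ≥ 2 probes. The greedy caller is proven
equivalent to an exhaustive connected-components oracle on randomized
configurations in the tests. DMRs are kept only when their member
probes annotate exactly one gene, and classified `promoter` (all
features in {TSS1500, TSS200, 5UTR, 1stExon}), `genic` (all in
{Body, 3UTR}) or `mixed`.

## ChIP at orthologous TSSs (`crossreg.chip`)

* Windows: 200 bp; pass iff ≥ 80% of bases are uniquely mappable
  (20-bp k-mer flags) in **both** species. The boundary (exactly
  160/200) passes.
* Peaks: excluded when ≥ 80% of bases fail to align to the other
  genome (exactly 80/100 is excluded). Bases outside the ortholog map
  count as unaligned; a peak entirely outside the map is treated as
  fully unaligned with a warning.
* Two-step retention: `shared` iff stringent in one species and relaxed
  in the other (either orientation); `X_only` iff stringent in X with
  no relaxed call in the other; `absent` otherwise. H3K27ac uses
  FDR < 5% / < 15%; H3K27me3 uses domain score ≥ 20 / any enriched
  call. A species "has a call" for a region when any retained peak
  overlaps it by ≥ 1 bp.
* Enrichment score: `(RPKM_mark − RPKM_input) / (genome-mean mark −
  genome-mean input)` at TSS ± 2000 bp (half-open). The genome-wide
  means are taken over the scored window set. A gene is enriched when
  its mean score across individuals is strictly > 1; thresholds
  {1, 2, 5, 10} are supported and enriched sets shrink monotonically by
  construction.
* Cross-species overlap uses a Pearson χ² with 1 df and no continuity
  correction (counts are large in intended use); a warning is attached
  when an expected cell is below 1.

One consequence of the score's definition worth knowing: when the two
channels are exchangeable (no enrichment anywhere), every window's RPKM
sits at the window-set average, so scores concentrate around **1**, not
0, and roughly half the genes exceed the threshold. The score measures
excess relative to the average window, and is only meaningful when real
enrichment structure gives the denominator signal; the generator's
`chip_fold = 1` setting exercises exactly this degenerate regime.

## Permutation category test (`crossreg.enrichment`)

The null resamples gene labels: `reps` gene sets of the category's
testable size are drawn uniformly without replacement from the tested
universe (random-key ranking, chunked to bound memory), and the
category's DE fraction is compared with the null fractions.
`p = (1 + #{null ≥ observed}) / (reps + 1)` — never exactly zero — with
a two-sided option doubling the smaller tail; the 95% band is the
2.5/97.5 null percentile interval (reported only when reps ≥ 1000).
Under a uniform null this p agrees with the exact hypergeometric tail
(verified within Monte-Carlo error in the tests). Default
reps = 100,000.

## Structure diagnostics (`crossreg.structure`)

PCA centres features (no unit-variance scaling by default, matching
expression-PCA practice; a flag exists), decomposes by SVD, and fixes
each component's sign by making its largest-magnitude loading positive.
PC–covariate association is a one-way F-test. Distances are Manhattan
by default (Euclidean available — both appear in comparative practice
and the package surfaces the choice). Neighbor joining follows the
standard Q-criterion agglomeration with deterministic tie-breaking by
the lexicographically lowest pair of clade labels; negative branch
lengths are reported as computed. The within-group distance
homogeneity test is a two-sided Mann–Whitney U on the two groups'
pairwise-distance multisets — exact by enumeration of group assignments
when the count is feasible (≤ 200,000), asymptotic otherwise; the test
ignores the dependence between pairwise distances sharing a sample, so
its p-values are heuristic, which is why the statistic is reported
alongside. β states: hypo β ≤ 0.2, hemi 0.2 < β < 0.8, hyper β ≥ 0.8
(strict inequalities at 0.2, inclusive at 0.8).

## Synthetic data (`crossreg.simulate`)

The generator's defaults describe the emulated study design: 2 species
× 7 iPSC lines, 12,171 expressed orthologous genes with a 37.9% DE
fraction, 335,307 retained probes with 3,529 planted DM regions, 26,115
orthologous TSSs with 3 ChIP individuals per species. Where the study
reports no value, the defaults are fixed choices:

| parameter | default | rationale |
|---|---|---|
| `lfc_sd` | 0.8 | most true fold changes below 2× — small-magnitude DE dominates |
| `nb_dispersion` | 0.05 | typical for technical-replicate-quality RNA-seq in clonal lines |
| `mean_log_expression` | 5.0 | log₂ CPM centre of expressed genes |
| `beta_precision` | 30 | β sd ≈ 0.09 at β = 0.5, array-like |
| `dm_delta_beta` | 0.2 | mid-range planted effect; tests override per scenario |
| `probe_mismatch_rate` / `snp_rate` | 0.3 / 0.05 | both filter branches exercised |
| `chip_fold` / `window_depth` | 5 / 50 | clearly detectable but not trivial enrichment |
| library-size sd | 0.2 (log) | forces non-trivial CPM normalisation |
| probe spacing | 60% gaps < 1 kb | both branches of the DMR gap rule exercised |

Each `simulate_*` call derives a child random stream from
`(seed, table-id)`, so outputs are byte-identical per seed and adding a
table never perturbs another. Planted DM regions are placed at most one
per natural < 1-kb probe cluster, so their boundaries are recoverable
exactly; region runs satisfy the DMR definition (≥ 2 probes, gaps
< 1 kb, one direction) by construction. Alignment-record truth flags
come from a second, independent transcription of the retention rules,
kept deliberately separate from `probes.classify_probe` so each checks
the other.

What the generator does **not** emulate: GC-content and mappability
biases in counts, correlated methylation beyond the planted regions,
probe cross-reactivity, batch effects (notably, a real cross-species
ChIP comparison confounds lab batch with species), cell-composition
heterogeneity, and raw reads or array intensities (inputs start at
counts/β). Passing tests therefore demonstrate the correctness of the
statistical machinery under its stated model, not robustness to those
real-data artefacts.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the pipeline at reduced
but non-trivial sizes chosen as the package's own defaults for fast,
stable checks: DE error control at 5,000 genes (null) and 2,000 genes
(planted effects); DM recovery at 60,000 probes with 600 planted
regions; ChIP recovery at 5,000 TSSs; permutation calibration at
20,000 permutations against the exact hypergeometric tail. The
full-scale defaults (12,171 genes / 335,307 probes / 26,115 TSSs) run
in seconds to minutes and are exercised by the examples where
instructive.

## Known limitations

* The combined-tissue model is fitted as fixed effects only; the
  duplicate-correlation (within-individual) adjustment of the reference
  workflow is not implemented, which overstates the effective sample
  size when individuals contribute multiple tissues.
* The type-II adjustment is a distribution-matching quantile map, not a
  three-state beta-mixture calibration.
* Voom-style precision weights are not applied; the moderated model is
  fitted unweighted on log₂(RPKM + 0.25).
* The Mann–Whitney homogeneity test treats pairwise distances as
  exchangeable units, ignoring their shared-sample dependence.
* χ² overlap tests assume large counts; the package warns rather than
  switching to an exact test when cells are small.
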