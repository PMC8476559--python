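# Methods

This note documents the models, conventions and numerical choices behind
`cnvassoc`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Copy-number calling

**Raw ratio.** For each sample × gene well the assay yields four peaks:
target genomic `g_T`, target competitor `c_T`, control-gene genomic
`g_I`, control-gene competitor `c_I`.  The raw relative copy number is
`(g_T/c_T) / (g_I/c_I)`.  When an assay carries two control-gene peak
pairs, their ratios are combined by the arithmetic mean — a symmetric
choice that is robust to one weak peak.  Failed assays propagate as
explicit missing values, never as zero (a zero is a biological null
genotype).

**Standardization.** Raw ratios for each gene are divided by
`median / expected_median_cn`, anchoring the cohort's median individual
at sCN = 2 (autosomes) or 1 (hemizygous males).  This assumes the cohort
median individual carries the modal diploid copy number; a cohort in
which most individuals are copy-variant would be mis-anchored, which is
inherent to median standardization rather than to this implementation.
The median is computed over the pooled cohort (cases + controls) by
default: separate per-group medians would absorb a genuine case-control
copy-number shift into the standardization.  A per-group option exists
for sensitivity analysis.  Even-length medians are the midpoint of the
two central order statistics.  X-linked genes are standardized per sex
stratum, each against its own median.

**Digitization.** `dCN = floor(sCN + 0.5)`, i.e. half-open bins with
boundaries at x.5 up to the last bin [5.5, 6.5).  Values ≥ 6.5 are
clamped to 6 with a warning rather than erroring: the analysis pools
high-copy categories anyway, and a hard error on a single outlying
sample would be disproportionate.

**QC.** A sample is retained iff its DNA-quantity flag passes *and* it
has a passing call for every required gene (the seven-assay multiplex by
default).  Exclusions are tallied in that order — DNA first, then assay
failure — mirroring standard cohort accounting (e.g. 368 accrued − 5
low-DNA − 36 assay failures = 327 analyzed).

**Accuracy vs noise.**  With independent log-normal noise of CV c on
each of the four peaks, the raw ratio has CV ≈ 2c.  At the default
c = 0.05 (ratio CV ≈ 0.10) the half-unit bins keep CN ≤ 1 calls
essentially error-free, CN = 2 at ≈ 98.7% accuracy, and degrade for
higher copy numbers (≈ 91% at CN = 3), since the bin width is constant
while multiplicative noise grows with the signal.  At c = 0.02 all
strata up to CN = 4 are called with ≥ 99% accuracy.  The tests assert
exactly these attainable levels.

## Association statistics

**Fisher exact, 2×k.**  The two-sided p-value is the total probability,
under the multivariate hypergeometric null with fixed margins, of all
tables whose point probability is ≤ the observed one (Freeman-Halton; at
k = 2 this is the standard two-sided Fisher test).  Exact computation
enumerates all feasible first rows via a vectorized column sweep and is
refused beyond 2×10⁶ candidate rows, where the `auto` method switches to
Monte Carlo: B tables drawn from the null by multivariate hypergeometric
sampling, p estimated with the add-one estimator and reported with its
standard error.  Probability ties are compared on the log scale with a
tolerance of 10⁻¹⁰ (relative to |log p|): wide enough for float error in
summed `gammaln` terms, narrow enough never to merge genuinely distinct
hypergeometric probabilities.

**Chi-squared.**  Pearson statistic with df = k − 1, no continuity
correction by default (Yates optional for 2×2).  Expected counts below 5
raise a recorded warning but never silently switch the test — test
choice is an explicit analysis decision.

**A note on printed-value conventions.**  In the reference study's
printed table, the 2×2 p-values match Fisher's exact test while the
multi-category p-values match the Pearson chi-squared, regardless of
which test marker each row carries.  The regression suite therefore
checks each printed value against the test that reproduces it, and
`regress_published` always reports both tests side by side.

**Odds ratios.**  `OR = (case_exposed · control_unexposed) /
(case_unexposed · control_exposed)`.  With a zero cell the OR is
unbounded; the default policy substitutes 1 for the empty cell and flags
the result as a *lower bound* (this convention reproduces the published
bound 18.5355 = 17·338/310 exactly), suppressing the CI.  The
Haldane-Anscombe +0.5 correction and a hard error are available
alternatives.  CIs are Woolf (normal approximation on log OR).

**Multiplicity.**  Bonferroni with a *declared* family size m
(default 11: nine per-gene tables plus two binary contrasts), capped at
1.  The published corrected p-values are not consistent with m = 11
applied to the published raw values (0.0331 → 0.3641, not the printed
0.3938); the package does not chase those four numbers and the
acceptance suite documents the inconsistency instead.

**Wilcoxon rank-sum** on continuous sCN uses the exact null distribution
for small untied samples and the tie-corrected normal approximation
otherwise.  **Clinical associations** (binary genotype status vs binary
clinical flags) are per-variable 2×2 Fisher tests with an optional
declared-family Bonferroni; constant variables are skipped with a
warning.

## Hardy-Weinberg testing for copy-number data

Only diploid totals k are observed.  The haplotype copy-class
frequencies q (classes 0..A_max) are estimated by EM:

- E-step: an individual with total k is assigned to unordered haplotype
  pairs (a, k−a) with posterior ∝ q_a·q_{k−a} (×2 when a ≠ k−a);
- M-step: q ← mean posterior haplotype counts / 2n.

The implementation runs over ordered pairs, which is algebraically
identical and vectorizes cleanly.  The multinomial log-likelihood of the
self-convolved q is recorded each iteration and asserted non-decreasing.
Initialization spreads each individual's total uniformly over its
feasible haplotype classes plus a +0.5 smoothing term, keeping the
starting point strictly positive so EM never truncates support; a
uniform init is available and the init is recorded.  Default
A_max = ceil(k_max/2), the smallest haplotype space consistent with the
data — larger spaces add parameters the totals cannot identify and
produce trivially saturated fits.  Convergence: max|Δq| < 10⁻⁹ (10⁻⁷ in
the bootstrap inner loop, where thousands of refits run), capped at 2000
iterations with a warning on non-convergence.

**Goodness of fit.**  Expected counts are n·(q̂ ∗ q̂) on the grid
k = 0..2·A_max.  Adjacent categories with expected < 1 are pooled from
both tails inward (the tails are where HW expectations vanish), then
χ² = Σ(O−E)²/E with df = (categories after pooling − 1) − A_max,
clamped at ≥ 1 with a saturation flag.  Because published conventions
for this df vary, a parametric bootstrap is provided: refit the EM on B
cohorts drawn from the fitted model and report
(1 + #{χ²* ≥ χ²_obs})/(B + 1).  Both tests hold their nominal 5% size
within (0.035, 0.065) over 2000 Hardy-Weinberg cohorts at n = 338
(asserted in the acceptance suite).  Exact published HWE p-values from
other software are *not* reproducible — they depend on unstated df,
pooling and allele-space conventions — and only the direction of the one
strong published rejection (C4B controls) is asserted.

## ddPCR quantification

Template molecules partition into droplets Poisson(λ), λ = CN·c0 for the
target and 2·c0 for the diploid reference.  Concentration from counts:
λ̂ = −ln(1 − k/n); the 95% CI propagates a Wilson interval for k/n
through the same transform (well-behaved at k near 0).  k = n is a
saturation error instructing dilution.  CN = ploidy·λ̂_target/λ̂_ref,
scale-invariant in c0.

**Gating.**  Cross-reactive homolog template produces a genuine
mid-amplitude cluster between negatives and true positives.  The default
"valley" policy histograms amplitudes (256 bins), smooths, finds
well-separated modes (relative floor 2% of peak density, absolute floor
1.5 counts/bin, neighbours merged unless the density between them drops
below half the smaller mode) and thresholds at the density minimum
between the two *uppermost* modes, excluding the cross cluster whenever
the true-positive cluster is present.  For a null sample the
true-positive cluster is absent and the uppermost pair would be
negative/cross; the optional `min_positive` amplitude floor — set from a
positive-control well, as thresholds are set in practice — keeps such
samples at zero positives.  Unimodal distributions fall back to a fixed
threshold with a warning.

**Concordance** between assays is ordinary least squares with R² the
squared Pearson correlation and p from the slope t-test.  The published
R² values (0.9925/0.9912) require the study's physical 16 samples and
are not targets; the simulated 16-well design (three wells per dCN 0–4
plus one) reproducibly yields R² ≥ 0.98.

## Synthetic cohorts

The generator emulates the reference study's conditions: 375 controls
and 368 accrued cases, female fraction 0.9 (the study's case group is
89% female), per-sample×gene assay failure 0.01 (≈ 7% of samples fail at
least one of seven genes, the order of the study's ≈ 10% exclusions),
low-DNA exclusion 5/368 among cases, peak-height noise CV 0.05 (the
study does not report a measurement CV; this stand-in is configurable),
and competitor spikes of 1 arbitrary unit (they cancel in
standardization).  Gene models carry per-haplotype copy-class
frequencies fitted by this package's own EM to the published control
distributions (e.g. CCL3L3 q = (0.159, 0.602, 0.239)); rare-variant
genes use direct haplotype counts, and TLR7 is X-linked with males
hemizygous.  Case genotypes are drawn retrospectively: the population
genotype distribution is re-weighted so the risk category's *odds* are
multiplied by the target OR exactly (defaults: CCL3L3-null at OR 18.5,
C4B-single-copy at OR 1.6), preserving genotype composition within
categories — appropriate for a case-control design, and it makes the
true OR known by construction.

What the generator does **not** emulate: plate/batch effects, peak
overlap or pull-up artifacts in the electropherogram, correlated assay
failures, linkage between genes (each gene is drawn independently —
notably C4A/C4B, which are physically linked in reality), or departure
from HWE in the source population.  Passing tests therefore validate
the *statistical machinery* under the stated measurement model, not the
wet-lab assay itself.

All randomness flows from one root `SeedSequence` through named
substreams per stage (sexes / genotypes / peaks / DNA flags; and in the
pipeline: cohort / Monte-Carlo Fisher / bootstrap / ddPCR), so every
output is bit-reproducible given (config, seed) and stages can be
re-run independently.

## Problem sizes in the test suite

The acceptance suite runs 2000 Hardy-Weinberg simulations at n = 338
with B = 200 bootstrap replicates each for test calibration, 500
retrospective cohorts per odds ratio for CI coverage, and 25 ddPCR wells
of 15 000 droplets for copy-number recovery — sizes at which the
binomial error of each asserted rate is several times smaller than the
asserted tolerance band.

## Known limitations

- Median standardization assumes a majority-modal cohort (above).
- The Freeman-Halton Monte Carlo p is stochastic; it is reported with
  its standard error and seeded for reproducibility.
- The EM likelihood for self-convolution models is well-behaved in
  practice but not proven unimodal for A_max > 2; the grid-search
  cross-check in the tests covers A_max = 2.
- Droplet channels are gated independently; 2-D (dual-channel) cluster
  calling is out of scope.
- No covariate adjustment or logistic regression: the design assumes
  frequency-matched controls.
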