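# Methods

`heatsol` re-implements, as a tested pipeline over synthetic data, the
statistical analysis of a proteome-wide heat-shock solubility experiment in
human cells: which proteins aggregate after a brief 44 °C shock, how fast
their aggregates dissolve during recovery, and whether the soluble remnants
of aggregating proteins are thermally stabilized.  This note documents the
models, the estimators, the tunable parameters, and the design decisions
that were genuinely open.

## Quantities and estimators

**Solubility** of a protein at recovery time *t* is the log2 ratio of its
soluble-fraction (NP-40 lysis) reporter intensity between heat-shocked and
mock-shocked samples, computed on replicate-matched channel pairs.
Summaries (the per-time-point mean, slopes) use observed replicate pairs
only; left-censored values are not imputed into ratio summaries, mirroring
the data requirement that solubility values come from at least two
quantified biological replicates.  Left-censored imputation (down-shifted
Gaussian: mean `mu_c − 1.8 sigma_c`, SD `0.3 sigma_c` per channel) is
implemented and tested for stages that need complete matrices.

**Aggregator calling.**  A protein is an aggregator when its t = 0
solubility is significantly below zero *and* below log2(2/3) ≈ −0.585
(both cut-offs strict).  Significance comes from an empirical-Bayes
moderated one-sample t-test: a scaled inverse-chi-square prior
(d0, s0²) is fitted to the observed per-protein variances by matching the
mean and variance of log s² to digamma/trigamma expressions (Newton
inversion of the trigamma function), the posterior variance
`(d0 s0² + d s²)/(d0 + d)` replaces s², and the statistic is referred to a
t distribution with d0 + d degrees of freedom (normal when d0 = ∞).  When
the observed spread of log s² does not exceed the pure chi-square
contribution, the prior is degenerate (d0 = ∞) and s0² is estimated by the
raw-scale mean of s², which is unbiased there (the log-scale
method-of-moments value would carry a chi-square bias of
`exp(digamma(d/2) − log(d/2))`, a factor ~1.78 at d = 2).  Multiple
testing uses Benjamini–Hochberg at 0.05.

**Total solubility** is log2(NP-40 / SDS) per condition; a pre-shock value
strictly below −0.6 flags a pre-existing insoluble sub-population.

**Disaggregation rate** is the ordinary-least-squares slope of mean
solubility over t ∈ {0, 1, 2, 3, 5} h, including the post-shock anchor;
at least 3 time points are required.  Feature correlations
(solubility, disorder fraction, gravy, pI, MW, secondary-structure
fractions vs slope) use Pearson when both vectors pass a Shapiro–Wilk gate
at p ≥ 0.05 and Spearman otherwise, with BH across the feature set.
Decile tags split aggregators 10/80/10 by slope rank, ties broken by
protein identifier.

**Complex coherence.**  For complexes with ≥ 5 members, ≥ 75 % of members
quantified and ≥ 2 aggregator members, coherence is the mean Euclidean
distance between the aggregator members' solubility vectors.  The null is
built from scrambled complexes: each draws an aggregator-slot count from
the empirical distribution of real per-complex counts and fills the slots
without replacement from the pooled aggregator set (10,000 scrambles).
Real per-complex distances are compared to scrambled ones with a two-sided
Wilcoxon rank-sum test (exact enumeration when both sides have n ≤ 10).
Recovery-normalized coherence divides each trajectory by its t = 0 value
(1 = still aggregated, 0 = recovered); subtraction is available as an
alternative mode.

**Thermal-stability score (2D thermal proteome profiling).**  After
per-temperature variance-stabilising normalization, every curve is the
log2 fold change against the 37.0 °C sample of its own condition and
replicate.  For a (heat, mock) curve pair, `d_T` is the per-temperature
difference; the mean of `d_T` at the two sub-shock temperatures (37.0 and
37.8 °C) is subtracted from all temperatures (absorbing aggregation that
occurred during the shock itself) and the corrected differences are
summed.  Replicates are bootstrapped: in each of 500 rounds, one heat (of
3) and one mock (of 2) replicate are drawn uniformly and independently per
temperature and per protein, and the composite pair is scored.  Within
each round, scores are standardised across proteins; each protein's 500
standardised scores are tested against zero with a one-sample t-test
(BH-adjusted across proteins — the "local FDR"), and the across-protein
z-transform of the per-protein means is the final score.  The "global FDR"
fits an empirical null Normal(0, σ0) with σ0 = MAD/0.6745, converts final
scores to two-sided tail-area p-values, and BH-adjusts them scaled by a
null proportion estimated from the central ±1 σ0 mass.  A protein is a hit
when both FDRs are < 0.01 and it was quantified at ≥ 6 temperatures; the
sign of the final score distinguishes stabilized from destabilized.

Two deliberate faithfulness choices: the 500 bootstrap draws are treated
as exchangeable samples in the t-test although they are dependent
resamples (this mirrors the procedure being re-implemented, and the
dual-FDR gate carries the error control — the null calibration test shows
the combined gate holds its level); and the "local FDR" is literally a
BH-adjusted p-value, not a density-based local false-discovery rate.
The per-round z-standardisation is across proteins within a round (the
within-protein alternative would erase between-protein effect-size
information before the final score).

**Sequence features.**  The gravy score is the *sum* of per-residue
Kyte–Doolittle hydropathy values (the length-normalised mean is an
option).  The isoelectric point solves net charge = 0 by Brent bisection
with the EMBOSS pKa set (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5,
D 3.9, E 4.1, C 8.5, Y 10.1); net charge is strictly decreasing in pH, so
the root is unique.  Molecular weight sums average residue masses plus one
water (18.0153 Da).  The Hsp70-binding-motif scan counts maximal runs of
exactly 4 or 5 consecutive hydrophobic residues ({L, I, V, F, M, W, Y})
immediately flanked on both sides by a basic residue ({K, R}); the
alphabet and flank rule are pinned behind module constants because the
verbal rule ("four or five hydrophobic residues flanked by positively
charged residues") under-determines them.

**Enrichment statistics.**  Term enrichment is an upper-tail
hypergeometric test against the quantified background with BH adjustment;
terms with zero foreground overlap are excluded from the BH family by
default (flag to include).  Category tests (localization, chromosome) are
two-sided Fisher exact tests on 2×2 tables.  Group comparisons use the
same Shapiro–Wilk gate as the correlations; box summaries use type-7
quartiles and 1.5×IQR whiskers clipped to the data.

## Synthetic-data generator

The generator emulates the *statistical structure* of the study, not its
biochemistry: two conditions (heat 44 °C / mock 37 °C) sampled at
{0, 1, 2, 3, 5} h with light (pre-existing) and heavy (newly synthesized)
SILAC fractions in TMT channels, NP-40 vs SDS lysis, and a 12-temperature
gradient (37.0–66.3 °C) with 2 mock and 3 heat replicates.

* **Classes and kinetics.**  A fraction (default 6.3 %) of proteins are
  aggregators with a planted log2 drop below log2(2/3); recovery is
  linear-in-log2 at rate `true_slope`, truncated at 0.  A Gaussian copula
  plants Spearman −0.42 between drop and slope and +0.25 between disorder
  fraction and slope among aggregators.
* **Effect-size marginals** (free parameters; the emulated study reports
  none): drop magnitude `log2(2/3) − Gamma(2, 0.6)` (mean drop ≈ −1.8),
  slope `Gamma(4, 0.05)` solubility-units/h.  The implied typical recovery
  time |drop|/slope ≈ 9 h exceeds the 5 h window, so most aggregators are
  still recovering at the last time point — matching the emulated
  observation and keeping the linear regime (and hence slope recovery)
  valid.  Stronger truncation or much larger noise would attenuate the
  planted correlations below their recovery tolerances.
* **Sequences** are per-class multinomial draws (lengths log-normal,
  means ~500 vs ~380 residues); the aggregator class is enriched in K, R
  (×1.35) and E (×1.15) and depleted in I, L, V, F (×0.70–0.80), which
  produces the downstream class differences: lower gravy, higher pI,
  higher MW.
* **Abundance and noise.**  log2 abundance ~ N(20, 2.5²) (a realistic
  proteome dynamic range; a narrow spread would make detection loss
  class-differential, since aggregators' heat channels sit ~1.8 log2
  lower).  Noise is multiplicative log-normal per cell (SD 0.15 log2,
  ≈ 11 % CV — typical TMT protein-level precision), per-channel scale
  offsets (SD 0.3), per-protein-per-batch offsets (SD 0.2), and
  left-censoring by a probit in log intensity below the 5 % detection
  quantile (≈ 5 % missing overall).
* **Heavy fraction.**  Label incorporation `1 − exp(−k (t + 1.5 h))`
  (the 1.5 h lead mirrors the pre-shock medium switch), a post-shock
  translational stall (depth 0.5, recovery constant 2 h) in the heat arm,
  and ~10 heat-induced proteins (6–12× induction ramping over the course).
  Newly synthesized proteins aggregate like pre-existing ones.
* **Melting.**  Soluble fraction
  `plateau + (1 − plateau) / (1 + exp((T − Tm)/melt_slope))` with
  Tm ~ N(50, 4) clipped to [40, 63] °C, melt_slope ~ U(0.8, 1.8) °C and
  plateau ~ U(0, 0.15).  The plateau cap matters: the summed
  baseline-corrected signal of a ΔTm shift scales with |log2 plateau|, and
  typical thermal-profiling non-melting fractions are small.  Heat curves
  use Tm + ΔTm (aggregators default ΔTm ~ N(+2.5, 0.5) °C, planting the
  stabilized-remnant effect); aggregators' heat curves also lose the
  pre-aggregated pool (×2^drop) at the two sub-shock temperatures.
* **Complexes.**  40 random complexes (5–20 members) plus 2 planted
  coherent complexes built by grouping aggregators whose planted kinetics
  are nearest neighbours — grouping, rather than overwriting values, keeps
  the planted marginals and copula correlations intact.

**What the generator does not emulate** — peptide/spectrum-level effects
(co-isolation ratio compression, peptide-to-protein roll-up), biological
covariance between sequence features and kinetics beyond the planted
copula, cell-to-cell variability, and real complex biology.  Passing tests
therefore demonstrate that the *estimators recover what was planted under
the stated noise model*, not that the biological conclusions of any real
dataset are reproduced.

## Numerical choices

* Variance-stabilising normalization fits the per-channel affine map
  (a, b) by least squares on the glog2-transformed 10th–90th percentile
  grid against a reference channel (the channel with the median of channel
  medians).  Fitting on the raw scale leaves the intercept dominated by
  the brightest quantiles and injects intensity-dependent distortion; the
  glog-scale fit weights quantiles evenly.  b is parameterised as
  exp(log b), so the transform is strictly increasing by construction;
  a failed fit falls back to a scale-only calibration with a warning.
* Batch correction is the per-protein additive least-squares model
  (subtract per-batch means, preserve the protein grand mean); it is
  idempotent and equals the saturated two-way fit.
* The trigamma inverse uses Newton iteration from `x0 = 0.5 + 1/y`
  (50-iteration cap, relative tolerance 1e−10).
* pI bisection uses Brent with xtol 1e−6 on [0, 14]; the bracket is
  asserted (termini always ionise, so it cannot fail on canonical
  sequences).
* Degenerate inputs: constant samples are "not normal" for the
  Shapiro–Wilk gate; all-tied rank-sum input returns p = 1; constant
  features are excluded from BH; zero across-protein-SD bootstrap rounds
  are dropped and logged; proteins without both baseline temperatures get
  no stability score.
* Tie-breaks: decile tagging sorts by (slope, protein_id) stably;
  upregulation ranking is a stable descending sort.

## Problem sizes

Defaults used by the test-suite and the acceptance script: 2,000–8,000
proteins for pipeline runs (8,000 gives ~500 aggregators for correlation
recovery), 500 bootstrap rounds, 10,000 complex scrambles, and 5–20
simulation seeds for calibration checks.  These sizes give stable
statistics while keeping a full run in minutes on one core.

## Known limitations

* The moderated test assumes a common residual df across proteins (the
  modal replicate count); proteins with fewer replicates are slightly
  mis-calibrated rather than refit.
* The bootstrap t-test inherits the dependence of resampled rounds; its
  p-values are anti-conservative in isolation and are only meaningful
  inside the dual-FDR gate.
* The slope estimator is biased toward zero for proteins that fully
  recover inside the sampling window (the linear fit crosses the kink);
  this is a property of the published estimator, not of the
  implementation.
* The quantile-matched glog normalization assumes most proteins are
  unchanged between channels; designs where a majority of the proteome
  shifts would need reference-channel curation.
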