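# Methods

## The discovery model

The pipeline treats DNA dosage as a candidate mechanism for tumour
over-expression. For a gene *g* in cohort *k* with gene-level copy-number
log2 ratio *t* and log2 expression *x*:

* **SCNA states.** Calls are the piecewise map 2 if *t* > 1, 1 if
  0.2 ≤ *t* ≤ 1, 0 if −0.2 < *t* < 0.2, −1 if −1 ≤ *t* ≤ −0.2, −2 if
  *t* < −1. The gain and loss threshold families are mutually consistent at
  every boundary, so a single function implements both; 0.2/−0.2 belong to
  the altered states and missing ratios (segment gaps) propagate to missing
  calls. Per-gene altered fractions are computed over non-missing calls
  only, so segment gaps do not deflate alteration estimates.
* **Candidate filter.** A gene is a per-cohort candidate when it is
  over-expressed (Welch *t* tumour vs normal; log2 fc > 0.5 strictly, BH
  *q* < 0.05 strictly, with a fold-change-only mode for cohorts whose
  normal panel cannot support a stable *q*), in the top decile of the
  metabolic universe by fold change (ties at the cut break to smaller *q*,
  then gene id), recurrently gained (gained fraction ≥ 0.2 — the only
  non-strict comparison, "at least 20 %"), and dosage-correlated
  (Spearman ρ > 0.3 strictly, BH *q* < 10⁻³ strictly). The BH universe for
  the correlation *q* is the set of genes actually tested within the
  cohort (post gain-filter); this is configurable because the adjustment
  universe is a genuinely open design choice.
* **Top-decile denominator.** The decile is taken over the full metabolic
  gene universe by default (`denominator="all"`); the alternative
  (`"passing"`, only genes surviving the fc/q filter) is exposed because
  either reading of "top 10 % over-expressed" is defensible.
* **Core signature.** Genes whose candidate flag is set in at least
  `min_cancers` (default 3) cohorts, with inclusion counts.
* **Loss side.** The mirrored screen uses under-expression
  (log2 fc < −0.5), loss fraction ≥ 0.2, and the *same positive* ρ
  threshold: dosage concordance means low copy number with low expression.

## Hypoxia scoring

The per-sample score is the mean over signature genes of the within-cohort
z-scored expression (zero-variance genes skipped). No canonical formula
exists for summarising a signature; mean-z was chosen because it is
location/scale invariant (exactly testable), monotone-equivalent to the
common alternatives, and linear — a `median_rank` variant is available.
Genes shared between the signature and any tested gene set are always
removed before correlating, to avoid self-correlation. High/low hypoxia
dichotomises at the cohort median, consistent with the survival layer's
median splits. The signature-vs-other comparison is a one-sided
Wilcoxon rank-sum test, exact when both groups have ≤ 50 untied values,
otherwise normal approximation with continuity correction.

## Permutation machinery

All empirical p-values use the add-one estimator
(1 + #{null ≥ observed}) / (1 + draws), so p is never 0 and the floor at
10⁴ draws is ≈ 10⁻⁴. The mRNA–mRNA null takes two disjoint random gene
sets of size √n_pairs (default 1000 × 1000 = 10⁶ correlations), computed
as a rank-transformed matrix product (ties handled by average ranks, i.e.
the tie-corrected Spearman). Correlation-count tables use the null's
95th/5th percentiles as cutoffs and exclude self-pairs; the per-cell
enrichment p reuses one shared set of random genes per table (draws are
exchangeable across cells, and a shared set is much cheaper than fresh
draws per cell). Fisher's two-sided p follows the probability-mass rule
(sum of margin-fixed tables at most as probable as the observed one) —
stated explicitly because two-sided conventions differ between tools.
Cytoband proximity is operationalised as same chromosome arm with band
indices differing by ≤ 1; no numeric definition of "proximal bands"
exists, so the radius is a parameter.

## Survival modelling

Follow-up is truncated (time > cutoff → censored at cutoff; the boundary
itself is untouched) before any modelling; 10 years is the default, 5 for
aggressive-histology cohorts. Univariate analysis median-dichotomises
expression (ties at the median go to the low group) and reports the Cox
hazard ratio with Wald test, plus the log-rank p (own implementation with
the standard hypergeometric tie correction, cross-checked against
lifelines). The multivariate recipe per training set:

1. log-rank screen at *P* < 0.1 on median-dichotomised expression —
   dichotomised for consistency with the univariate layer (continuous
   screening is the other defensible choice);
2. LASSO Cox on **continuous** expression of the survivors (an L1 penalty
   on dichotomised inputs would be degenerate), via coordinate-descent
   coxnet; clinical covariates (age ≥ 50 as 0/1, ordinal stage with
   stage 1 as baseline) enter with zero penalty when requested, so they
   are never dropped;
3. the penalty grid (30 values, ratio 0.01) is scored by 10-fold
   cross-validated Breslow partial-likelihood deviance on the held-out
   fold, folds stratified by event status so no fold is event-free; the
   smallest mean deviance wins;
4. validation-side risk is the linear predictor on standardised features;
   Harrell's concordance (risk ties scoring 0.5) measures discrimination.

Repeated-split evaluation redraws an event-stratified random split per
repeat (training fraction 0.5 by default; 2/3 emulates 2:1 splits for
small cohorts), reports the held-out concordance distribution, optional
external-cohort concordance, and per-gene inclusion frequencies with a
0.2 reporting threshold. A final classifier can be refit on the full
cohort from the frequently included genes.

## The synthetic cohort generator

`simulate_cohort` draws, per cohort (seed + cancer index, everything from
one `numpy` generator):

* latent hypoxia *h* ~ U(0, 1) per tumour sample;
* per-chromosome segmental baselines: 3–8 segments, log2 ratio
  N(0, 0.05); planted drivers receive a focal gain U(0.3, 1.2) in a
  Bernoulli subset with probability `driver_gain_fraction` (0.5);
  hypoxia-coupled drivers use p = clip(0.5 + slope·(h − ½)), i.e. the
  slope is centred on the latent mean so the *marginal* gain fraction
  stays at the target while gains co-vary with hypoxia — what the
  association tests measure;
* tumour expression = gene baseline N(7, 1) + 1.0 log2 shift (drivers) +
  c·(standardised log2 ratio) (drivers) + 1.0·h (signature genes and
  coupled drivers) + N(0, 1) noise; normals are baseline + noise. The
  coupling multiplier c is solved by bisection on a fixed 20 000-draw
  calibration sample from the generator's own copy-number mixture, so the
  realised expression–dosage Spearman ρ hits `driver_coupling` (0.6) at
  the generator's noise level;
* mutations ~ Bernoulli(0.01) per gene and sample, with a random variant
  class;
* survival: event time ~ Exp(0.1 yr⁻¹ · exp(Σ β·z)) with z the
  standardised expression of the planted prognostic genes and β = ±0.8
  alternating in sign (standardisation keeps the baseline hazard
  interpretable; raw log2 baselines near 7 would make exp(β·x)
  astronomical); censoring ~ Exp(0.05 yr⁻¹); age ~ N(58, 10); stage ~
  Categorical(0.3, 0.4, 0.2, 0.1). Stage does not enter the hazard by
  default, keeping the survival ground truth attributable to genes.

The gene universe (ids, uniform coordinates over 10 chromosomes, cytoband
blocks of 50 genes, planted driver/signature/prognostic sets, a 25 %
metabolic flag containing all drivers) depends only on the base seed, so
pan-cancer cohorts share genes and annotation while samples differ.

**What the generator does not emulate**, and hence what passing tests do
not certify on real data: realistic marginal expression distributions
(RSEM-like skew, heteroscedasticity), batch and platform effects,
subclonal or allele-specific copy number, whole-arm events and co-amplified
amplicons (co-occurrence structure is crafted directly in the tests that
need it), correlated gene–gene expression networks beyond the planted
hypoxia axis, non-exponential hazards, and informative censoring.

## Numerical and edge-case conventions

* Expression input must be complete; copy-number may contain missing
  values, which are deleted pairwise in correlations and excluded from
  altered fractions. SEG coordinates are 1-based inclusive on both ends.
* `log2(x + 1)` with pseudocount 1 so zero reads map to 0, matching the
  zero-read gene filter (> 75 % zeros, strict).
* Probe collapse keeps the probe with the largest sample standard
  deviation; equal-sd ties break to the lexicographically smallest probe
  id for determinism.
* Welch's test with both group variances zero returns t = 0, p = 1 at
  equal means, ±∞ and p = 0 otherwise; Spearman on a constant vector
  yields a missing result rather than an error.
* Simulation problem sizes used in the test-suite calibration runs
  (e.g. 10 recovery seeds at 3 × 200 tumours, 100 split repeats at
  n = 600) are the package's reference conditions; enlarging them only
  sharpens the same checks.

## Known limitations

* The driver cascade assumes tumour/normal pairs exist for differential
  expression; cohorts without normals can only use the fold-change-free
  operations.
* The LASSO penalty is chosen by minimum mean CV deviance; the sparser
  "one standard error" rule is not implemented.
* Proportional-hazards adequacy is not tested; no competing risks or
  time-dependent covariates.
* The generic over-representation test substitutes for curated
  pathway-database enrichment; no pathway catalogue ships with the
  package, and the hypoxia signature used in tests is synthetic.
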