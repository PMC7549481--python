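# Methods

This note documents the models, the synthetic cohort the package is
validated on, the numerical choices, and the known limitations.

## The synthetic cohort

Every analysis stage is exercised against cohorts from
`slepd.simulate`, whose defaults encode the study conditions:

* **Design.** Three arms (placebo, 2 mg, 4 mg) of 90 patients sampled
  at weeks {0, 2, 4, 12, 24}, plus 50 healthy controls at week 0.
  Covariates: age ~ N(45, 12²) clipped to [18, 80], 92% female,
  log leucocyte count ~ N(log 5.8, 0.35²). Covariates carry no
  expression effect by default; they exist so the repeated-measures
  model estimates them, as the analysis includes them unconditionally.
* **Expression.** Per gene g, patient i, week w:
  `y = m_g + e·1[g∈IFN]·1[i high] + d(arm)·r(w)·δ·1[g∈IFN] + b_i + ε`,
  with gene-level healthy means m_g ~ N(8, 1), elevation e = 2 log2
  carried by a fraction 0.6 of patients (inside the 50–75% range
  reported for the interferon signature in active SLE), maximal 4 mg
  effect δ = −0.5 log2 with dose scaling d = (0, 0.5, 1) and onset
  ramp r = (0.5, 0.75, 1, 1) over weeks (2, 4, 12, 24), patient
  intercept b_i ~ N(0, 0.25²) (half the residual sd, giving a
  repeated-measures correlation ≈ 0.2), residual ε ~ N(0, 0.5²).
  The treatment effect applies to the elevated (IFN-block) genes of
  every patient in the arm. Probe-level output adds zero-mean probe
  affinities (sd 0.5), extra probe noise (sd 0.25) and optionally a
  fraction of outlier probes shifted +6 log2 in 10% of samples.
* **Clinical trajectories.** SLEDAI-2K change from baseline =
  drift(w) + d(arm)·1[high]·benefit(w) + N(0, 3²), rounded to
  integers and clipped so scores stay in [0, 105]; baseline scores
  ~ round(N(9, 3²)) clipped to [4, 40], matching the enrolment
  criterion of a score ≥ 4 with arm means near 9. Default drift
  (−0.5, −1, −1.5, −2) and responder benefit (−1, −2, −3, −4) over
  weeks (2, 4, 12, 24). The discretization follows from the score
  being integer-valued while the analysis treats changes as
  quantitative.
* **Cytokines.** Log-normal per analyte with healthy log-mean at
  log LLOQ (so roughly half of healthy samples are censored,
  mirroring panels where controls are mostly near the limit), SLE
  shift +1 log, patient intercept sd 0.3, residual sd_log 0.8, and
  arm effects at weeks ≥ 12 (IL-6: −0.4 on 4 mg; IL-12p40: −0.3;
  2 mg at half). Values under the analyte's LLOQ are flagged and
  withheld; the uncensored draw is kept in the recorded truth.

What the generator does **not** emulate: batch effects, array spatial
artifacts, probe sequence biology, missing visits, informative
dropout, covariate-expression confounding, or heavy-tailed clinical
noise. Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed generative model, not
robustness to those real-data pathologies.

## Preprocessing

Background correction defaults to identity (synthetic intensities
carry no optical background); a per-sample quantile-floor subtraction
(1st percentile, clamp at 0.5) is available for data that does. The
exon-array convolution background model used by RMA-style pipelines is
array-chemistry-specific and out of scope.

Quantile normalization maps each sample's sorted values onto the
across-sample mean of sorted vectors; ties receive the mean of their
tied target quantiles, and the operation is idempotent.

Summarization fits, per transcript cluster,
`log2(y_ps) = μ + probe_p + sample_s` by iteratively reweighted least
squares with Huber weights (k = 1.345 on residuals standardized by the
MAD/0.6745 scale, re-estimated each iteration), probe effects
constrained to sum to zero so `μ̂ + ŝ_s` is the sample summary.
Median polish is the common alternative; the robust-regression
formulation is used because it exposes explicit sample effects. The
weighted normal equations are solved exactly each iteration by
eliminating the diagonal sample block (cost O(probes × samples)),
converging when the largest coefficient change is < 1e-8 or at 50
iterations; single-probe clusters pass through with a log message.
As k → ∞ the fit converges to the OLS two-way fit (tested).

Small-panel caveat: quantile normalization assumes most features are
unaffected by the biology. On the 120-gene demonstration panel where
50 genes truly differ between groups, forcing identical per-sample
distributions reabsorbs part of the signal (recovery RMSE 0.13 log2
after summarization alone vs 0.54 after normalization, and PD effects
attenuated roughly twofold in the driver narrative). On genome-wide
panels (~70k TCs) this term is negligible; the calibration experiments
for the model itself therefore run on gene-level simulations.

## Baseline ranking

Week-0 SLE samples vs healthy controls, per gene: difference of group
means (log2 fold difference), Welch's t (the least-assumption default
two-sample test), BH q over all genes. Ranking is by fold difference,
descending for the elevated list and ascending for the decreased list;
ranking by significance is available by sorting the output table.

## The repeated-measures PD model

Per gene, all SLE samples (patients require a baseline plus ≥ 1
post-baseline visit; others are excluded with a logged count):

* Fixed effects: treatment (reference placebo), week as a discrete
  factor (reference 0), their interaction, plus age (centered), sex,
  and log cell-count covariates. Cell counts enter log-transformed
  because counts are right-skewed.
* Covariance: within-patient `σ²R` with spatial power
  `R_ij = ρ^|week_i − week_j|` — the standard choice for the unequally
  spaced visit grid; compound symmetry and independence are options.
  ρ is estimated by profiled REML (ML available): for fixed ρ the
  model whitens per patient via the Cholesky factor of R and solves
  GLS; the scalar criterion is minimized over ρ by bounded search
  (tolerance √1e-8). Patients sharing a visit pattern share one
  factorization, so the per-evaluation cost is linear in patients.
* The PD contrast for (arm, week) is the interaction coefficient under
  the reference coding: (arm change from baseline) − (placebo change
  from baseline). The placebo self-contrast is exactly 0. Inference
  is Wald with the normal reference — per-gene sample sizes are large
  (1350 observations); no small-sample df correction (e.g.
  Kenward-Roger) is applied, a documented limitation. BH q-values are
  computed within each (arm, week) slice across the evaluated genes;
  non-converged genes are reported with q = NaN, never dropped
  silently.

Calibration (see `slepd.experiments.mmrm_effect_recovery` and the
acceptance suite): with 200 genes carrying −0.5 log2 at (4 mg, week
12) and 200 null genes at 90 patients/arm, the mean recovered contrast
is within ±0.05 of truth and the null type-I error sits inside the
binomial 99% CI of the nominal 5%. Note the generator's patient
intercept plus the status-linked elevation produce a correlation
structure that spatial power can only approximate; the Wald test stays
calibrated regardless because GLS point estimates are unbiased under
covariance misspecification.

## N-of-1 signature stratification

Per patient, differences d_g = x_patient,g − mean over patients of
x_·,g across the signature genes feed a two-sided one-sample Wilcoxon
signed-rank test (zero differences dropped by the standard convention,
exact null distribution for small n without ties); high = p < α with
positive median difference, low = p < α with negative, otherwise
neither. This one-sample formulation is the natural reading of
"patient vs population mean" (one difference per gene); a two-sample
rank-sum variant (patient values vs population-mean values) is
available via `method="rank_sum"`, and the population mean includes
the index patient by default (leave-one-out optional) — at 90+
patients the distinction is negligible.

Because the reference is the population mean, the effective shift for
a high patient is (1 − frac_high) × elevation: when 60% of patients
carry a +1 log2 signature the net shift is only +0.4 and sensitivity
drops. The recall experiment therefore plants a minority (1/3) of
high patients with the stated per-gene noise, where recall is ≥ 95%;
at the cohort default elevation of +2 log2, recall is high at any
fraction.

The trajectory test statistic is the unweighted mean over
post-baseline visits of (mean SLEDAI-2K change, signature-low) −
(mean change, signature-high); patients called neither are excluded,
matching an analysis that contrasts only the two strata. Each of B
iterations (default 10 000) shuffles the high/low labels among the
same patients preserving group sizes; the one-sided p (high improves
more) uses the add-one convention p = (1 + #{null ≥ observed})/(B+1),
which is strictly positive and valid at finite B. A two-sided option
compares absolute values. A mean rather than a sum over visits is
used; they are equivalent up to a constant at a fixed visit set.
Calibration: under label-uninformative trajectories the rejection
rate at α = 0.05 over 500 replicates sits inside the exact binomial
99% CI (acceptance suite).

LOESS curves (tricube weights, locally linear, no robustifying
iterations, span 0.75 by default) summarize the group trajectories on
a week grid for display only; the permutation statistic never uses
them. The smoother is statsmodels lowess, verified against a tricube
weighted-least-squares oracle to machine precision.

## Percentile co-elevation and Fisher's test

Per gene, the threshold is the empirical 95th percentile of healthy
values, using linear interpolation between order statistics (pinned
because percentile definitions differ across software); a patient is
high only when strictly above it, so a patient exactly at the
threshold is not flagged. The joint 2×2 classification is tested with
Fisher's exact test: sample odds ratio (both-normal × both-high)/
(A-only × B-only), infinite on a zero denominator; two-sided p by
summing hypergeometric probabilities no larger than the observed
table's (verified against full enumeration for small tables). On the
269-patient worked-example counts (56, 5, 34, 174) the odds ratio is
57.32 and p is far below 2×10⁻¹⁶.

## Cytokines

Censored values are imputed to 0.5×LLOQ (idempotent; a missing LLOQ is
an error). Baseline comparisons report detectable fractions per group
and a two-sided Mann-Whitney U on log imputed concentrations; a fully
censored pair of groups degenerates and is flagged with p = 1. Change
from baseline uses natural-log deltas (the base cancels in rank
tests; natural log pins reported medians); patients censored at both
the baseline and the target visit are excluded with the exclusion
count reported, and each arm is compared with placebo by two-sided
Mann-Whitney U (Welch t optional). Rank tests are the default because
imputation makes the deltas non-Gaussian point-masses near ±log 2·LLOQ
terms. No multiplicity correction is applied across analytes by
default (a BH option exists). Deltas are invariant to the
concentration unit. Note the imputation itself can shift medians when
censoring is differential between visits — visible in the worked
example as a 4 mg IL-6 median delta more negative than the planted
effect.

## Network extraction

From one (arm, week) PD slice — the 4 mg week-12 contrast in the
drivers — genes are selected by (a) the n_top = 50 smallest q
(ties broken by p then feature id for determinism), (b) sharing a
transcription-regulation or phosphorylation edge with JAK1 or JAK2 in
either direction (a directed option exists) with q < 0.05, and (c)
the anchor set {STAT1, STAT2, JAK1, JAK2, TYK2}. The induced
undirected subgraph keeps only components containing an anchor;
self-loops are dropped with a log message; node categories come from
a user-supplied annotation table (unannotated → other). An empty edge
table returns the anchors flagged `no_edges`; a non-empty table
containing no anchor is an error. The package bundles no interaction
database — curated databases are proprietary — so the driver builds a
clearly labelled synthetic edge table; any SIF/TSV edge list can be
substituted.

## Problem sizes and determinism

The calibration experiments run at the trial's size (90 patients/arm)
with 500 replicates for the permutation null, 100 for power, and
200 + 200 genes for the MMRM study — sizes at which the binomial CIs
quoted above are meaningful while the full suite completes in about
two minutes. Same seed and configuration give bit-identical outputs
throughout (tested for the CLI bundle and the permutation test); all
seeds derive from a single integer per run.
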