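# Methods

This note records the models behind each `tfaflow` stage, the defaults and
why, what the synthetic-data generator does and does not emulate, and the
numerical choices a maintainer would want to know.

## Data model

A cohort is three tables.  The **Ct table** holds raw qPCR threshold
cycles, one row per sample (patient × collection day) and one column per
assay: 264 target genes plus 8 housekeeping genes (*DOCK2, EEF1A1, OTULIN,
FTL, MYL6, MYL12B, RPS10, RPS25*), with a batch label.  **Annotations**
carry per-sample patient, day, timepoint index, infection and relapse
flags and RNA QC metadata; a separate episode list gives each GVHD episode
(type, onset day, resolution day, grade — flares are separate episodes).
The **repertoire** maps each gene to exactly one four-gene module, each
module to one aggregate, with a functional label (`TBD` when
uncharacterized).

## Preprocessing

*QC*: samples need A260:A280 purity > 1.7 **and** RNA integrity number
(RIN) > 6, with a Bioanalyzer-override flag that retains a sample showing
discrete RNA bands regardless; both thresholds are strict inequalities and
configurable.  Missing QC metadata keeps the sample with a warning by
default.

*Detectable range*: Ct outside [5, 35] cycles is censored to missing.  The
instrument's true cutoffs are not part of the data model, so the range is
configurable; [5, 35] is a typical microfluidic qPCR window.

*Housekeeping normalization*: per sample, the reference is the arithmetic
mean of the present housekeeping Ct values (equivalently the geometric
mean of their linear abundances); log2 expression of gene *g* is
`hk_ref − Ct_g` (−ΔCt) and linear abundance is `2^(−ΔCt)`.  A sample with
fewer than half the pool present is excluded and logged.  The
normalization is invariant to any constant shift applied to all Ct values
of a sample — the property that makes −ΔCt a within-sample abundance
scale.

*Batch correction* is a parametric empirical-Bayes location/scale
adjustment on the log2 scale: gene-wise standardize, estimate per-batch
per-gene location γ̂ and scale δ̂² (denominator *n*, matching the pooled
variance, which makes re-correction of homogenized data an identity),
shrink γ̂ toward a cross-gene normal prior and δ̂² toward an inverse-gamma
prior (method-of-moments hyperparameters, iterated to a fixed point),
remove them, restore the grand mean.  Missing entries are ignored in every
moment and stay missing; single-sample batches pass through with a
warning; a single batch is a no-op.  `shrink=False` gives the direct
per-batch standardization, which is also the large-batch limit of the EB
estimates.  Correction runs on the log2 scale even though the processing
order lists anti-log first: the location/scale model assumes approximate
normality, which holds on the log scale.  Non-parametric priors are not
implemented; the parametric default plus the no-shrinkage mode cover the
practical range.

## Fingerprint scoring

Module activity per sample is the mean log2 expression of member genes
(missing ignored).  Percent response against a reference group is
`%members with FC > 1.5 up − %members down`, bounded in [−100, 100], with
FC the ratio of a sample's linear abundance to the reference-group mean —
the same 1.5 threshold as the DEG gate, for consistency.  Aggregate scores
are unweighted means of member-module scores; scoring is invariant to
sample and within-module gene order.

## Clinical logic

Phases: NEVER (patient has no episode), ACTIVE (day inside any episode's
[onset, resolution], closed on both ends; unresolved episodes extend to
the end of follow-up), PRE (before the first onset), POST (otherwise),
UNCLEAR (annotation conflict; excluded everywhere).  Confounder exclusion
drops samples inside infection windows (inclusive bounds — the
clearance-day sample still reflects the infection) or flagged as relapse,
and is idempotent.  Series eligibility for per-series analysis is ≥ 10
timepoints; group analyses can first truncate at a timepoint index
(default 19 in the PGEE protocol) so the sparse late tails of a few
long-followed patients do not dominate.  Episode alignment re-indexes
samples as `day − onset`; rank 0 is the first sample at/after onset,
episodes need at least one pre-onset sample (configurable), and the mean
curve averages values and aligned days per rank across episodes.
Late-acute and overlap presentations run through the acute stream.

## Differential testing

DEG: Welch (unequal-variance) two-sample t on log2 values, fold change as
the ratio of linear-scale group means, flagged iff *p* < 0.05 **and**
FC > 1.5 in either direction; both gates are necessary.  Groups are
compared in sorted label order, so swapping labels inverts FC and leaves
*p* unchanged.  No multiple-testing correction by default (the analysis
tradition this follows works at raw *p* < 0.05); Benjamini–Hochberg by
flag.  A log2-difference gate is available as an alternative fold-change
mode.

Hierarchical clustering uses correlation distance and average linkage
(scipy); zero-variance rows get the maximum correlation distance 2, and
all-missing rows raise with the row named.

The longitudinal model per gene is
`log2 ~ time + group + time×group + (1 | patient)` by REML
(statsmodels MixedLM), with time in units of 100 days for well-scaled
coefficients.  Wald p-values use a t reference with a between-within style
denominator df, `n_obs − 4 − (n_patients − 1)`; this is a simple stand-in
for a Satterthwaite approximation and is slightly conservative for
between-patient effects.  Singular fits fall back to OLS with
cluster-robust (by patient) standard errors, flagged in the result.
Under the recovery conditions used in acceptance (10 patients/group × 12
timepoints, slope difference 0.5 log2 per 100 days, residual sd 0.4,
random-intercept sd 0.5) the interaction estimate is unbiased within a few
percent and 95% CI coverage is at the nominal level.

## Change-point detection

Each (patient, gene) series with ≥ 10 observed points is segmented by
PELT under the Gaussian cost that charges both mean and variance shifts:
segment cost `n·log(σ̂²)` with a variance floor of 1e−8 so constant
segments are well defined.  The MBIC penalty adds `log(n_seg)` per segment
plus `β = 3·log(n)` per changepoint (three parameters per extra segment:
mean, variance, position); a plain numeric β or BIC is available.
Minimum segment length is 2.

Two exactness details matter.  With a minimum segment length, the
textbook prune-at-*t* rule can discard a candidate that is still optimal
for *t′* < *t* + min_seg, so pruning is delayed by min_seg.  The MBIC
per-segment log-length term breaks the cost's subadditivity by at most
`log(n)`, so pruning under MBIC uses a slack of −log(n).  With both,
the pruned search provably returns the same optimum as the exhaustive
O(n²) dynamic program, which the test suite verifies on series up to
length 25.  Positions are invariant to adding a constant or scaling the
series (the mean-variance cost is location-scale equivariant) and are
reported in clinical timepoint coordinates after dropping missing values
(recorded), so onset mapping is unambiguous.

The onset shortlist keeps, per patient, genes with at least one
changepoint whose changepoints all fall at the last timepoint strictly
before an onset or at the first timepoint at/after it; genes that also
change in any no-GVHD control series are removed.  The cohort summary
reports, per gene and cohort, the percentage of analyzed series with at
least one changepoint.

## Penalized GEE

The marginal model is binomial-logit: per-sample GVHD outcome on
standardized gene abundances, clusters = patients, exchangeable working
correlation by default (AR-1 available; the moment estimator of ρ is
clamped inside the positive-definite range and at 0.95).  The SCAD
penalty (a = 3.7) enters the estimating equation as `n·E(β)β` with
`E = diag(p′_λ(|β_j|)/(|β_j| + 10⁻⁶))`, n the number of clusters and the
intercept unpenalized.  Newton-type updates solve the local-quadratic
approximation; coefficients below 10⁻³ are clamped to exactly zero during
iteration (under LQA their penalty weight diverges and they cannot
recover; clamping removes the oscillation that otherwise prevents
convergence).  The solver warm-starts at a lightly ridge-regularized GEE
estimate: an unpenalized start diverges under quasi-complete separation
and would land beyond SCAD's flat region (|β| > aλ) where no shrinkage
applies.  Tolerance 1e−6, max 100 iterations; non-convergence returns the
last iterate flagged, separation sets a warning flag.  Rows with missing
features drop out of the estimating equations.  At λ = 0 with singleton
clusters and independence correlation the solution equals IRLS logistic
regression (verified to < 1e−6 against statsmodels GLM).

λ is chosen by cross-validation with folds partitioning *patients*
(never splitting one across folds) on held-out binomial deviance.  The
default selection rule is the **one-standard-error rule**: the largest λ
within one SE (across folds) of the minimizing mean deviance.  The bare
minimizer is available (`rule="min"`, ties to the larger λ) but
systematically overselects when the fit is used for feature selection —
in the selection-recovery study it admits 6–11 false positives where the
1se rule keeps ≤ 2 — the familiar prediction-vs-selection trade-off that
motivates the same convention in penalized regression software.  A
training fold with one outcome class is re-randomized with a warning.

The analysis protocol builds the outcome per mode: **cohort** (every
sample of an ever-GVHD patient = 1), **active** (active-GVHD samples vs
never + pre samples, post-GVHD dropped), **pure** (cohort after
confounder exclusion); timepoints are truncated at index 19 first.  Modes
needing a class with < 2 patients raise.

## Synthetic cohorts

The generator emulates the study conditions: 15 patients (11 GVHD, 4
never), one pre-transplant sample at day −7, weekly sampling from
engraftment (day 21) while the visit starts on day ≤ 100 and biweekly
after, to 215 days of follow-up (the cohort median); 264 genes in 66
modules + 8 housekeeping; acute onsets uniform on [engraftment, 100] with
Exponential(mean 30 d) durations, 40% of GVHD patients adding a chronic
episode on [100, follow-up]; infection windows for 60% of patients,
relapse for 20%; per-module latent factors (sd 0.3 log2) so module scoring
is meaningfully correlated; residual sd 0.5 log2; gene-specific batch
offsets (sd 0.5 Ct, 3 batches) that deliberately survive housekeeping
normalization; 5% MCAR missingness plus censoring above Ct 35.
Phase-linked effect templates add a log2 shift to all genes of a
functional signature inside a day window around each onset (defaults:
interferon +1.0 on [−7, +30], erythroid +0.8 on [0, +60]).  Ground truth
(episodes, effect gene sets, batch assignment) ships with every cohort.

What it does **not** emulate: immunosuppression pharmacokinetics and
therapy-driven expression, organ-specific GVHD biology, sequencing-style
count noise, probe efficiencies, non-MCAR dropout correlated with disease
state, and donor samples.  Passing recovery tests therefore show the
pipeline recovers the *kind* of structure the study analyzes — phase-
linked modular shifts under realistic missingness, batch and correlation
structure — not that it would reproduce any particular clinical gene list.

## Problem sizes in the acceptance script

All simulations are sized to run comfortably on one CPU: DEG null
calibration over 200 replicate cohorts of 40 genes × 30 samples; PELT vs
the exhaustive dynamic program on 60 series of length 10–25; LMM recovery
over 100 replicates of 10 patients/group × 12 timepoints; PGEE selection
recovery over 50 replicates of 40 patients × 10 timepoints × 50 genes
with 3 signal genes at 1.0 log-odds and latent exchangeable within-patient
outcome correlation 0.3, λ by 5-fold patient-level CV over a 10-point grid
on [0.05, 1.2]; batch equalization on a constructed two-batch offset.
The cohort-table quantities (median span 215 days, 245 post-transplant
samples, 12 change-point-eligible series, 26 GVHD patients) come from the
per-patient series summary and subtype breakdown shipped as package data.

## Known limitations

Satterthwaite df are approximated (above); PGEE reports no post-selection
standard errors; the changepoint stage segments genes independently (no
multivariate joint segmentation); percent-response scoring needs an
explicit reference group; UNCLEAR phase labels rely on an annotation flag
rather than automated conflict detection between overlapping episodes.
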