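# Methods and design notes

## Timeline rules and their encodings

All clinical dates are stored as integer days from a configurable epoch
(files carry ISO-8601; the default epoch is 2015-01-01). Working in
integer days makes every window rule exact and removes calendar/timezone
ambiguity.

**Endpoints.** OS runs from a therapy line's start day to death, censored
at the last recorded follow-up. rwPFS uses the event window
`[start + 14, U)`: progression, new-metastasis, and death events qualify
only from day 14 onward (clinical-note "progression" recorded in the
first two weeks typically reflects baseline disease), and only strictly
before `U`, the treatment end day when recorded, else the next line's
start day, else the last follow-up. A recorded death day qualifies even
when the progression-event table lacks a death row. Boundary choices —
day 14 inclusive, `U` exclusive — are encoded in one place and pinned by
a brute-force oracle test that rescans every event literally (1,000
fuzz-generated timelines, zero tolerance).

**Resistance phenotyping.** The three rules are closed-interval window
tests: EOT anchoring (±30 days of treatment end, or ≥60 days after start
when the end date is missing), resistance (next line within 90 days of
the treatment end, or a progressive-disease event within 90 days of the
*collection* day — the two clocks deliberately differ, one anchored at
treatment end and one at the biopsy), and the primary/acquired split at
180 days of ICI duration (`< 180` primary, `>= 180` acquired). Biopsies
link to the latest ICI or ICI+chemo line starting on or before
`collection + 30`; samples with no linkable line are `not_eot`, and
resistant samples with no recorded end day are `unclassifiable` rather
than silently dropped, so the filter-cascade report always partitions the
input.

## PD-L1 imputation

The threshold search evaluates Cohen's kappa between `expr >= t` and the
binary IHC label at every observed unique expression value (optionally
midpoints), keeping the smallest maximizer. Kappa of a constant table
(chance agreement 1) is defined as 0. Two independently fitted binary
models (≥1%, ≥50%) must satisfy `t_ge1 <= t_ge50` to produce the
three-class call; incoherent pairs are an error rather than silently
reordered. Observed IHC always wins over imputation.

A note on recovery resolution: threshold estimators of this type converge
at a cube-root rate, so at n = 500 with class separation 2 and sd 0.5 the
recovered cut scatters ~0.1 log2 units around the class midpoint — far
wider than the spacing of adjacent observed values there. Recovery tests
therefore assert closeness on the sampling-resolution scale (≤ 0.25
units, ≤ 2% classification disagreement with the midpoint rule) together
with sensitivity/specificity ≥ 0.9 and an exhaustive re-scan confirming
the returned kappa is the grid maximum.

## Normalization and scoring

TMM follows the standard recipe: the reference sample is the one whose
75th-percentile count fraction is closest to the cross-sample mean; each
sample's gene-wise log ratios (M) and log abundances (A) against the
reference, over genes nonzero in both, are doubly trimmed by rank (30%
per M tail, 5% per A tail) and combined as a precision-weighted mean
(delta-method weights); factors are rescaled to geometric mean 1. The
implementation was cross-checked against an independent literal
re-implementation (and, during development, against the reference R
implementation) to 10 decimal places on NB fixtures.

log2 CPM uses a prior count expressed *per million*:
`prior_j = prior_count * eff_lib_j / 1e6` with
`value = log2((count + prior_j) / (eff_lib_j + 2 prior_j) * 1e6)`. Because
the prior scales with the effective library, the value depends only on
the count fraction, making the transform exactly invariant to uniform
count scaling and to depth changes at fixed composition (a fixed prior
satisfies neither identity exactly). Defaults: prior 0.5, log base 2.

Signature scores are unweighted means of log-scale normalized expression
over the signature genes present in the matrix (missing genes are
dropped and counted). Covariate-adjusted group means fit
`score ~ group + covariates` by OLS and evaluate each group level on a
balanced reference grid — factor covariates weighted equally, numeric
covariates at their mean ("observed" weighting is available as a switch).
This is one of several marginal-mean conventions; the balanced grid was
chosen because unequal biopsy-site frequencies between arms are exactly
the confounding one wants removed.

Pseudobulk columns are exact integer sums of member-cell counts per
(patient, cell type); columns under `min_cells` (default 10) are flagged,
not dropped, and excluded/unlabeled cells are counted so total counts are
conserved. Cell-type signature profiles normalize the pseudobulk matrix
(TMM + log2 CPM across columns), score the signature per column, and
rank cell types by median score.

## Differential expression and enrichment

Per-gene DE is ordinary least squares on log2 CPM with a two-level group
factor (configurable reference level; the group coefficient is the log2
fold change) plus factor/numeric covariates. Variance moderation is OFF
by default; an optional simple shrinkage pools residual variances toward
their mean with prior weight d0 = 4 and adds d0 to the t degrees of
freedom — a documented simplification, not an empirical-Bayes fit. Genes
with numerically zero residual variance get t = 0, p = 1, and a flag.
The paired design is handled by a one-sample t-test on within-patient
(post − pre) differences, which removes the patient-level term exactly;
this is the package's deliberate simplification of intrapatient-
correlation modeling, adequate for complete pairs and documented as such.

Preranked enrichment sorts genes by the chosen statistic (t by default;
descending, stable gene-symbol tie-break), accumulates
`|stat|^w / sum_hits |stat|^w` at hits (w = 1) and `−1/(N − n_hit)` at
misses, and takes the maximum-magnitude excursion as ES; the running sum
ends at 0 by construction. The null is gene-label permutation (random
same-size sets), matching the preranked setting; NES divides ES by the
mean |permuted ES| of the same sign, and p is the same-sign tail with the
+1 correction. The implementation avoids the O(N) walk per permutation by
evaluating the running sum only at hit positions, which makes the
500-draw null-calibration protocol (300 permutations per draw; the
operational default stays at 1,000 permutations) run in seconds.

## Survival screen

The univariate per-gene Cox screen maximizes the Breslow partial
likelihood with a Newton iteration vectorized across all genes
simultaneously (shared risk-set cumulants; step clipping at ±2 with
convergence tolerance 1e-8). It matches lifelines coefficients and
standard errors to ~1e-4 on tie-free data and keeps genome-wide screens
and 100-replicate calibration runs in the seconds range. Expression
enters continuously (hazard ratio per log2 unit) — chosen for power; the
median-split Kaplan–Meier view is available separately. Constant or
non-convergent genes are flagged and excluded from hit sets.
Covariate-adjusted mode delegates each fit to lifelines.

Cross-cohort intersection takes genes with p < α (default 0.05,
unadjusted — replication across cohorts is the multiplicity control;
within-cohort BH is available) in both cohorts, requires concordant
direction by default, and reports discordant genes separately. Projection
builds a signature from each hit partition and ranks cell types by
median pseudobulk score.

## Synthetic-data generator

The generator is the package's test substrate and defines its study
conditions:

* **Timelines** are constructed, not sampled freely: each planted arm
  (naive / EOT-nonresistant / primary / acquired; default mix
  0.40/0.20/0.15/0.25) realizes dates strictly inside or outside every
  rule window with ≥ 2 days of slack, so the phenotyper must reproduce
  the planted labels exactly and boundary behavior is tested
  deterministically. A separate fuzz mode samples unconstrained timelines
  for the endpoint oracle tests.
* **Expression** is negative-binomial: gene baselines log2-normal
  (mean 5, sd 1.5, clipped to [1, 12]), dispersion 0.1, library depth
  log-normal around 2e6 (sd 0.15). Planted modules follow the observed
  resistance biology: an 18-gene IFNγ module at +1 log2 in acquired
  resistance, 12-gene B-cell and 10-gene DC modules at −1 log2 in primary
  resistance.
* **CD274/PD-L1 coupling**: each patient's PD-L1 class (probabilities
  0.45/0.30/0.25) sets a latent CD274 log2-CPM mean (5/7/9; generating
  thresholds 6 and 8 recorded in the truth file) with sd 0.45 plus NB
  noise at gene-wise dispersion 0.02 (CD274 gets a tighter dispersion
  than the global default so the total class overlap sits at the ~0.5-sd
  scale; gene-wise dispersions are standard in RNA-seq noise models).
  60% of biopsies carry observed IHC; the rest are imputation targets.
* **Survival**: exponential event times with hazard
  `h0 * exp(0.8 * (u_unfav − u_fav) + 0.4 * stage_IV)`, h0 = 1/500 per
  day, administrative censoring at 3 years. The 15 favorable and 15
  unfavorable prognostic genes each load on a shared per-patient latent
  program score (u ~ N(0,1)) added to their log2 means — co-expressed
  prognostic programs are what real immune-infiltration biology looks
  like, and they make the per-gene marginal screen target well defined;
  30 *independent* per-gene hazards at |log HR| = 0.8 would imply an
  implausible e^±4 spread of patient hazards and severe frailty
  attenuation of every marginal fit. The event clock starts at a
  per-patient timeline-safe anchor (the line start for naive patients;
  just past the resistance window for post-ICI patients) so merged death
  events cannot flip planted phenotype labels; anchors are recorded in
  the truth file, and for naive-only configurations OS is exactly
  Exponential(h0), which the generator tests verify against the closed
  form.
* **Single-cell atlas**: 12 patients × 7 cell types (tumor, T, B, DC,
  macrophage, monocyte, ciliated) × 20 cells, NB counts at 1/400 bulk
  depth; module genes are enriched in their home cell types (B-cell/DC
  modules +3 log2, IFNγ +2 in T cells), favorable prognostic genes +2 in
  the myeloid types, unfavorable +2 in ciliated/tumor cells.
* A self-audit pass applies the real phenotyper to every generated cohort
  and refuses to emit tables whose labels deviate from the planted truth.

What the generator does **not** emulate: real library-preparation
artifacts (GC/length bias, batch effects), correlated gene-gene noise
outside the planted programs, informative censoring, irregular visit
schedules, or measurement error in therapy dates. Passing recovery tests
therefore demonstrates that the *machinery* is correct and calibrated
under the stated generative model — not that real-cohort effect estimates
are unbiased under violations of it.

## Problem sizes and numerical choices

Default test-scale conditions: 300 patients / 2,000 genes per cohort for
end-to-end runs; 500 patients for phenotyping recovery; 1,000 fuzz
timelines for the endpoint oracle; 2,000 genes × 40 samples for DE null
calibration; 100 replicates × 200 genes for Cox type-I calibration; 500
random-set draws at 300 permutations for enrichment null calibration.
These sizes give tight Monte-Carlo bands (binomial se ≈ 0.0015 on a 0.05
type-I fraction at 20,000 fits) while keeping the full suite and the
acceptance script fast on a single CPU.

Numerical conventions: closed intervals for all "within N days" windows;
kappa ties break to the smaller threshold; GSEA ranking ties break by
gene symbol; BH q-values come from the standard step-up with enforced
monotonicity; zero-variance genes and non-convergent Cox fits are
flagged, never silently dropped; every stochastic routine takes an
explicit seed and the pipeline derives all stage seeds from one config
seed, making full runs byte-reproducible.
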