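# Methods

## The evaluation problem

A screening exam carries a continuous AI malignancy score s ∈ [0, 1], two
independent binary reader decisions recorded before any consensus
conference, and a ground-truth label: biopsy-confirmed screen-detected
cancer or follow-up-proven normal. Three decision pathways are compared
on the same exams:

1. **Radiologist** — the recorded reader decision;
2. **Standalone AI** — positive iff s ≥ θ, with θ fitted on validation to
   a sensitivity target (by default the measured validation radiologist
   sensitivity);
3. **Decision referral** — auto-negative below θ_low, auto-positive above
   θ_high, reader decision in between.

The evaluation simulates the referral pathway retrospectively under the
assumption that confident AI calls are accepted as-is: triaged exams
become negatives even when the exam is a cancer, safety-net exams become
positives even when normal. No change in reader behaviour from seeing AI
output is modelled; that is an explicit scope boundary, not an
approximation we control.

## Threshold fitting

Candidate thresholds are the observed validation scores (plus 0 on the
triage side); no interpolation. θ_low is the **largest** candidate such
that the weighted fraction of validation cancer mass scoring ≥ θ_low is at
least the NT target; θ_high the **smallest** candidate keeping at least
the SN target of weighted normal mass at or below it. Choosing the
conservative side means the achieved operating characteristic is ≥ the
target on validation. Confidence is strict: s exactly equal to a
threshold is referred, so (θ_low = 0, θ_high = 1) reproduces the
radiologist pathway exactly, and θ_low = θ_high = θ reproduces standalone
AI except for exams scoring exactly θ (which are referred and counted).
If the fitted θ_high falls below θ_low the configuration is infeasible: a
named error when fitted singly, an explicitly marked row in grid output.
Threshold fitting is weighted by default; because the default weights are
constant within a label this equals unweighted fitting unless a
finer-grained stratum weighting is used. The choice is recorded in the
`weighted` field of the configuration.

## Enrichment weighting

Study cohorts oversample cancers. With population prevalence π (a
required external input, never inferred from the sample), each record
gets w = target-proportion(label) / sample-proportion(label), so weighted
label proportions equal (π, 1−π) exactly. Weights enter all estimates in
ratio form — their scale is irrelevant and no normalisation to 1 is done.
Two consequences worth keeping in mind:

* weighted sensitivity and specificity equal their unweighted
  counterparts (weights constant within a label); weighting moves only
  cross-label quantities — triaging performance, ROC/AUROC, automation
  fractions;
* the Kish effective sample size (Σw)²/Σw² is reported alongside weighted
  estimates as a variance-inflation diagnostic.

A generic hook accepts target proportions over any categorical column for
schemes finer than the two-label default.

## Metrics

Sensitivity and specificity accept fractional calls so the two readers
can be averaged per exam (a referred cancer recalled by one of two
readers contributes 0.5); the averaged estimate equals the mean of the
two single-reader evaluations by linearity. Triaging performance is the
weighted fraction of **all** exams that are truly normal and triaged —
safety-net automation is reported separately, not folded in, and the
same definition is applied to every pathway (for standalone AI this is
(1−π)·Sp). ROC curves are exact weighted staircases over every distinct
score with a +∞ threshold so (0,0) and (1,1) always exist; AUROC is the
weighted Mann–Whitney statistic with ties credited ½, computed by the
trapezoid over the staircase and cross-checked in the test suite against
scikit-learn's implementation and brute-force pair enumeration. Tables
print percentage points to one decimal; internal arithmetic is full
precision.

## Resampling inference

**Bootstrap (95% percentile CIs, B = 1000 by default).** Each replicate
(1) samples one of the two recorded reader decisions per exam — skipped
for standalone AI, which uses no reader — and (2) resamples exams with
replacement, then recomputes the metric. Per-label weights are refit on
each resample so the weighted prevalence stays pinned at π. Replicates on
which a metric is undefined (e.g. a resample with no cancers) are redrawn
and counted in the returned estimate. The point estimate is always the
reader-averaged evaluation of the original cohort. Delta CIs evaluate
both pathways on the same resample with the same sampled readers,
preserving pairing. Percentile intervals were chosen over BCa as the
minimal defensible reading of "B bootstrap samples"; the machinery is
isolated so the interval rule can be swapped.

A caution on interpreting these CIs: step (1) deliberately folds
*reader variability* into the interval. The replicate statistic has
single-reader variance, a factor 2/(1+ρ) above the reader-averaged
estimator's variance (ρ = correlation of the two readers' calls). For a
fixed true sensitivity the interval is therefore conservative whenever
readers disagree, and attains nominal 95% coverage exactly in the limit
of identical readers. The test suite checks both facts: nominal coverage
(95% ± 2 pp over 500 simulated cohorts) with near-identical readers, and
no under-coverage with discordant ones.

**Permutation test (two-sided, P = 10 000 by default).** For a difference
between two pathways, the per-exam reader-averaged call pair (a_i, b_i)
is swapped as a block with probability ½ per trial and the weighted
difference recomputed; under the null that the pathways are exchangeable
this sign-flip group is exact. Two conventions needed fixing where the
procedure is under-determined, and both were chosen for statistical
validity, verified by simulation against an exchangeable null before the
acceptance conditions were frozen:

* re-sampling a single reader inside each null trial while comparing
  against the reader-averaged observed delta is invalid (null draws carry
  about twice the variance of the observed statistic; measured type-I
  error ≈ 0.005 at α = 0.05), so reader-averaging is treated as the
  estimator and the swap acts on averaged pairs;
* the statistic lives on a coarse lattice (multiples of half a label
  weight), so ties with the observed value carry real mass; they receive
  half credit (mid-p). Full credit measured type-I ≈ 0.025; mid-p
  measured 0.041.

Monte-Carlo p-values use add-one smoothing, p = (1 + #greater + ½·#tied)
/ (P + 1), guaranteeing p ≥ 1/(P+1); identical arms return p = 1 by
convention. For ≤ 16 discordant exams the full 2^k distribution is
enumerated instead. All resampling is a pure function of (inputs, seed):
one root seed spawns per-purpose child streams, so adding a metric never
perturbs another's draws.

## Subgroup reports and the operating-point grid

`stratified_report` computes per-level reader-averaged sensitivity for
all three pathways with a per-level permutation p and significance
markers at p ≤ 0.05/0.01/0.001/0.0001 (1–4 stars). Missing stratum
values form an explicit "unknown" level; levels with fewer cancers than a
minimum count (default 10) are reported but flagged unstable. Lesion-size
bins default to ≤10, 11–20, >20 mm and are configurable placeholders, not
clinically authoritative cut-points. `operating_point_grid` fits every
(NT, SN) pair on validation and evaluates on test, emitting radiologist
and standalone anchors plus one row per configuration sorted by
sensitivity. Structural invariants tested: triaging performance is flat
in the SN target for fixed NT (it depends only on θ_low) and
non-increasing as the NT target rises.

## Synthetic cohort generator

The generator emulates an enriched double-reader screening cohort with
fully known ground truth.

* **Labels**: Bernoulli at the enriched prevalence min(E·π, 0.5);
  E is the cancer-oversampling factor, with π and the drawn counts
  recorded so weighting can undo the enrichment.
* **Latents**: per exam, a trivariate Gaussian (AI, reader 1, reader 2)
  with correlation matrix [[1, ρ_ra, ρ_ra], [ρ_ra, 1, ρ_rr],
  [ρ_ra, ρ_rr, 1]], drawn via Cholesky; a non-positive-definite request
  raises a named error. The explicit-matrix form was preferred over a
  shared-difficulty-factor parameterisation because the factor form
  cannot express ρ_rr = 0 with ρ_ra > 0 and is a special case of the
  matrix form anyway.
* **AI score**: cancers shift the AI latent to N(μ, σ²) vs N(0, 1) for
  normals (classic binormal ROC, closed-form AUROC Φ(μ/√(1+σ²))); the
  score is the standard-normal CDF of the latent — a monotone map, so
  AUROC is untouched, and scores must not be read as calibrated
  probabilities.
* **Readers**: recall iff the reader latent exceeds a class-conditional
  cut. Marginals stay standard normal within a class for any admissible
  correlation, so the cuts are exact quantiles Φ⁻¹(1−Se) (cancers) and
  Φ⁻¹(Sp) (normals) and calibration needs no iteration.
* **Subgroups / lesion sizes**: optional categorical columns with mixing
  proportions and per-level shifts of the cancer AI mean (negative =
  harder for the AI); optional log-normal lesion sizes on cancers only
  (default log-mean 2.48, log-sd 0.5 → median ≈ 12 mm, a plausible
  screen-detected size distribution).

ρ_ra > 0 is the load-bearing mechanism: ambiguous-for-the-AI exams are
then also harder for readers, so the confident subset's AUROC exceeds
the full-cohort AUROC — the property that lets referral beat both the
reader and standalone AI simultaneously.

Default parameters sketch a realistic modern screening regime — μ = 2.326
and σ = 1 (AUROC ≈ 0.95), reader Se 0.87 / Sp 0.934, π = 0.006, E = 10,
ρ_ra = 0.3, ρ_rr = 0.4. They are illustrative of that regime, not fitted
to any dataset; in particular the correlation defaults are conventional
"moderate" values, since no inter-reader agreement statistic was
available to anchor them. A closed-form oracle for the combined system's
(Se, Sp, triage) at any threshold pair exists in the ρ_ra = 0 regime,
where the referred subset's reader operating point equals the marginal
one and the pathway factorises; calling it with ρ_ra ≠ 0 raises a named
out-of-regime error.

**What passing tests do and do not show.** The generator produces
exchangeable exams with Gaussian latent dependence, exact per-class
reader marginals and a single global enrichment mechanism. Real screening
data have site and device heterogeneity, non-Gaussian score shapes,
label noise from imperfect follow-up, and readers whose accuracy varies
over time and case mix. Agreement with the closed-form oracles therefore
validates the *evaluation machinery* (routing, weighting, metrics,
inference), not any claim about a particular clinical dataset.

## Problem sizes and numerical choices

The test suite exercises the closed-form oracles at n = 2·10⁵–5·10⁵
draws (Monte-Carlo tolerances ±0.005 absolute), permutation validity
over 1000 simulated null datasets at P = 500, and bootstrap coverage
over 500 cohorts at B = 200 — scaled-down resampling counts for the
suite, while the library defaults stay B = 1000 and P = 10 000. The
acceptance script evaluates a 20 000-exam validation and 50 000-exam
test cohort at the default regime with full B and P; these sizes give
roughly 1200 and 3000 cancers, comparable to the enriched evaluation
cohorts the framework targets. Threshold feasibility comparisons use a
10⁻¹² absolute slack so ties at a target are treated as achieving it;
permutation tie detection uses the same slack. Degenerate inputs raise
named errors rather than returning NaN: single-label cohorts (weighting,
ROC, Se/Sp), empty or single-label confident subsets (with counts in
the message), unfitted or infeasible configurations, and non-PD
correlation requests.

## Known limitations

* Only the two-label (cancer/normal) weighting is built in; finer "study
  type" strata are supported through the generic hook but no defaults are
  shipped.
* Subgroup bins and minimum-count flags are configurable conventions, not
  validated clinical definitions.
* No interval cancers, no per-woman longitudinal structure, no
  consensus-conference simulation, and no human–AI interaction effects:
  the referral pathway's confident calls are accepted by construction.
* Bootstrap CIs are percentile-only; no closed-form (Wald/Wilson)
  intervals are offered as primary outputs, and no multiplicity
  correction is applied across grid rows.
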