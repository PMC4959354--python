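# Methods

## Overview

`psamine` implements a discovery pipeline for prognostic patterns in
longitudinal PSA series of ADT-treated prostate-cancer patients: velocity
transformation and nadir split, two discretizations, per-class frequent
sequential pattern mining, cross-validated predictive selection, an
informativeness partial order, and Kaplan–Meier/log-rank comparison against
the classical dichotomized markers. This note records the modelling
assumptions, the numerical conventions, and the design choices made where
the procedure was genuinely open.

## Velocity transformation and segments

PSAV is the raw difference quotient over consecutive measurements,
`(PSA_t2 − PSA_t1)/(t2 − t1)` in ng/(ml·mo); PSA is deliberately *not*
log-transformed so that equal absolute monthly changes are treated equally
regardless of the level. The nadir is the series minimum with ties broken by
the earliest time, so the nadir is always itself a measurement time; a
velocity point belongs to the before-nadir segment iff its interval ends at
or before the nadir and to the after-nadir segment iff it starts at or after
it — the two segments partition all points, and either may be empty.
Patients with fewer than two measurements in a segment contribute no
velocity instances there but are retained for baseline model fitting: they
carry covariate information but no pattern information. Measurements after a
patient's event are excluded at read time so every stage sees the same
truncated series.

## Discretization

Both methods fit on the pooled velocity instances of one segment, with the
patient's outcome class attached to each instance.

* **Equal-frequency binning** places boundaries at the 1/k … (k−1)/k
  empirical quantiles (k = 5 by default), using the type-1 / inverse-CDF
  quantile so small-sample results are exactly reproducible. With distinct
  values, bin occupancies differ by at most one. Ties that collapse
  boundaries raise an error advising a smaller k.
* **Entropy/MDL (Fayyad–Irani) discretization** recursively accepts the
  candidate cut (midpoints between adjacent distinct values whose class
  composition differs) with maximal information gain, only when the gain
  exceeds `[log2(N−1) + log2(3^k − 2) − k·Ent(S) + k1·Ent(S1) +
  k2·Ent(S2)]/N`. It may legitimately return a single state — the pipeline
  then records "entropy-based discretization not applicable" for that
  segment and proceeds with equal-frequency binning alone (this is the
  expected outcome for before-nadir pools, whose class-conditional velocity
  distributions are nearly identical).

Intervals are left-open right-closed with unbounded extremes, so a value
exactly on a boundary belongs to the lower state. Fitted boundaries are
always data-dependent outputs, never constants.

## Pattern mining

Patterns are state subsequences — time-ordered, not necessarily
consecutive. The miner is PrefixSpan with pseudo-projected databases;
support counts each sequence at most once (default
`counting_mode="per_sequence"`), with empty sequences excluded from both the
numerator and denominator of class support. Defaults follow the method's
published operating point: minimum support 0.3, maximum length 3. A
`per_instance` mode counts non-overlapping leftmost occurrences against the
total number of state instances (minimum frequency 0.1), which reproduces
the length-one bookkeeping of the pattern-growth worked example. Output
ordering is deterministic (length, then descending support, then
lexicographic) because downstream selection iterates the list. An
exhaustive-enumeration oracle (`brute_force_patterns`) with the same
contract exists purely for verification.

## Predictive selection

Each candidate pattern becomes a per-patient binary feature (1 iff the
patient's segment state sequence contains it; patients without a sequence
count as 0). Folds are stratified by event status and fixed by seed; the
baseline design matrix holds the 14 covariates with one-hot encoding for
drug order and clinical stage, standardized within training folds. The
binary outcome model is L2-regularized logistic regression (scikit-learn);
the time-to-event model is a ridge-stabilized Cox proportional hazards fit
(scikit-survival, ridge α = 1.0 — needed because a good pattern indicator
nearly separates the classes; only the held-out risk *ranking* enters
Harrell's C). Improvements are tested one-sided (augmented > baseline) with
paired t-tests over the 10 fold pairs; a pattern is kept when both mean
improvements are positive and both p-values are ≤ α = 0.05. The published
account of this step is self-contradictory ("patterns that had p ≤ 0.05 were
excluded" versus keeping significant improvers); we keep significant
improvers, which matches the reported result tables. No multiple-testing
correction is applied across candidates, matching the original procedure;
the type-I error of a single comparison is verified empirically instead.
Identical indicator vectors are evaluated once and shared (a pure
computational cache; results are unchanged).

## Informative selection

Among accepted patterns, relative information is a partial order with
structural rules taking precedence over frequency:

1. a pattern carries at least as much information as any of its proper
   sub-patterns (same scheme);
2. for equal lengths, a pattern whose state intervals are elementwise
   subsets of another's carries at least as much information;
3. otherwise the rarer pattern (lower class support by default;
   `frequency_basis="state_instance"` uses products of per-state instance
   frequencies) carries more information; exact ties are incomparable.

Dominated patterns are pruned; remaining ties break by lowest support, then
greatest length, then lexicographic order, with the tie-break path logged.
"Frequency" in rule 3 is pattern class-support by default because the
published result tables report pattern supports; the instance-frequency
basis is provided as a configuration switch since the rule's prose example
uses state instance frequencies.

## Survival comparison

Kaplan–Meier curves and two-group log-rank tests (lifelines) compare the
final pattern (present/absent) with pretreatment PSA (≥ 100 ng/ml), PSA
nadir (≥ 0.2 ng/ml) and time to nadir (≥ 12 months). Nadir and time to
nadir are derived from each patient's measurement series; patients without
measurements are excluded from those two comparisons with a logged reason,
and a dichotomization that empties a group skips that comparison (logged).
Patients lacking an after-nadir sequence are scored pattern-absent rather
than excluded, which keeps n constant across comparisons and matches the
contrapositive logic of the predictive step. Curve points (time, survival,
at-risk) are the canonical output; plotting is left to the caller so the
package runs headless.

## Synthetic cohort generator

No public cohort accompanies the method, so `simulate.generate_cohort`
builds cohorts in which the premise of the discovered pattern is true by
construction, while everything else is deliberately uninformative:

* **Scaffold.** Pretreatment PSA is lognormal (log-mean 4.2, log-sd 1.0 →
  median ≈ 66 ng/ml); the nadir is a heavy-tailed lognormal fraction of it
  (median 2 %, so a realistic minority of patients reach nadir < 0.2
  ng/ml); time to nadir is normal with mean 10.3 and sd 3 months (clipped to
  [3, 20]); visits are spaced uniformly 1–6 months and the nadir snaps to
  the nearest visit. The pre-nadir branch is an exponential-in-time
  interpolation from the pretreatment level to the nadir.
* **Outcome assignment.** Progression is Bernoulli with a logistic model on
  standardized covariates; the intercept is calibrated by bisection so the
  mean probability equals the configured event fraction (0.36). Effect
  directions follow the univariate associations reported for this setting:
  age, Gleason score, bone metastasis and pretreatment PSA increase the
  odds; time to nadir and nadir level decrease them (the nadir direction is
  the reported one even though it runs against the common clinical
  intuition). With all effects zero, outcome and covariates are independent.
* **Post-nadir dynamics.** Every patient fluctuates at visit scale: rises of
  0.3–1.2 ng/(ml·mo) and near-flat drift, both scaled by an amplitude
  proportional to the nadir level (amp = max(1, nadir/5)) since PSA
  fluctuation grows with the level; decline magnitudes stay absolute because
  the mined threshold (0.048 ng/(ml·mo)) is absolute. Non-progressors
  express exactly the configured declines (default 2, each 2–4× the
  threshold, depth drawn once per patient) as a consecutive re-response
  phase near the end of follow-up; follow-up extends past the censoring draw
  if needed so the planted declines always exist. Progressors run the *same*
  iid fluctuation process — so state composition and ordering carry no class
  signal — but never a repeated substantial decline; 75 % show one transient
  decline partway to their event, which keeps single-decline patterns only
  weakly class-associated. The event time is drawn from the doubling-time
  growth schedule, `dt·log2(2.5)` months after the nadir with ±15 % jitter,
  making event times stochastically increasing in the doubling time (mean
  16 months). Progressors are followed to their event; censoring
  (uniform 24–36 months) applies to non-progressors only, so the configured
  event fraction is the observed one. Small additive measurement noise
  (sd 0.02 ng/ml) is applied to all values.

  The symmetric-fluctuation design is load-bearing: if progressors instead
  rise monotonically, then *ordering* patterns (high state before low state)
  discriminate the classes and the informative-selection step — which
  prefers the rarest accepted pattern — returns arbitrary rare patterns
  rather than the planted repeated decline. With the symmetric design the
  pipeline recovers a pattern containing at least two lowest-state labels in
  ≥ 95 % of seeds at n = 300.
* **What the generator does not emulate.** No pharmacokinetics, no assay
  floor or detection limit, no visit-schedule dependence on disease status,
  no clinical progression adjudication, and only a smooth decline before the
  nadir (no before-nadir pattern structure). Passing tests therefore show
  the pipeline recovers planted post-nadir structure under realistic
  sampling/censoring — not that such structure exists in any real cohort.

All randomness derives from one root seed through named substreams
(covariates, scaffold, class, trajectory, noise), so adding a covariate does
not perturb trajectories and identical seeds give identical cohorts.

## Numerical conventions and degenerate inputs

* Boundary membership goes to the lower state (right-closed intervals).
* Support comparisons use a 1e-9 relative guard so exact-threshold patterns
  are kept identically by the miner and the brute-force oracle.
* Equal-frequency fitting refuses pools with fewer distinct values than
  bins, or with ties that collapse boundaries.
* The supervised discretizer returns a single state for single-class or
  constant pools (not an error).
* Paired t-tests with zero-variance differences return p = 0 for a positive
  mean and p = 1 otherwise.
* A CV fold whose training data defeats the Cox fit (no comparable pairs)
  scores C = 0.5 for that fold with a logged warning; folds are re-drawn
  with a shifted seed (up to 10 times) if a split leaves one outcome class
  empty.
* Pipeline outputs are byte-identical under a fixed seed and configuration.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in minutes on one CPU: recovery experiments use 20 cohorts of n = 300;
the type-I-error study uses 200 cohorts of n = 120 with 10-fold CV; oracle
equivalence uses 200 random instances (alphabet ≤ 5, ≤ 60 sequences, length
≤ 8); null log-rank uses 500 permutations of an 80-patient cohort; the
Kaplan–Meier check uses n = 1000 stratified inverse-CDF exponential draws
(the stratification keeps the sample's own Monte Carlo error near 1/n, so
the 0.03 sup-norm tolerance tests the estimator, not the draw).

## Known limitations

* The generator's class signal is concentrated entirely in repeated
  declines; it cannot probe how the pipeline behaves when several competing
  true signals coexist.
* Lemma rule 3 compares supports across classes and schemes on a single
  scale; with near-tied supports the selected pattern can alternate between
  patterns expressing the same clinical statement (e.g. `M→L→L` vs `L→L`).
* No time-gap constraints in mining: a pattern may take arbitrarily long to
  complete, which delays its clinical availability.
* The before-nadir branch is expected to end with "no predictive patterns"
  on generated data, but with small cohorts a borderline pattern can pass
  the unadjusted α = 0.05 joint test — a faithful property of the original
  uncorrected procedure, not a defect of the implementation.
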