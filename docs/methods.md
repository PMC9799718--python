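# Methods

## Phenotype definitions

A visit is classified from its raw measurements alone.

* **Weight category** (Chinese guideline cut-offs): normal 18.5 ≤ BMI < 24,
  overweight 24 ≤ BMI < 28, obese BMI ≥ 28 kg/m²; both bounds closed below,
  open above.  BMI < 18.5 is an eligibility failure, not a category.
* **Metabolic status** (revised NCEP ATP III, abdominal obesity deliberately
  excluded): unhealthy iff ≥ 2 of
  1. SBP ≥ 130 or DBP ≥ 85 mmHg, or on antihypertensive medication;
  2. FPG ≥ 5.6 mmol/L, or 2-h glucose ≥ 7.8 mmol/L, or on hypoglycemic
     medication — an absent 2-h value simply contributes nothing (most
     check-ups do not include an OGTT); a switch can make it required;
  3. TG ≥ 1.7 mmol/L;
  4. HDL-C < 1.0 (male) / < 1.3 (female) mmol/L — strict `<`, as the
     criterion is printed.
* **Covariates**, all binary with strict `>` so the boundary value stays in
  the reference group: female, middle-aged (age > 45 y), ALT > 40 U/L,
  AST > 40 U/L, SCr > 133/106 μmol/L (male/female), UA > 420/360 μmol/L.

Units are fixed (mmHg, mmol/L, U/L, μmol/L); a loader option converts
mg/dL inputs (glucose ÷18.016, TG ÷88.57, HDL ÷38.67, SCr ×88.42) before
classification.  No imputation is performed: a missing required field is an
error at classification time and an exclusion at cohort assembly.

## Cohort assembly

Eligibility rules are applied per subject, in a fixed order so every
exclusion has one primary reason: baseline BMI < 18.5; baseline age outside
[20, 60]; an excluded-disease flag at any visit; missing required baseline
measurements; fewer than two visits.  Visit times are years since each
subject's first visit.  The observed transition table counts **all**
consecutive visit pairs (the inter-visit gap averages ~1 year but is not
forced to be annual); this pooled-pairs convention is what the bundled
reference table reproduces exactly.  Printed-style percentages use decimal
round-half-up at 2 decimals — with banker's rounding one reference cell
(68/4084 = 1.6650 %) would disagree with the printed 1.67.

## The multistate model

Time-homogeneous CTMC on the 2×3 phenotype grid with 14 allowed adjacent
edges; no absorbing state.  P(t) = exp(Qt) is computed by
scaling-and-squaring Padé (`scipy.linalg.expm`), with tiny negative
round-off clipped and rows renormalised (deviations are ≤ 1e-13).  Mean
sojourn time is −1/q_rr; a zero diagonal is reported as an infinite
sojourn rather than an error so degenerate generators remain inspectable.

### Likelihood

For subject i with visits (t_k, s_k) and interval-start covariates z_k,

    ℓ = Σ_i Σ_k log P_{z_k}(t_{k+1} − t_k)[s_k, s_{k+1}],
    Q(z) applied edgewise: q_rs(z) = q_rs(0) exp(β_rs' z).

Covariates enter at the start of each interval (stepwise-constant
time-varying covariates), so e.g. the age group can update as a subject
crosses 45 during follow-up.  Parameters are unconstrained — log
intensities and raw β — which keeps the optimisation smooth and the
intensities positive by construction.

Implementation: intervals are grouped by distinct covariate pattern; for
each pattern's generator one eigendecomposition serves every interval
length (P(t) = V e^{Λt} V⁻¹).  The decomposition is accepted only if it
reproduces Q to 1e-10 relative; otherwise, and for any probability that
comes out below 1e-12 (the eig path cannot resolve entries near round-off),
the entry is recomputed with `expm`.  A transition probability of exactly
zero yields −∞ from the public log-likelihood; inside the optimiser
probabilities are floored at 1e-300 so the penalty stays finite.

### Optimisation and uncertainty

BFGS from crude initial rates (observed direct moves divided by
person-time attributed to the interval's starting state, floored at
1e-3/year for unobserved edges).  Gradients are central differences with
relative step 1e-6; default gradient-norm tolerance 1e-3 and relative-step
tolerance 1e-8.  The `converged` flag reports the optimiser's own status.
The observed information is a central-difference Hessian with step
1e-3·max(1, |θ|): at log-likelihood magnitudes ~1e4 a much smaller step
would be dominated by cancellation error in double precision, while 1e-3
keeps the truncation error far below the sampling uncertainty.  Its inverse
gives the covariance; if inversion fails or yields non-positive variances
the CIs are reported as unavailable rather than fabricated.  All intervals
(intensities, sojourns, hazard ratios) are normal-theory on the log scale,
hence asymmetric on the natural scale.

By default a covariate model puts all requested covariates on all 14 edges
simultaneously (a multiple-variable analysis); univariable fits are just
single-covariate specs.  A stratified-fit convenience refits per baseline
sex × age-group subgroup.

## Goodness of fit

At each grid time t (default yearly, 0–7), the observed prevalence counts
each subject still under observation (last visit ≥ t) at its most recent
observed state; the expected prevalence averages P_z(t)[baseline state, ·]
over the same subjects using baseline covariates.  The denominators shrink
as subjects drop out, mirroring the declining cohort.  The summary is the
max |observed − expected| per state; the assessment is descriptive, no
formal panel-data GOF test is attempted.  The carried-forward /
under-observation conventions are this package's documented choice; with
exactly-annual visits they make the observed series an unbiased multinomial
draw from the expected one, which is what the self-consistency test checks
(3 Monte-Carlo SE bands).

## Synthetic cohort generator

Exact (event-driven) simulation: exponential holding times with rate
−q_rr, destinations with probability q_rs/(−q_rr), truncated at the
follow-up cap — so latent paths are a true CTMC and discretisation cannot
bias oracle comparisons.  Panels read the latent path at jittered visit
times (baseline 0; intervals Normal(1 y, 0.15 y) floored at 0.3 y; at most
8 y of follow-up).

Default study conditions (the reference cohort's printed anchors):

* baseline mix (45.03, 18.08, 3.60, 9.42, 15.93, 7.93)%;
* metabolic deterioration intensities 0.15 / 0.38 / 0.56 per year
  (normal → obese columns) and improvement 0.64 / 0.44 / 0.27 — the 0.44
  is attached to the MUOW→MHOW edge, the only grid-adjacent reading;
* the eight weight-transition rates are **derived, not printed**: each
  state's total exit rate is fixed to the reciprocal of its printed mean
  sojourn (3.84, 1.56, 1.16, 1.23, 1.59, 2.34 y), and the two states with
  two residual exits (MHOW, MUOW) split the budget in proportion to the
  observed transition frequencies.  This derivation reproduces the
  reference cohort's printed 6-year stay probabilities to within ~1
  percentage point, which supports the interpretation;
* covariate prevalences: female 0.5227, middle-aged 0.253 (both printed);
  elevated ALT 0.10, AST 0.05, SCr 0.02, UA 0.15 (not printed; chosen once
  as plausible check-up prevalences);
* visits per subject ∈ {2..8} with probabilities
  (0.24, 0.22, 0.23, 0.12, 0.08, 0.06, 0.05), matching the cohort's two
  printed follow-up anchors (31% with ≥ 5 total check-ups; median
  follow-up ≈ 3 y).

The measurement emitter draws BMI uniformly inside the latent weight
category's interval (obese capped at 32 to stay near the printed medians),
picks how many metabolic criteria are met (healthy: 0–1; unhealthy: 2–4),
chooses which ones at random, and samples each value on the matching side
of its threshold; marker values follow per-subject elevated flags.  By
construction re-classification reproduces the latent states exactly, and
the emitted frame is verified before being returned.  What the generator
does **not** emulate: correlated biochemistry within a visit, measurement
error and regression to the mean around thresholds, secular trends,
state-dependent visit schedules, or covariate-dependent baseline states.
Passing recovery tests therefore show the estimator is correct under the
model's own assumptions — not that a real cohort satisfies them.

## Test problem sizes

The standard recovery experiment is 2,000 subjects × 6 exactly-annual
visits (10,000 intervals), which puts ~9–11% relative sampling SE on the
rates out of the rarest state (MHO, 3.6% of baseline); covariate recovery
uses 4,000 subjects for a single-edge effect and 20 replicates of 1,000
subjects for CI calibration.  The Monte-Carlo cross-checks of the simulator
use 20,000 subjects at a single 1-year lag.  These sizes were chosen as the
smallest at which the checked tolerances are meaningful.

## Known limitations

Time-homogeneous generator (no age/calendar inhomogeneity); no
misclassification (hidden-Markov) layer, so threshold-noise-induced
oscillation in real data would inflate apparent transition rates; no exact
transition times, death, or informative censoring; no model-selection
utilities beyond the reported log-likelihood.  The bundled reference
tables are summary data — subject-level estimates for the real cohort are
not reproducible from them, which is precisely why the synthetic generator
exists.
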