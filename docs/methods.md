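# Methods

This note documents the models, conventions and deliberate design choices
behind each stage of the engine. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohort generator

The generator emulates an administrative cohort of community-dwelling older
adults spread over several facilities, in which transfer from usual primary
care into a geriatric team-care model is driven by *observed* need.

**Covariates.** Age ~ Normal(80, 7²) truncated at 18; race Multinomial(0.124
black, 0.833 white, 0.043 other/missing); female 2%; advance directive 28%;
dementia 3.3%; prior-year hospitalizations Poisson(0.11); CAN score (0–99
percentile predictor of hospitalization/mortality) and JFI (0–13 frailty
index) as correlated truncated normals — Normal(50, 30²) and Normal(4, 2²)
with latent correlation 0.3, clamped to their scales. The correlation is a
knob (no joint distribution is published for these scores; 0.3 is a guess
encoding that both track frailty). Marginals target the enrolled-study
population, so fixtures resemble it.

**Selection into treatment.** Transfer propensity is logistic:

    logit p_i = β₀ + β_age z(age) + β_can z(CAN) + β_jfi z(JFI)
              + β_dem · 1{dementia} + β_hosp z(hosp) + β_u U_i

with z(·) standardized by the configured marginal mean/SD, U_i a
standard-normal *unobserved* confounder (default weight 0, available for
residual-confounding studies), and defaults β₀ = −2.2 (≈10% base rate),
β_age = 0.4, β_can = β_jfi = 0.6, β_dem = 0.8, β_hosp = 0.3. Selection on
observables is the default because the design's validity argument rests on
matching observables. These weights produce unmatched |SMD| of roughly
0.2–0.7 on the selection covariates — imbalance the matching stage must
remove.

**Visits.** Day 0 is the start of the exposure period; the pre-exposure
window is days [−365, 0) and the exposure window [0, 365), both half-open.
Each patient draws max(2, Poisson(6)) visits per window, uniform within the
window; transferred patients' exposure visits are at the treatment clinic.
A 5% `crossover_prob` fraction receives one opposite-clinic visit in the
exposure window, so the eligibility filter has genuine rejections.

**Scale.** The default cohort is 6 facilities × 1,500 patients (9,000 total).
This was chosen so the recruitable candidate pools are deep (median ≈ 80) —
the same order as the design's reported pools — while a full study run stays
under ten seconds. The generator does not emulate: survey-collected
covariates, death or disenrollment during follow-up, facility-level practice
differences beyond the exact-match key, or calendar effects. Passing tests
therefore show the *engine* behaves as specified under the stated selection
model, not that any real cohort is as easy to balance.

## Eligibility

Windows are half-open integer-day intervals; a boundary-day visit belongs to
the later window (avoids double counting; no day-level convention is
standard). Exclusion flags (hospice/palliative care/institutionalized) are
applied at classification, since they are population requirements rather than
recruitment-stage attrition. Rolling pulls use a 91-day ("quarterly") default
cadence with a final pull that sees the whole exposure year; a patient is
emitted at the *first* pull satisfying an arm's criteria and never re-emitted,
mirroring how rolling enrollment locks in decisions. Consequently a later
disqualifying visit cannot retract an earlier emission — the
pulls-partition-the-eligible-set property holds exactly when eligibility is
monotone in information (e.g. no clinic crossovers). The facility filter
counts treatment-clinic visits inside the exposure window against a
configurable volume threshold.

## Matching

- **"Age within 5 years"** is a symmetric pairwise caliper |Δage| ≤ 5 by
  default; "within" reads as proximity, and fixed bins create boundary
  artifacts (an `age_bin_width` option exists for sensitivity analysis).
- **Distance.** The four continuous variables (age, hospitalization count,
  CAN, JFI) are standardized by mean/SD fitted on the control-eligible
  population at the current pull (controls dominate the population; the
  reference is a parameter, not a fact of the design). The default distance
  is Euclidean on the standardized variables — Mahalanobis with diagonal
  covariance; a full-covariance mode (inverse covariance of the standardized
  controls) is available, since published descriptions of such distances
  rarely pin the covariance down. Age participates in both the caliper and
  the distance, exactly as listed in both variable sets.
- **Tiers.** Priority thresholds 0.1, 0.25, 0.5 are continued with 1.0, 2.0
  and an unbounded final tier (a geometric-ish continuation; configurable).
  Bands are half-open: distance exactly 0.1 falls in tier 2.
- **Determinism.** Candidates sort by (tier, distance, control id); the id
  breaks ties so pools are reproducible. Pools are rebuilt at each pull
  against the cumulative control set (configurable choice; freezing at first
  construction is the alternative).
- A control may sit in many pools simultaneously; uniqueness is enforced at
  enrollment, matching the dyadic design.

## Recruitment simulation

Time is discretized to weeks, because the protocol is stated in weeks
(2-week escalation, 5-week window); "days between enrollments" is reported
as 7 × week-lag, with optional uniform within-week jitter (off by default).
Pull k opens at week 13·k (≈ quarterly). All recruitable treated patients of
a pull attempt enrollment at its opening week (probability
`p_enroll_treated`, default 1.0 — the design enrolls treated patients
essentially at will; lower it to study treated-side attrition). On treated
enrollment at week w, tier 1 is open during [w, w+2), tiers ≤ 2 during
[w+2, w+4), and so on; each week up to `contacts_per_week` (default 3, a
guess at per-week telephone capacity) not-yet-attempted candidates in open
tiers are contacted in (tier, distance) order, each enrolling with
probability `confirm_eligible_prob · p_enroll_control` (defaults 1.0 · 0.2,
the expected telephone recruitment rate). Letters and medical-record review
are collapsed into `confirm_eligible_prob`; no separate delay is modeled.
The first enrollment forms the dyad and closes the window; the window closes
unconditionally at w+5. An enrolled control leaves every other pool
immediately. The simulation stops at `target_dyads` (default 275) or pool
exhaustion and emits a replayable event log.

With the default 2-week escalation and 5-week window only tiers 1–3
(distance < 0.5) are reachable; how many dyads form then depends on how
densely the cohort populates those tiers — a geometry that differs between
any synthetic cohort and the real one, which is why the simulator's realized
recruitment statistics (matched fraction, tier shares, day lags) are outputs
to study, not quantities the engine promises to reproduce.

## Balance

Continuous SMD uses the unweighted pooled SD √((s₁²+s₂²)/2) with group 1 the
treated arm — this form reproduces the published matched-table values for
age, CAN and JFI from their printed summaries. Binary SMD replaces variances
by p(1−p). A dyad-adjusted paired SMD (mean difference over SD of
differences) is provided as an option but is not the default, since the
unpaired form is the one that recomputes. Summaries are pairwise-complete
per covariate, with per-group missing counts reported and no imputation;
SMDs render to 2 decimals in the text table and full precision in CSV. Both
denominator-degenerate cases (all-zero SDs with unequal means; proportions
of 0/1 with unequal values) raise a distinct undefined-SMD error, except the
equal-value case which is defined as 0.

## Power

Outcomes are counts of "days not at home" over 18 months. For zero-inflation
π and target marginal mean μ, the component rate is λ = μ/(1−π), so marginal
means are matched exactly (the design speaks of what patients "average", a
marginal statement). ZIP moments E[Y] = (1−π)λ and Var[Y] = (1−π)λ(1+πλ) are
verified empirically in the suite. The ZINB component is NB2 with shape k;
its marginal variance exceeds the ZIP's by λ²(1−π)/k, giving the closed-form
calibration k = (1−π)λ² / ((r−1)·Var_ZIP) for a target variance ratio r
(e.g. r = 12, the "variance up to 12×" scenario; readings of "12×" other
than a variance ratio can be explored by setting `nb_dispersion` directly).

Clustering: dyad partners share a facility; facilities carry a mean-preserving
log-normal frailty exp(u − σ²/2), u ~ N(0, σ²), with σ² chosen so that the
between-cluster share of the count variance is icc/(1−icc) times the
within-cluster (ZIP/ZINB) variance — the package's operational definition of
the ICC on the count scale. Defaults π = 0.3, icc = 0.05 over 57 clusters,
and analysis = zero-inflated count regression (statsmodels) with a
cluster-robust Wald test on the count-model treatment coefficient are
*reconstruction choices*: no published value exists for any of them, and each
is a config knob. Alternative analyses: cluster-robust Poisson GLM and a
paired Wilcoxon signed-rank on dyad differences.

Replicates whose fit fails (non-convergence, non-finite p-value) are excluded
from the rejection fraction — counting them as non-rejections would bias
power downward for reasons unrelated to the design — with a hard error if
more than 10% fail. Default 1,000 replicates give a Monte-Carlo SE ≤ 1.6
percentage points; `power_curve` reuses one seed across the n-grid (common
random numbers) so the curve is monotone up to residual noise.

## Numerical conventions and degenerate inputs

- All randomness flows through numpy `Generator`s; configs carry seeds and
  the pipeline splits one global seed into per-stage substreams
  (`SeedSequence.spawn`), so stages are independently reproducible.
- Standardizer SDs use ddof = 1; a zero-variance matching variable is an
  error naming the variable (matching in a population with a constant
  matching variable is a configuration problem, not a numerical one).
- Empty pools are valid (flagged non-recruitable); empty dyad sets produce
  empty summaries, not errors; an empty arm in a balance comparison is a
  degenerate-input error.
- Pool-size median and range are reported over *all* pools, with a second
  median conditional on recruitability, since the headline "median pool"
  statistic of such designs conditions on having enough matches.

## Known limitations

- The recruitment clock is weekly and pull-synchronized; staggered
  within-pull treated enrollment and day-level contact timing are not
  modeled.
- The ZINB 80%-power scenario depends on dispersion/ICC/analysis choices
  that have no published values; the module exposes it as an exploration
  surface rather than asserting any particular number.
- Balance of survey-collected covariates unavailable at matching time — a
  key empirical argument for the design — cannot be demonstrated on
  synthetic cohorts unless such covariates are added to the generator and
  correlated with the selection model.
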