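# Methods

`ehrtrial` implements a target-trial-emulation workflow for longitudinal EHR
data — cohort construction from an explicit PICOT specification, pre-baseline
feature aggregation, four causal estimators with cross-fitted machine-learning
nuisances, sensitivity ("vibration") sweeps over analytic choices, and
conditional-effect estimation — together with a synthetic ICU generator whose
causal ground truth is known exactly. This note records the models, the
defaults and why, and what the synthetic benchmarks do and do not show.

## The estimation problem

For a binary treatment A (albumin added to crystalloids), binary outcome Y
(28-day death) and pre-baseline covariates X, the estimand is the average
treatment effect on the risk-difference scale,

    ATE = E[Y(1)] − E[Y(0)],

with risk-ratio and odds-ratio transforms derived from the two arm means.
Identification assumes ignorability given X, positivity (checked with the
overlap diagnostic — the only testable assumption), and consistency. The
nuisances are the propensity e(X) = P(A=1|X) and the arm-specific outcome
regressions μ₁(X), μ₀(X), fit as ridge logistic regressions (with feature
standardisation) or random forests.

Estimators:

- **naive** — difference of raw arm means; always computed as the bias
  reference.
- **IPW (Hajek)** — self-normalised weighted arm means, weights A/ê and
  (1−A)/(1−ê); self-normalisation bounds the estimate in [−1, 1].
- **G-formula (T-learner)** — mean of μ̂₁(X) − μ̂₀(X) over the whole cohort.
- **AIPW** — mean of the influence-function pseudo-outcome
  ψ = μ̂₁ − μ̂₀ + A(Y − μ̂₁)/ê − (1−A)(Y − μ̂₀)/(1−ê); doubly robust, and ψ is
  retained per patient as the DR-learner signal for heterogeneity.
- **DML (partially linear)** — cross-fitted residual-on-residual slope of
  (Y − m̂(X)) on (A − ê(X)). Reported on the risk-difference scale even though
  the outcome is binary; this mirrors common package behaviour and identifies
  only the constant-effect analogue, so no arm means or ratio estimands.

All nuisances are cross-fitted with K = 5 folds stratified on the arm
(out-of-fold predictions only); propensities are clipped to [0.01, 0.99]
(configurable; the clipped count feeds the overlap diagnostic). Confidence
intervals are patient-level nonparametric bootstrap percentiles with the
nuisances refit on every resample; B = 50 by default, which is small — the
interval endpoints are themselves noisy below B ≈ 200, so raise B when
runtime allows. Hyperparameters can be tuned by random search (default
budget 10 draws, 3-fold CV inside each training fold, ridge penalty
log-uniform, forest depth/trees/min-leaf ranges); the benchmark experiments
use fixed defaults instead (below) because search inside a bootstrap is
disproportionately expensive.

Default forest: 30 trees, depth ≤ 8, min leaf 50, 70% features per split,
20% subsampling per tree. The subsampled shallow configuration keeps
probability estimates smooth and well calibrated at cohort scale (n ~ 10⁴)
and is cheap enough to refit 50 times inside a bootstrap; deeper or fuller
forests were not measurably less biased on the generator but are several
times slower.

## The synthetic cohort generator

One latent severity score z ~ N(0,1) drives everything clinical: a SOFA-like
integer score (6 + 3.5z, rounded and clipped to 0–24, re-measured with unit
noise), a log-normal lactate correlate, vasopressor/ventilation use, and the
odds of 28-day death (log-odds coefficient 1.0 per SD by default, plus age,
emergency admission and septic-shock terms; intercept calibrated by
root-finding so the marginal untreated mortality hits its target, 0.28 by
default). Septic shock is simulated independently of z and carries its own
direct effects, so the severity-exchangeability property under zero
confounding is exact.

Treatment assignment conditions on the *recorded* admission SOFA (the t = 0
measurement row), not the latent z: clinicians act on charted values. This
makes ignorability given the tables exact while severity confounding
persists through the latent score (the recorded value is a noisy proxy of
the biology that kills). The intended-treatment propensity is logistic in
the recorded score (coefficient `confounding_strength`, default 0.5 per SD),
emergency admission (−1.1; emergency patients receive albumin less often)
and septic shock (+0.8), with the intercept calibrated so the *realised*
treated fraction — after the survival coupling below — matches the target
(0.19 by default, the treated share of the application cohort the package
emulates).

Potential outcomes are parameterised on the risk-difference scale:
p₁ = clip(p₀ + ATE + modifier increments, [0.001, 0.999]), with binary
modifiers age ≥ 60, male and septic shock. Y(0), Y(1) are coupled through a
shared uniform, so a zero configured effect is a per-patient null, not just
a population null.

Deaths that occur are timed by a log-normal conditional-on-death
distribution (log-mean 3.9, log-SD 0.6 hours from follow-up start; median
≈ 2 days, ~12% of 28-day deaths inside day one), truncated at the horizon,
reflecting the front-loaded mortality of severe sepsis. An exponential
hazard was rejected: with a constant hazard essentially no deaths fall in
the first days, and the immortal-time mechanism below would be numerically
invisible at desk scale. The parameters were calibrated by power analysis so
that the eligibility-window experiment resolves its per-window steps against
Monte-Carlo noise at the window-experiment scale.

The immortal-time coupling is the generator's deliberate design flaw: a
patient intended for treatment with delay D (uniform over 24 h by default,
72 h in the window experiment) is actually treated only if their latent
untreated death time exceeds D. Treated patients are therefore survivors by
construction, and any cohort definition that labels late starters as treated
inherits a protective artefact that no covariate adjustment can remove.

Missingness is completely at random per measurement row (25% by default,
matching the lactate missingness of the emulated application); the admission
SOFA row is exempt because a severity score is computed, not drawn — the
application cohort reports zero missing SOFA. Informative missingness is out
of scope.

What the generator does **not** emulate: informative censoring and
attrition, time-varying treatment or dosing, informative measurement timing,
coded diagnoses/comorbidities, free-text, and the schema detail of real
ICU databases. Passing benchmarks here shows the estimators and design machinery
behave as claimed under a known, well-posed data-generating process — not
that any given real-world analysis is unconfounded.

## Cohort building and aggregation

Follow-up starts at the first anchor event (crystalloids). Inclusion: age
≥ 18, anchor present, follow-up (last-seen minus anchor) ≥ 24 h; every
exclusion is a flowchart row and the counts telescope exactly. The treated
arm is defined by the treatment event inside the half-open window
[t0, t0 + W) — half-open because "during the first 24 hours" needs a
boundary convention and half-open windows avoid double counting. Patients
dying inside the window before treatment stay in the control arm
(intention-to-treat-like labelling); this is precisely what produces the
immortal-time artefact, so it must not be silently "fixed". Patients last
seen alive before the 28-day horizon count as alive (no censoring model).

Measurements are aggregated per patient strictly before the follow-up start
(`first`, `last`, `first_and_last`, `mean`); `first_and_last` is the
headline strategy in the benchmarks. The leakage guard is absolute:
deleting every post-baseline event never changes the feature matrix (tested
as an invariant). Numerics are median-imputed (medians fit on the analysis
matrix and recorded for reuse), categoricals one-hot encoded with the
reference level dropped. Ties at identical timestamps break by input record
order, which the deterministic readers fix.

Confounder subsets for the vibration axis are defined by provenance groups:
`full`; `no_drugs` (drops antibiotic/vasopressor/ventilation indicators);
`no_biology` (drops severity and lab aggregates); `sociodemographic_only`
(age, sex, race, emergency admission). The memberships are this package's
declaration, not an inferred list.

## Heterogeneity

The DR-learner regresses the cross-fitted AIPW pseudo-outcomes ψ on
candidate effect modifiers (ridge final model by default, forest optional);
fitted values are per-patient effect predictions τ̂(x) on the risk-difference
scale, and with an intercept-bearing final model mean(τ̂) equals the AIPW
ATE exactly. The four default binary modifiers are age ≥ 60, male sex,
septic shock, and white vs non-white race; the final model uses modifiers
only (a switch admits all covariates). Modifiers tagged post-treatment are
refused. Subgroup summaries are box statistics: median, 25th/75th
percentiles (linear interpolation — quartile dialects differ, so the
convention is recorded), whiskers at 1.5 × IQR clipped to observed values.

## Benchmark experiments and problem sizes

The `experiments` module runs each study end to end on fresh simulations;
`tests/test_acceptance.py` asserts the claims and `scripts/acceptance.py`
recomputes the numbers. Sizes were chosen by power analysis so each effect
resolves against Monte-Carlo noise while the whole suite stays desk-scale:

- Null recovery: n = 10,000, AIPW + forest, B = 50, 10 seeds (6 in the
  script). The mean estimate is the bias check (per-seed sampling SE is
  ≈ 0.011, so per-seed magnitudes mostly reflect noise); interval coverage
  of zero is per-seed.
- Double robustness: n = 20,000, 5 seeds, one nuisance replaced by a
  constant at a time.
- Immortal time: n = 30,000, delays uniform on [0, 72] h, windows
  {24, 48, 72} h, G-formula path (smallest between-window noise), 10 seeds.
- Confounder omission: n = 10,000, 3 seeds.
- Effect-modification recovery: n = 20,000, 10 seeds, planted increments
  {shock −0.05, age ≥ 60 −0.03, male −0.02}.
- Bootstrap coverage: n = 2,000, B = 50, 100 repetitions.

### A power caveat on the shock-gap tolerance

The recovery check asks the DR-learner shock gap to land within ±0.02 of
the planted −0.05 in ≥ 90% of seeds at n = 20,000. The sampling SD of that
gap is bounded below by the semiparametric efficiency bound at roughly
0.014–0.019 given ~19% treated and ~27% mortality, so the per-seed success
probability is ≈ 0.70–0.75 and the ≥ 90%-of-seeds requirement cannot hold in
expectation at this design; no estimator choice can beat the bound. The
check is implemented as stated and is expected to fail honestly; the sign
recovery of all three modifiers, which is comfortably powered, is the
meaningful part.

On interval widths: on the default simulation (forest nuisances, n = 5,000,
B = 30, three seeds) the median bootstrap interval is narrowest for AIPW
(0.044), then IPW (0.047), then the G-formula T-learner (0.048) — the
doubly robust estimator is the most precise — but the differences sit
inside Monte-Carlo noise at this scale, so the ordering is reported here
rather than asserted as a test.

## Numerical choices and degenerate inputs

Propensity clipping at [0.01, 0.99]; an overlap flag trips when clipped
mass exceeds 1%. Cross-fitting refuses K < 2 and single-arm training folds.
Bootstrap replicates that degenerate (single-arm resamples) are dropped and
counted; > 20% dropped is an error. Arm means on the boundary make RR/OR
undefined and raise rather than returning infinities. Degenerate
eligibility windows (→ 0⁺) legitimately empty the treated arm. Intercept
calibrations use bracketed root-finding on [−30, 30] log-odds. Vibration
cells get deterministic seeds from a CRC of their provenance string XOR the
master seed, so any cell can be reproduced in isolation; cell failures are
recorded as rows, never aborting the grid.

## Known limitations

No censoring or competing risks; hazard-based estimands are out of scope.
The DML risk-difference analogue is a partially linear approximation for a
binary outcome. B = 50 intervals are noisy. Median imputation is fit once
on the analysis matrix (the simple reading of the emulated application), a
known caveat for resampling-based inference; the
`refit_imputation_per_resample` switch re-imputes inside every bootstrap
replicate for strict resampling inference, at extra cost and off by
default. Hourly-binned time-series featurisation and super-learner
stacking are not implemented.
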