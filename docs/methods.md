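# Methods

## The identification problem and the estimators

Age, period and cohort satisfy `A = P − C` exactly, so an APC regression on
all three is rank deficient.  Both estimators in this package assume the
entire period effect is carried by a known mediator set (front-door
identification), that the mediators are conditionally independent given
their modelled parents, and that mediator-outcome confounding is either
absent or controlled.

**Path tracing** (`apcmech.pathtrace`).  Mediator models (Step 1) and the
outcome model (Step 2) are fitted by OLS or probit/logit GLMs through
statsmodels.  With categorical time dimensions the scalar product rule
generalises to one product per (mediator, category) pair: the period effect
for category *k* is `Σ_m γ̂_{m,k} · δ̂_m`, summed over mediators; age and
cohort effects are the outcome model's dummy coefficients plus any mediated
contributions (e.g. age→BMI in the *more causes* scenario).  The rule is
exact for linear models.  For probit models the products live on the latent
scale; for *binary* mediators the latent-scale product overstates the
mean-scale mediated effect by roughly the inverse link slope (~2.5–3× at
the prevalences used here), so probit output is flagged as a latent-scale
approximation.  Logistic fits and product terms are refused outright and
redirected to the Monte Carlo estimator.

**Monte Carlo integration** (`apcmech.mcfrontdoor`).  Steps 3–5 simulate
mediators from the Step-1 fits, simulate potential outcomes from the Step-2
fit over independently drawn category triples (the identity deliberately
broken; a draw design that reproduces it is rejected, and the Step-5 design
is rank-checked), and refit an ordinary APC dummy regression with the
family matching the outcome type.  This estimator is consistent for the
marginal causal estimand for any parametric family, including logistic
links and interactions (`extra_columns_fn` applies the same constructed
covariates in fitting and in simulation).

Numerical choices:

- **Draw design.** Default is a full factorial over all
  `n_age × n_period × n_cohort` category triples (825 in the default
  scheme), replicated to the requested draw count; balanced designs have
  lower variance than uniform random draws (also available).
- **Common random numbers.** For linear-family outcomes the same
  standardized noise draws are reused in every factorial cell, so Monte
  Carlo noise cancels exactly out of coefficient contrasts — this makes the
  linear-setting equality between the two estimators exact at finite draw
  counts.  For binary outcomes no such cancellation exists and coupling
  would invalidate the independence assumptions behind the reported Monte
  Carlo standard errors, so it is disabled there.
- **Monte Carlo error.** Within one call the first-stage fits are fixed, so
  the Step-5 coefficient standard errors measure pure simulation noise;
  they are reported in an `mc_se` column and shrink as draws grow.
- **Uncertainty.** Nonparametric bootstrap (default B = 500 for path
  tracing, percentile intervals; the MC draw seed is held fixed across
  replicates so the spread reflects data resampling only).  The
  delta-method SE is exposed only for single-pathway linear settings.
  Replicate failures are dropped and counted; more than 10 % aborts.

## The synthetic cardiovascular-mortality generator

`apcmech.datagen` emulates an APC mortality study: n individuals (default
100,000) with age ~ U(40, 95) and period ~ U(1990, 2015), categorised into
five-year groups (11 age, 5 period, 15 overlapping cohort categories; the
range maxima close the last bins, so birth years 1895–1975 arise but the
boundary cohort categories are simply the extreme index values).  The
binary CVD-death outcome is drawn from a probit or logistic model — or, in
the linear variant, the latent index plus Gaussian noise (σ_Y = 1) is
observed directly as a continuous risk score.

Four period mediators carry the whole period effect, with the sign
structure: unmeasured (continuous, period effect negative/linear, outcome
effect positive), BMI (continuous, positive S-curve, positive), smoking
(binary, negative S-curve, positive), statin (binary, positive S-curve,
negative).  Measured-mediator period curves are scaled logistic S-curves of
the period index — the simplest monotone nonlinear form.  Binary mediator
curves are anchored to plausible prevalences (smoking 45 %→15 %, statin
2 %→30 % across 1990–2015); BMI rises 2 units around a mean of 25 with
residual SD 1.5 (kept modest so that mediator dispersion does not let
probit non-collapsibility dominate latent-scale comparisons between nested
outcome models); the unmeasured bundle has unit slope and unit noise.

**Calibration ("percent of effect").**  Effect shares are variance shares
of each pathway's *systematic* contribution to the latent linear predictor
(mediator noise excluded, cross-pathway covariances not apportioned),
computed exactly on the age × period category grid.  Defaults: age 70 %,
period 20 % (split 40/20/20/20 over unmeasured/BMI/smoking/statin), cohort
10 %.  The absolute latent scale is anchored by baseline-risk targets —
mean outcome ≈ 0.5 % in ages 40–44, with the direct age gradient spanning
to 20 % at the top age on the link scale, mimicking high-income-country
CVD mortality; the intercept is tuned by root-finding on a fixed-seed
internal sample (realized top-age risk lands somewhat below the nominal
anchor because mediator dispersion flattens the link).  Age is positive,
cohort negative, and the net period effect negative, consistent with the
sign table.  The total latent variance implied by the default shares is
held fixed when shares are swept, so effect-size sweeps change the split,
not the overall scale.

Scenario extras:

- *more causes*: age→BMI is sized so the BMI-mediated age variance is 30 %
  of the total age variance (this is a probability-scale quantity — BMI is
  continuous, so latent and realized scales coincide).  Cohort→smoking is
  sized on the **latent** scale (the latent slope product carries 30 % of
  the nominal cohort variance) because the inverse-link slope compresses
  the realized contribution ~3×; sizing it on the realized scale would make
  the estimated cohort bias as large as the age bias, contradicting the
  qualitative pattern the generator is built to reproduce (age bias
  dominant, period essentially unbiased).  The direct cohort slope is
  topped up so total realized cohort variance keeps its share.
- *confounding*: a genotype (Bernoulli, prevalence 50 %, independent of the
  time dimensions) raises BMI (+3 units), smoking (+15 prevalence points at
  the period midpoint) and mortality.  Its outcome effect is sized so
  `Var(δ_g·G)` equals one third of the total age-contribution variance —
  one defensible reading of "accounts for roughly a third of the age
  association"; the analogous 35 % cohort figure cannot hold simultaneously
  and is treated as a diagnostic, not a constraint.

Reproducibility: one seed sequence per `generate()` call, with per-variable
child streams, so datasets are byte-identical across runs and robust to
scenario-specific extra variables.

**What the generator does *not* emulate:** longitudinal follow-up (each
individual is observed once), competing risks, measurement error in the
mediators, real mortality-registry age structure, or secular trends beyond
monotone period curves.  Passing tests therefore demonstrate the
estimators' behaviour under a controlled front-door data-generating
process, not performance on registry data.

## Omitted-dimension and omitted-mediator bias algebra

`apcmech.biastheory` implements the exact reattribution identities of the
linear associational model: dropping period yields expected coefficients
`(α+β, θ+β)` in the age-cohort model (the period effect split equally);
dropping age yields `(β+α, θ−α)`; dropping cohort `(α−θ, β+θ)`.  Omitting a
period mediator adds its slope product γ·δ to both the age and cohort
slopes and removes it from the recovered period slope; opposite-sign
products cancel.  The forms are written for scalar slopes; with equal-width
categories they govern the linear component of the dummy profiles, which is
why the harness summarises bias as a fitted linear trend across categories.
They are exposed for linear settings only — in probit/logistic variants the
harness demonstrates the bias empirically instead.

## Experiment harness and problem sizes

`apcmech.harness` runs scenario × variant × mis-specification grids with a
per-cell, per-replication seed ledger.  Bias is computed against the
correctly specified cell's mean estimate — the operational truth at large
n — never across link functions (probit and logistic grids are not
numerically comparable).  The default estimator is path tracing for
probit/linear variants and Monte Carlo integration for logistic.

The default scale is a desk preset (20 replications of n = 20,000; sweeps
use the same), at which all documented bias directions and monotonicity
patterns are stable; the full-scale design (1,000 × 100,000) is available
via `ExperimentSpec.paper_scale()`.  The test suite uses 20 × 20,000 for
the direction and sweep suites, n = 100,000 with four replicate datasets
per cell for correct-specification recovery (compared in root-mean-square
against a 600,000-draw estimand oracle computed by running the Monte Carlo
integration with the generator's true coefficients), and one million
factorial draws for the linear-setting equivalence check.

## Known limitations

- Probit path tracing reports latent-scale quantities; with binary
  mediators these are systematic overstatements of the marginal estimand
  (use `mcfrontdoor` when that matters).
- The delta-method SE covers only the single-pathway linear case; all other
  settings use the bootstrap.
- Equal-width bins only; no Lexis-triangle handling, no continuous-time
  APC modelling, no relaxation of the mediator-independence assumptions.
- The closed-form bias algebra does not cover collider-stratification bias
  (demonstrated by simulation only).
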