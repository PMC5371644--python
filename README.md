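# apcmech — mechanism-based age-period-cohort estimation

Age-period-cohort (APC) analysis tries to decompose an outcome's temporal
variation into effects of age *A*, calendar period *P* and birth cohort *C*.
Because `A = P − C`, the associational model

    E(Y | A, P, C) = η + α·A + β·P + θ·C

has infinitely many solutions.  The *mechanism-based* approach resolves this
through Pearl's front-door criterion: if one dimension's entire effect runs
through a measured set of mediators M₁ … M_K, its effect can be recovered
indirectly (from mediator models) while the other two are estimated
directly.  For period mediated by M, the two-step recipe is

    Step 1 (per mediator):  M = γ₀ + γ₁·P + ν
    Step 2 (outcome):       Y = δ₀ + δ₁·A + δ₂·C + δ₃·M + ξ

with `α̂ = δ̂₁`, `θ̂ = δ̂₂` and `β̂ = Σ_m γ̂₁,m · δ̂₃,m` (Wright's
path-tracing product-of-coefficients rule).  That rule is exact for linear
models and latent-scale probit models, and invalid for logistic links or
product terms.  For those cases the package implements a Monte Carlo
integration extension (a parametric g-formula): simulate mediators from the
Step-1 fits, simulate potential outcomes `Ỹ(ã, p̃, c̃)` from the Step-2 fit
over **independently** drawn age/period/cohort categories — deliberately
breaking the `a = p − c` identity — and fit an ordinary, now identifiable,
APC dummy regression to the simulated data.  Standard errors come from the
nonparametric bootstrap (percentile intervals).

The package is aimed at demographers and epidemiologists who want to apply,
or stress-test, mechanism-based APC estimation.  It ships:

- `apcmech.core` — five-year age/period categorisation, overlapping cohort
  categories (`n_cohort = n_age + n_period − 1`), dummy coding, identity
  validation, delimited-text I/O;
- `apcmech.datagen` — a calibrated synthetic cardiovascular-mortality
  generator (ages 40–95, years 1990–2015, binary CVD-death outcome, four
  period mediators: a continuous *unmeasured* bundle, BMI, smoking and
  statin therapy, in probit/logistic/linear variants and three bias
  scenarios: *simple*, *more causes*, *confounding* by a genotype);
- `apcmech.pathtrace` — the classical estimator with delta-method and
  bootstrap uncertainty;
- `apcmech.mcfrontdoor` — the Monte Carlo integration estimator;
- `apcmech.biastheory` — closed-form expected coefficients for
  omitted-dimension models (age-cohort, period-cohort, age-period) and
  omitted-mediator bias;
- `apcmech.harness` — replicated scenario × variant × mis-specification
  experiments and effect-size sweeps.

## Worked example

Generate the default *simple* world (probit variant, n = 100,000; age set
to carry 70 % of the APC effect, the period mediators 20 %, cohort 10 %),
then estimate with and without the unmeasured mediator:

```python
from apcmech import datagen, pathtrace

cfg = datagen.ScenarioConfig(scenario="simple", variant="probit",
                             n=100_000, seed=1)
params = datagen.calibrate(cfg)
ds = datagen.generate(cfg, params)

print(datagen.attribution_shares(params, ds).as_tuple())
# (0.700, 0.200, 0.100)

est = pathtrace.estimate(ds)
print(est.values("period").round(3))
# [ 0.    -0.649 -1.571 -2.518 -3.156]   <- per period category, probit scale

mis = pathtrace.estimate(ds.drop_mediators(["unmeasured"]))
print(mis.values("period").round(3))
# [ 0.    -0.525 -1.324 -2.146 -2.663]   <- period bias: upward (less negative)
```

The mediated period effect is negative (falling smoking, statin uptake and
the unmeasured bundle outweigh rising BMI).  Dropping the unmeasured
mediator removes a negative pathway: the period estimates are biased upward
while the age trend flattens from a slope of 0.168 to 0.048 per five-year
category — the omitted period effect is reattributed to age and cohort, as
the closed-form algebra in `apcmech.biastheory` predicts:

```sh
$ apcmech bias expected --alpha 1 --beta 0.5 --theta 0.2 --model age-cohort
age: +1.5
cohort: +0.7
```

The same CLI covers generation, estimation and experiments:

```sh
apcmech simulate --scenario confounding --n 100000 --seed 1 --out data.csv
apcmech estimate mc --data data.csv --confounder genotype --draws 1000000 \
    --bootstrap 100 --seed 1 --out estimates.csv
apcmech experiment run --out results/
```

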