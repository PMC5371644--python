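"""Calibrated synthetic cardiovascular-mortality data generator.

The generator emulates an APC study of CVD death: individuals aged 40-95
observed in calendar years 1990-2015 (drawn uniformly, then categorised into
five-year groups), a binary death outcome, and four mediators that carry the
entire period effect:

=========== =========== ================= ==================
mediator     type        period -> M       M -> outcome
=========== =========== ================= ==================
unmeasured   continuous  negative (linear) positive
bmi          continuous  positive (S-curve) positive
smoking      binary      negative (S-curve) positive
statin       binary      positive (S-curve) negative
=========== =========== ================= ==================

Three scenarios are supported:

* ``simple`` - age and cohort act directly on the outcome, period acts only
  through the four mediators;
* ``more_causes`` - additionally, age has a negative effect on BMI and
  cohort a positive effect on smoking;
* ``confounding`` - a genotype (prevalence 50 %, independent of the time
  dimensions) raises BMI, smoking and CVD mortality, confounding the
  mediator-outcome relationships.

Each scenario comes in ``probit``, ``logistic`` and ``linear`` variants.  In
the linear variant the latent index itself (plus Gaussian noise) is the
observed continuous outcome; binary mediators are then generated with probit
links.

Calibration targets "percent of effect" statements as *variance shares*: the
variance, across the population, of each pathway's systematic contribution
to the latent linear predictor (mediator noise excluded; cross-pathway
covariances not apportioned).  By default age accounts for 70 % of the total
APC variance, the period-mediated pathways for 20 % and cohort for 10 %,
with the period share split 40/20/20/20 across
unmeasured/BMI/smoking/statin.  The absolute latent scale is anchored so the
direct age gradient spans baseline risks of roughly 0.5 % (ages 40-44) to
20 % (top age category) on the outcome link scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit as logit_q
from scipy.stats import norm

from .core import APCDataset, CategoryScheme, DEFAULT_SCHEME, categorize

SCENARIOS = ("simple", "more_causes", "confounding")
VARIANTS = ("probit", "logistic", "linear")
MEDIATOR_ORDER = ("unmeasured", "bmi", "smoking", "statin")

# prevalence anchors for the binary mediators over the period range
# (first -> last period category); chosen to mimic falling smoking rates and
# the introduction of statin therapy in high-income countries, 1990-2015
SMOKING_PREV = (0.45, 0.15)
STATIN_PREV = (0.02, 0.30)
BMI_BASE, BMI_RISE, BMI_SD = 25.0, 2.0, 1.5
UNMEASURED_SLOPE, UNMEASURED_SD = -1.0, 1.0
# genotype effects (confounding scenario): shift in BMI units, shift in
# smoking prevalence at the period midpoint, and outcome-effect variance as
# a fraction of the total age-contribution variance (the "roughly one third
# of the age association" anchor)
GENOTYPE_BMI_SHIFT = 3.0
GENOTYPE_SMOKING_PREV_SHIFT = 0.15
GENOTYPE_AGE_VAR_RATIO = 0.33


class CalibrationError(ValueError):
    pass


def _inv_link(link: str):
    return {"probit": norm.cdf, "logit": expit}[link]


def _q_link(link: str):
    return {"probit": norm.ppf, "logit": logit_q}[link]


@dataclass(frozen=True)
class MediatorSpec:
    """Declarative description of one mediator's role in the causal graph."""

    name: str
    kind: str  # continuous | binary
    sign_period_to_m: int
    sign_m_to_y: int
    form: str = "linear"  # linear | sigmoid

    @property
    def sign_period_to_y(self) -> int:
        return self.sign_period_to_m * self.sign_m_to_y


PAPER_MEDIATORS = (
    MediatorSpec("unmeasured", "continuous", -1, +1, "linear"),
    MediatorSpec("bmi", "continuous", +1, +1, "sigmoid"),
    MediatorSpec("smoking", "binary", -1, +1, "sigmoid"),
    MediatorSpec("statin", "binary", +1, -1, "sigmoid"),
)


@dataclass(frozen=True)
class ScenarioConfig:
    """A data-generating world: scenario, link variant, sample size, shares."""

    scenario: str = "simple"
    variant: str = "probit"
    n: int = 100_000
    seed: int = 0
    shares: tuple[float, float, float] = (0.70, 0.20, 0.10)  # age, period, cohort
    mediator_shares: Mapping[str, float] = field(
        default_factory=lambda: {"unmeasured": 0.40, "bmi": 0.20, "smoking": 0.20, "statin": 0.20}
    )
    age_to_bmi_share: float = 0.30
    cohort_to_smoking_share: float = 0.30
    genotype_prevalence: float = 0.50
    baseline_risk_targets: tuple[float, float] = (0.005, 0.20)
    sigma_y: float = 1.0  # linear variant only

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.n <= 0:
            raise ValueError("n must be positive")
        s = np.asarray(self.shares, dtype=float)
        if s.min() < 0 or s.max() > 1 or abs(s.sum() - 1.0) > 1e-8:
            raise CalibrationError(f"APC shares must lie in [0,1] and sum to 1, got {self.shares}")
        ms = np.asarray(list(self.mediator_shares.values()), dtype=float)
        if ms.min() < 0 or abs(ms.sum() - 1.0) > 1e-8:
            raise CalibrationError("mediator shares must be nonnegative and sum to 1")
        for frac in (self.age_to_bmi_share, self.cohort_to_smoking_share,
                     self.genotype_prevalence):
            if not 0 <= frac <= 1:
                raise CalibrationError(f"fraction {frac} outside [0,1]")
        lo, hi = self.baseline_risk_targets
        if not (0 < lo < hi < 1):
            raise CalibrationError("baseline risk targets must satisfy 0 < low < high < 1")


@dataclass
class MediatorParams:
    """Generator-side coefficients for one mediator.

    The systematic period curve is ``slope * p_idx`` (linear form) or
    ``amp * expit(p_idx - center)`` (monotone S-curve); for binary mediators
    the curve lives on the link (latent) scale.
    """

    name: str
    kind: str
    form: str
    delta: float  # mediator -> outcome coefficient (latent outcome scale)
    intercept: float = 0.0
    slope: float = 0.0
    amp: float = 0.0
    sigma: float | None = None  # continuous only
    age_coef: float = 0.0
    cohort_coef: float = 0.0
    genotype_coef: float = 0.0
    link: str | None = None  # binary only

    def period_curve(self, p_idx: np.ndarray, center: float) -> np.ndarray:
        p_idx = np.asarray(p_idx, dtype=float)
        if self.form == "linear":
            return self.slope * p_idx
        return self.amp * expit(p_idx - center)

    def latent(self, p_idx, center, a_idx=0.0, c_dev=0.0, g=0.0) -> np.ndarray:
        return (self.intercept + self.period_curve(p_idx, center)
                + self.age_coef * np.asarray(a_idx, dtype=float)
                + self.cohort_coef * np.asarray(c_dev, dtype=float)
                + self.genotype_coef * np.asarray(g, dtype=float))

    def mean(self, p_idx, center, a_idx=0.0, c_dev=0.0, g=0.0) -> np.ndarray:
        """Conditional mean of the mediator given its parents."""
        lat = self.latent(p_idx, center, a_idx, c_dev, g)
        return _inv_link(self.link)(lat) if self.kind == "binary" else lat

    def period_mean(self, p_idx, center) -> np.ndarray:
        """Conditional mean as a function of period alone (other parents at reference)."""
        return self.mean(p_idx, center)


@dataclass
class GeneratorParams:
    """Fully calibrated coefficients realising a :class:`ScenarioConfig`."""

    config: ScenarioConfig
    scheme: CategoryScheme
    alpha: float  # direct age slope per age category, latent scale
    theta: float  # direct cohort slope per cohort category, latent scale
    eta: float  # outcome intercept, latent scale
    mediators: dict[str, MediatorParams]
    delta_genotype: float = 0.0
    sigma_y: float | None = None  # linear variant only
    v_total: float = 0.0  # total latent APC variance the shares refer to
    p_center: float = 0.0
    c_mean: float = 0.0

    @property
    def variant(self) -> str:
        return self.config.variant

    @property
    def outcome_link(self) -> str | None:
        return {"probit": "probit", "logistic": "logit", "linear": None}[self.variant]

    @property
    def mediator_link(self) -> str:
        # binary mediators use the variant's link; probit in the linear variant
        return "logit" if self.variant == "logistic" else "probit"


def _grid(scheme: CategoryScheme):
    """Joint distribution of (a_idx, p_idx) implied by uniform age/period draws."""
    wa = np.diff(scheme.age_edges)
    wa = wa / wa.sum()
    wp = np.diff(scheme.period_edges)
    wp = wp / wp.sum()
    a = np.arange(scheme.n_age)
    p = np.arange(scheme.n_period)
    A, P = np.meshgrid(a, p, indexing="ij")
    W = np.outer(wa, wp)
    return A.ravel().astype(float), P.ravel().astype(float), W.ravel(), wa, wp


def _wvar(x: np.ndarray, w: np.ndarray) -> float:
    m = float(np.sum(w * x))
    return float(np.sum(w * (x - m) ** 2))


def _solve_prevalence_curve(prev: tuple[float, float], link: str, n_period: int,
                            center: float) -> tuple[float, float]:
    """Intercept and amplitude of an S-curve latent hitting the prevalence anchors."""
    q = _q_link(link)
    s0, s1 = expit(0 - center), expit(n_period - 1 - center)
    lo, hi = q(prev[0]), q(prev[1])
    amp = (hi - lo) / (s1 - s0)
    intercept = lo - amp * s0
    return intercept, amp


def calibrate(config: ScenarioConfig, scheme: CategoryScheme = DEFAULT_SCHEME) -> GeneratorParams:
    """Choose generator coefficients realising the configured effect shares.

    All variance computations are exact finite sums over the category grid
    (age and period indices are independent and follow the bin-width
    distribution of the scheme), so calibration is deterministic.  The
    outcome intercept is then tuned numerically so the mean outcome level in
    the youngest age category matches the lower baseline-risk target.
    """
    a_g, p_g, w_g, wa, wp = _grid(scheme)
    p_vals = np.arange(scheme.n_period, dtype=float)
    center = (scheme.n_period - 1) / 2.0
    var_a = _wvar(np.arange(scheme.n_age, dtype=float), wa)
    var_c = _wvar(p_g - a_g, w_g)
    c_mean = float(np.sum(w_g * (p_g - a_g + scheme.n_age - 1)))

    # latent scale anchored by the baseline-risk span under the *default*
    # age share, so the total APC variance is a fixed property of the
    # variant, comparable across share configurations (effect-size sweeps)
    q = _q_link("logit" if config.variant == "logistic" else "probit")
    span = q(config.baseline_risk_targets[1]) - q(config.baseline_risk_targets[0])
    alpha_default = span / (scheme.n_age - 1)
    v_total = alpha_default**2 * var_a / 0.70
    s_age, s_period, s_cohort = config.shares
    v_age, v_period, v_cohort = s_age * v_total, s_period * v_total, s_cohort * v_total

    med_link = "logit" if config.variant == "logistic" else "probit"
    mediators: dict[str, MediatorParams] = {}
    for spec in PAPER_MEDIATORS:
        ms = float(config.mediator_shares.get(spec.name, 0.0))
        if spec.name == "unmeasured":
            m = MediatorParams(spec.name, spec.kind, "linear", delta=0.0,
                               slope=UNMEASURED_SLOPE, sigma=UNMEASURED_SD)
        elif spec.name == "bmi":
            m = MediatorParams(spec.name, spec.kind, "sigmoid", delta=0.0,
                               intercept=BMI_BASE, amp=BMI_RISE, sigma=BMI_SD)
        elif spec.name == "smoking":
            i0, amp = _solve_prevalence_curve(SMOKING_PREV, med_link, scheme.n_period, center)
            m = MediatorParams(spec.name, spec.kind, "sigmoid", delta=0.0,
                               intercept=i0, amp=amp, link=med_link)
        else:  # statin
            i0, amp = _solve_prevalence_curve(STATIN_PREV, med_link, scheme.n_period, center)
            m = MediatorParams(spec.name, spec.kind, "sigmoid", delta=0.0,
                               intercept=i0, amp=amp, link=med_link)
        curve_var = _wvar(m.period_mean(p_vals, center), wp)
        if ms * v_period == 0.0:
            m.delta = 0.0
        else:
            if curve_var <= 0:
                raise CalibrationError(f"flat period curve for mediator {spec.name}")
            m.delta = spec.sign_m_to_y * float(np.sqrt(ms * v_period / curve_var))
        mediators[spec.name] = m

    # direct age/cohort slopes; in more_causes part of each effect is routed
    # through a mediator, variance-additively
    r_ab = config.age_to_bmi_share if config.scenario == "more_causes" else 0.0
    r_cs = config.cohort_to_smoking_share if config.scenario == "more_causes" else 0.0
    alpha = float(np.sqrt((1.0 - r_ab) * v_age / var_a))
    theta = -float(np.sqrt(v_cohort / var_c))  # reduced below if cohort->smoking is active

    if config.scenario == "more_causes":
        bmi = mediators["bmi"]
        if r_ab > 0:
            if bmi.delta == 0:
                raise CalibrationError("cannot route age effect through BMI: its outcome "
                                       "coefficient is zero under the configured shares")
            # negative age->BMI slope with Var(delta_bmi * b_age * a_idx) = r_ab * v_age
            bmi.age_coef = -float(np.sqrt(r_ab * v_age / var_a)) / bmi.delta
        smoking = mediators["smoking"]
        if r_cs > 0:
            if smoking.delta == 0:
                raise CalibrationError("cannot route cohort effect through smoking: its "
                                       "outcome coefficient is zero")
            # the additional cohort->smoking path is sized on the *latent*
            # (link) scale, where the generator's coefficients live: the
            # latent slope product delta_s * s_c carries r_cs of the nominal
            # cohort variance.  The realized probability-scale contribution
            # is much smaller (the link slope compresses it), so the direct
            # cohort slope is topped back up to preserve the total realized
            # cohort variance.
            smoking.cohort_coef = float(
                np.sqrt(r_cs * v_cohort / var_c) / smoking.delta)
            c_dev = (p_g - a_g + scheme.n_age - 1) - c_mean
            lat_p = smoking.intercept + smoking.period_curve(p_g, center)
            inv = _inv_link(med_link)
            contrib = smoking.delta * (inv(lat_p + smoking.cohort_coef * c_dev) - inv(lat_p))
            v_real = _wvar(contrib, w_g)
            theta = -float(np.sqrt(max(v_cohort - v_real, 0.0) / var_c))

    delta_genotype = 0.0
    if config.scenario == "confounding":
        bmi, smoking = mediators["bmi"], mediators["smoking"]
        bmi.genotype_coef = GENOTYPE_BMI_SHIFT
        pi_mid = _inv_link(med_link)(smoking.latent(center, center))
        qm = _q_link(med_link)
        smoking.genotype_coef = float(
            qm(min(pi_mid + GENOTYPE_SMOKING_PREV_SHIFT, 0.99)) - qm(pi_mid))
        # Var(delta_g * G) = ratio * Var(age contribution), G ~ Bernoulli(prev)
        var_g = config.genotype_prevalence * (1.0 - config.genotype_prevalence)
        delta_genotype = float(np.sqrt(GENOTYPE_AGE_VAR_RATIO * v_age / var_g))

    params = GeneratorParams(
        config=config, scheme=scheme, alpha=alpha, theta=theta, eta=0.0,
        mediators=mediators, delta_genotype=delta_genotype,
        sigma_y=config.sigma_y if config.variant == "linear" else None,
        v_total=v_total, p_center=center, c_mean=c_mean,
    )
    params.eta = _solve_intercept(params)
    return params


def _solve_intercept(params: GeneratorParams, n_internal: int = 20_000) -> float:
    """Tune the outcome intercept so the mean outcome in the youngest age
    category matches the lower baseline-risk target (an internal, fixed-seed
    Monte Carlo average over mediator noise)."""
    cfg = params.config
    scheme = params.scheme
    rng = np.random.default_rng(123_456_789)
    _, _, _, _, wp = _grid(scheme)
    p = rng.choice(scheme.n_period, size=n_internal, p=wp).astype(float)
    a = np.zeros(n_internal)
    c = p - a + scheme.n_age - 1
    g = (rng.random(n_internal) < cfg.genotype_prevalence).astype(float) \
        if cfg.scenario == "confounding" else np.zeros(n_internal)
    med_sum = np.zeros(n_internal)
    for m in params.mediators.values():
        vals = _draw_mediator(m, params, p, a, c, g, rng)
        med_sum += m.delta * vals
    rest = params.theta * c + med_sum + params.delta_genotype * g

    target_prob = cfg.baseline_risk_targets[0]
    if params.outcome_link is None:
        return float(_q_link("probit")(target_prob) - rest.mean())
    inv = _inv_link(params.outcome_link)

    def f(eta: float) -> float:
        return float(inv(eta + rest).mean() - target_prob)

    return float(optimize.brentq(f, -30.0, 10.0, xtol=1e-10))


def _draw_mediator(m: MediatorParams, params: GeneratorParams,
                   p: np.ndarray, a: np.ndarray, c: np.ndarray, g: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    c_dev = c - params.c_mean
    if m.kind == "continuous":
        mu = m.latent(p, params.p_center, a, c_dev, g)
        return mu + rng.normal(0.0, m.sigma, size=len(p))
    pi = _inv_link(m.link)(m.latent(p, params.p_center, a, c_dev, g))
    return (rng.random(len(p)) < pi).astype(float)


def generate(config: ScenarioConfig, params: GeneratorParams | None = None,
             scheme: CategoryScheme = DEFAULT_SCHEME) -> APCDataset:
    """Generate an individual-level dataset under the configured world.

    Deterministic given ``config.seed``; per-variable RNG streams are spawned
    from a single seed sequence so adding a scenario-specific variable does
    not perturb the shared ones.
    """
    if params is None:
        params = calibrate(config, scheme)
    elif params.config != config:
        raise ValueError("supplied GeneratorParams were calibrated for a different config")
    scheme = params.scheme
    ss = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ("time", "genotype", *MEDIATOR_ORDER, "outcome"), ss.spawn(7))}

    n = config.n
    age_lo, age_hi = scheme.age_edges[0], scheme.age_edges[-1]
    per_lo, per_hi = scheme.period_edges[0], scheme.period_edges[-1]
    age = streams["time"].uniform(age_lo, age_hi, n)
    period = streams["time"].uniform(per_lo, per_hi, n)
    a_idx, p_idx, c_idx = categorize(age, period, scheme)
    a = a_idx.astype(float)
    p = p_idx.astype(float)
    c = (p_idx - a_idx).astype(float) + scheme.n_age - 1

    g = np.zeros(n)
    if config.scenario == "confounding":
        g = (streams["genotype"].random(n) < config.genotype_prevalence).astype(float)

    cols = {
        "age": age, "period": period, "cohort": period - age,
        "a_idx": a_idx, "p_idx": p_idx, "c_idx": c_idx.astype(int),
    }
    latent = params.eta + params.alpha * a + params.theta * c + params.delta_genotype * g
    kinds = {}
    for name in MEDIATOR_ORDER:
        m = params.mediators[name]
        vals = _draw_mediator(m, params, p, a, c, g, streams[name])
        cols[name] = vals
        kinds[name] = m.kind
        latent = latent + m.delta * vals
    if config.scenario == "confounding":
        cols["genotype"] = g

    if params.outcome_link is None:
        outcome = latent + streams["outcome"].normal(0.0, params.sigma_y, n)
    else:
        pi = _inv_link(params.outcome_link)(latent)
        outcome = (streams["outcome"].random(n) < pi).astype(float)
    cols["outcome"] = outcome

    return APCDataset(
        df=pd.DataFrame(cols),
        scheme=scheme,
        mediators=MEDIATOR_ORDER,
        mediator_kinds=kinds,
        confounder="genotype" if config.scenario == "confounding" else None,
        provenance={"generator": "apcmech.datagen", "scenario": config.scenario,
                    "variant": config.variant, "seed": config.seed, "n": config.n},
    )


@dataclass
class AttributionShares:
    """Empirical variance-share decomposition of the latent linear predictor."""

    age: float
    period: float
    cohort: float
    mediator_shares: dict[str, float]
    age_via_bmi: float | None = None
    cohort_via_smoking: float | None = None

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.age, self.period, self.cohort)


def attribution_shares(params: GeneratorParams, dataset: APCDataset) -> AttributionShares:
    """Recompute, on a generated dataset, the variance shares the generator
    was calibrated to.

    Contributions are *systematic*: each pathway is evaluated at the
    conditional mean of its mediator given the pathway's source, so mediator
    noise (which is not a time effect) is excluded.  Shares are marginal
    pathway variances normalised over the three APC components;
    cross-pathway covariances are not apportioned.
    """
    if set(params.mediators) != set(dataset.mediators):
        raise ValueError("params and dataset disagree on the mediator set")
    a = dataset.indices("age").astype(float)
    p = dataset.indices("period").astype(float)
    c = dataset.indices("cohort").astype(float)
    c_dev = c - params.c_mean
    center = params.p_center

    v_age_direct = float(np.var(params.alpha * a))
    v_coh_direct = float(np.var(params.theta * c))
    per_var: dict[str, float] = {}
    for name, m in params.mediators.items():
        per_var[name] = float(np.var(m.delta * m.period_mean(p, center)))
    v_period = sum(per_var.values())

    v_age_via_bmi = 0.0
    v_coh_via_smoke = 0.0
    bmi = params.mediators.get("bmi")
    if bmi is not None and bmi.age_coef != 0.0:
        v_age_via_bmi = float(np.var(bmi.delta * bmi.age_coef * a))
    smoking = params.mediators.get("smoking")
    if smoking is not None and smoking.cohort_coef != 0.0:
        lat_p = smoking.intercept + smoking.period_curve(p, center)
        inv = _inv_link(smoking.link)
        contrib = smoking.delta * (inv(lat_p + smoking.cohort_coef * c_dev) - inv(lat_p))
        v_coh_via_smoke = float(np.var(contrib))

    v_age = v_age_direct + v_age_via_bmi
    v_coh = v_coh_direct + v_coh_via_smoke
    total = v_age + v_period + v_coh
    if total == 0:
        raise ValueError("all APC contributions have zero variance")
    med_shares = ({k: v / v_period for k, v in per_var.items()} if v_period > 0
                  else {k: 0.0 for k in per_var})
    return AttributionShares(
        age=v_age / total, period=v_period / total, cohort=v_coh / total,
        mediator_shares=med_shares,
        age_via_bmi=(v_age_via_bmi / v_age if v_age_via_bmi > 0 else None),
        cohort_via_smoking=(v_coh_via_smoke / v_coh if v_coh_via_smoke > 0 else None),
    )


def drop_mediators(dataset: APCDataset, names) -> APCDataset:
    """Remove mediator columns, emulating estimation with an incomplete set."""
    return dataset.drop_mediators(names)


# --------------------------------------------------------------- oracles
def true_model_fits(params: GeneratorParams):
    """Exact first- and second-step model fits implied by the generator.

    Returns ``(mediator_fits, outcome_fit)`` in the estimator's fitted-model
    containers, with dummy-coded coefficients evaluated from the true
    coefficient functions.  Used as the reference ("estimand") side of
    recovery checks: feeding these into the Monte Carlo integration step
    yields the true causal APC effects without estimation error.
    """
    from .pathtrace import MediatorModelFit, OutcomeModelFit

    scheme = params.scheme
    center = params.p_center
    med_fits = []
    for name, m in params.mediators.items():
        coefs = {"const": float(m.latent(0.0, center, 0.0, -params.c_mean, 0.0))}
        base = coefs["const"]
        for k in range(1, scheme.n_period):
            coefs[f"period_{k}"] = float(
                m.latent(float(k), center, 0.0, -params.c_mean, 0.0)) - base
        exposures = ["period"]
        if m.age_coef != 0.0:
            exposures.append("age")
            for k in range(1, scheme.n_age):
                coefs[f"age_{k}"] = m.age_coef * k
        if m.cohort_coef != 0.0:
            exposures.append("cohort")
            for k in range(1, scheme.n_cohort):
                coefs[f"cohort_{k}"] = m.cohort_coef * k
        confounder = None
        if m.genotype_coef != 0.0:
            confounder = "genotype"
            coefs["genotype"] = m.genotype_coef
        family = "linear" if m.kind == "continuous" else m.link
        med_fits.append(MediatorModelFit(
            name=name, family=family, params=coefs,
            sigma=m.sigma, exposures=tuple(exposures), confounder=confounder, nobs=0))

    out_coefs = {"const": params.eta}
    for k in range(1, scheme.n_age):
        out_coefs[f"age_{k}"] = params.alpha * k
    for k in range(1, scheme.n_cohort):
        out_coefs[f"cohort_{k}"] = params.theta * k
    for name, m in params.mediators.items():
        out_coefs[name] = m.delta
    confounder = None
    if params.delta_genotype != 0.0:
        confounder = "genotype"
        out_coefs["genotype"] = params.delta_genotype
    family = {"probit": "probit", "logistic": "logit", "linear": "linear"}[params.variant]
    out_fit = OutcomeModelFit(
        family=family, params=out_coefs, mediators=tuple(params.mediators),
        direct_dims=("age", "cohort"), confounder=confounder,
        sigma=params.sigma_y, nobs=0)
    return med_fits, out_fit


def linear_truth(params: GeneratorParams) -> dict[str, np.ndarray]:
    """Closed-form per-category APC effects on the latent (linear) scale.

    Exact for the linear variant: the period effect for category ``k`` is the
    sum over mediators of ``delta_m * (E[M|p=k] - E[M|p=0])``.
    """
    scheme = params.scheme
    alpha_k = params.alpha * np.arange(scheme.n_age, dtype=float)
    theta_k = params.theta * np.arange(scheme.n_cohort, dtype=float)
    p_vals = np.arange(scheme.n_period, dtype=float)
    beta_k = np.zeros(scheme.n_period)
    for m in params.mediators.values():
        mu = m.period_mean(p_vals, params.p_center)
        beta_k += m.delta * (mu - mu[0])
    return {"age": alpha_k, "period": beta_k, "cohort": theta_k}


def true_apc_estimates(params: GeneratorParams, n_draws: int = 2_000_000, seed: int = 0):
    """Causal-estimand oracle: Monte Carlo integration with the *true* models.

    Simulates potential outcomes from the generator's own coefficients over
    independently drawn (age, period, cohort) categories and fits the
    identifiable APC model, i.e. computes the estimand the estimators target,
    free of first-stage estimation error (up to Monte Carlo noise).
    """
    from . import mcfrontdoor

    med_fits, out_fit = true_model_fits(params)
    world = mcfrontdoor.simulate_world(
        med_fits, out_fit, params.scheme, n_draws=n_draws, seed=seed,
        genotype_prevalence=(params.config.genotype_prevalence
                             if params.config.scenario == "confounding" else None))
    est = mcfrontdoor.fit_apc_on_simulated(world)
    est.tag = "truth"
    return est
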