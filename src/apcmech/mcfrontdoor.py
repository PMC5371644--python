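"""Front-door APC estimation by Monte Carlo integration.

Path tracing breaks down for logistic links, product terms or other
nonlinearities.  This estimator instead *simulates* its way to identification
(a parametric g-formula):

1. fit a model per mediator on period (Step 1);
2. fit the outcome model on age, cohort and the mediators (Step 2);
3. simulate mediator values ``M~(p~)`` from the Step-1 fits over draws of the
   period category (Step 3);
4. simulate potential outcomes ``Y~(a~, p~, c~)`` from the Step-2 fit, with
   the age, period and cohort categories drawn *independently* so the linear
   identity ``a = p - c`` deliberately fails to hold (Step 4);
5. fit an ordinary APC dummy regression to the simulated data — identifiable
   because the collinearity is broken (Step 5);
6. bootstrap the whole pipeline for standard errors (Step 6).

Draw ranges are always the category ranges observed in the source data.  The
default draw design is a full factorial over every (age, period, cohort)
category triple, replicated until the requested number of draws is reached;
this includes triples impossible in the real world, which is precisely the
point.  Because the first-stage fits are held fixed within a call, the
Step-5 coefficient standard errors measure pure Monte Carlo error and are
reported alongside the estimates (column ``mc_se``); they shrink as the draw
count grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from .core import APCDataset, CategoryScheme, DIMENSIONS
from .pathtrace import (APCEstimates, BootstrapResult, MediatorModelFit, OutcomeModelFit,
                        bootstrap as _bootstrap, fit_mediator_models, fit_outcome_model,
                        _make_table, _sm_family)

_INV = {"probit": norm.cdf, "logit": expit}


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo integration settings.

    ``n_draws`` is the total simulated sample size; ``design`` is
    ``"factorial"`` (balanced over all category triples, default) or
    ``"random"`` (independent uniform category draws).  Age, period and
    cohort draws are always independent — that requirement is not
    configurable.
    """

    n_draws: int = 1_000_000
    design: str = "factorial"
    seed: int = 0
    reuse_p: bool = True
    couple_noise: bool = True  # common random numbers across factorial cells

    def __post_init__(self) -> None:
        if self.design not in ("factorial", "random"):
            raise ValueError(f"unknown draw design {self.design!r}")
        if self.n_draws < 1:
            raise ValueError("n_draws must be positive")


@dataclass
class SimulatedWorld:
    """Simulated mediators and potential outcomes over independent APC draws."""

    df: pd.DataFrame  # a_idx, p_idx, c_idx, mediator columns, outcome
    scheme: CategoryScheme
    family: str  # family of the Step-5 refit (linear | probit | logit)
    mediators: tuple[str, ...]


def _coef_vector(params: Mapping[str, float], dim: str, n_cat: int) -> np.ndarray:
    return np.array([0.0] + [float(params.get(f"{dim}_{k}", 0.0)) for k in range(1, n_cat)])


def _check_range(draws: np.ndarray, n_cat: int, what: str) -> None:
    if draws.min() < 0 or draws.max() > n_cat - 1:
        raise ValueError(f"{what} draws outside the empirically observed category range "
                         f"[0, {n_cat - 1}]")


class _Sampler:
    """Plain noise source: independent draws per simulated row."""

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def normal(self, n: int) -> np.ndarray:
        return self.rng.normal(size=n)

    def uniform(self, n: int) -> np.ndarray:
        return self.rng.random(n)


class _CoupledSampler(_Sampler):
    """Common random numbers across factorial cells.

    Rows are ordered replicate-major over the factorial cells; each variable
    reuses one standardized draw per replicate in every cell, so Monte Carlo
    noise is shared between cells and cancels out of coefficient contrasts.
    Marginal distributions per row are unchanged (each variable gets its own
    independent stream), so estimates stay unbiased.
    """

    def __init__(self, rng: np.random.Generator, n_cells: int) -> None:
        super().__init__(rng)
        self.n_cells = n_cells

    def _tile(self, draws: np.ndarray) -> np.ndarray:
        return np.repeat(draws, self.n_cells)

    def normal(self, n: int) -> np.ndarray:
        assert n % self.n_cells == 0
        return self._tile(self.rng.normal(size=n // self.n_cells))

    def uniform(self, n: int) -> np.ndarray:
        assert n % self.n_cells == 0
        return self._tile(self.rng.random(n // self.n_cells))


def draw_categories(scheme: CategoryScheme, config: MCConfig,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Independent draws of (a~, p~, c~) category indices covering the full range."""
    if config.design == "factorial":
        n_cells = scheme.n_age * scheme.n_period * scheme.n_cohort
        m = max(1, int(np.ceil(config.n_draws / n_cells)))
        a, p, c = np.meshgrid(np.arange(scheme.n_age), np.arange(scheme.n_period),
                              np.arange(scheme.n_cohort), indexing="ij")
        a = np.tile(a.ravel(), m)
        p = np.tile(p.ravel(), m)
        c = np.tile(c.ravel(), m)
    else:
        a = rng.integers(0, scheme.n_age, config.n_draws)
        p = rng.integers(0, scheme.n_period, config.n_draws)
        c = rng.integers(0, scheme.n_cohort, config.n_draws)
    return a.astype(np.int64), p.astype(np.int64), c.astype(np.int64)


def simulate_mediators(
    mediator_fits: Sequence[MediatorModelFit],
    p: np.ndarray,
    scheme: CategoryScheme,
    rng: np.random.Generator,
    a: np.ndarray | None = None,
    c: np.ndarray | None = None,
    g: np.ndarray | None = None,
    sampler: _Sampler | None = None,
) -> dict[str, np.ndarray]:
    """Step 3: draw mediator values from the fitted first-step models.

    Continuous mediators get Gaussian noise with the fitted residual SD;
    binary mediators are Bernoulli with the link-inverted mean.  Mediators
    exposed to age/cohort (or the confounder) use the corresponding draws.
    """
    p = np.asarray(p)
    _check_range(p, scheme.n_period, "period")
    sampler = sampler or _Sampler(rng)
    out: dict[str, np.ndarray] = {}
    for fit in mediator_fits:
        latent = np.full(len(p), float(fit.params.get("const", 0.0)))
        for dim, draws in (("period", p), ("age", a), ("cohort", c)):
            if dim in fit.exposures:
                if draws is None:
                    raise ValueError(f"mediator {fit.name!r} is exposed to {dim} "
                                     "but no draws were supplied")
                _check_range(np.asarray(draws), scheme.n_categories(dim), dim)
                latent += _coef_vector(fit.params, dim, scheme.n_categories(dim))[draws]
        if fit.confounder is not None:
            if g is None:
                raise ValueError(f"mediator {fit.name!r} includes confounder "
                                 f"{fit.confounder!r} but no confounder draws were supplied")
            latent += float(fit.params[fit.confounder]) * np.asarray(g, dtype=float)
        if fit.family == "linear":
            out[fit.name] = latent + fit.sigma * sampler.normal(len(p))
        else:
            out[fit.name] = (sampler.uniform(len(p)) < _INV[fit.family](latent)).astype(float)
    return out


def simulate_outcomes(
    outcome_fit: OutcomeModelFit,
    mediator_values: Mapping[str, np.ndarray],
    a: np.ndarray,
    p: np.ndarray,
    c: np.ndarray,
    scheme: CategoryScheme,
    rng: np.random.Generator,
    g: np.ndarray | None = None,
    extra_columns_fn: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
    sampler: _Sampler | None = None,
) -> np.ndarray:
    """Step 4: draw potential outcomes ``Y~(a~, p~, c~)`` from the Step-2 fit.

    Rejects draw designs in which the real-world identity ``c = p - a +
    (n_age - 1)`` holds for every row — such draws would reproduce the
    collinearity instead of breaking it.
    """
    a, p, c = (np.asarray(x, dtype=np.int64) for x in (a, p, c))
    for draws, dim in ((a, "age"), (p, "period"), (c, "cohort")):
        _check_range(draws, scheme.n_categories(dim), dim)
    if len(a) > 1 and np.array_equal(c, p - a + scheme.n_age - 1):
        raise ValueError("draws satisfy the APC identity everywhere; age, period and "
                         "cohort must be drawn independently")
    latent = np.full(len(a), float(outcome_fit.params.get("const", 0.0)))
    for dim, draws in (("age", a), ("period", p), ("cohort", c)):
        if dim in outcome_fit.direct_dims:
            latent += _coef_vector(outcome_fit.params, dim, scheme.n_categories(dim))[draws]
    for name in outcome_fit.mediators:
        latent += float(outcome_fit.params[name]) * mediator_values[name]
    if outcome_fit.confounder is not None:
        if g is None:
            raise ValueError("outcome model includes a confounder but no draws were supplied")
        latent += float(outcome_fit.params[outcome_fit.confounder]) * np.asarray(g, float)
    if extra_columns_fn is not None:
        base = pd.DataFrame({"a_idx": a, "p_idx": p, "c_idx": c,
                             **{k: v for k, v in mediator_values.items()}})
        for col, vals in extra_columns_fn(base).items():
            latent += float(outcome_fit.params[col]) * np.asarray(vals, dtype=float)
    sampler = sampler or _Sampler(rng)
    if outcome_fit.family == "linear":
        return latent + outcome_fit.sigma * sampler.normal(len(a))
    return (sampler.uniform(len(a)) < _INV[outcome_fit.family](latent)).astype(float)


def simulate_world(
    mediator_fits: Sequence[MediatorModelFit],
    outcome_fit: OutcomeModelFit,
    scheme: CategoryScheme,
    n_draws: int = 1_000_000,
    seed: int = 0,
    design: str = "factorial",
    reuse_p: bool = True,
    couple_noise: bool = True,
    genotype_prevalence: float | None = None,
    extra_columns_fn: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> SimulatedWorld:
    """Steps 3-4: build the identifiable simulated data set."""
    config = MCConfig(n_draws=n_draws, design=design, seed=seed, reuse_p=reuse_p,
                      couple_noise=couple_noise)
    rng = np.random.default_rng(seed)
    a, p, c = draw_categories(scheme, config, rng)
    n_cells = scheme.n_age * scheme.n_period * scheme.n_cohort
    sampler: _Sampler = _Sampler(rng)
    # coupling cancels additive noise out of linear coefficient contrasts; for
    # binary outcomes it brings no such cancellation and would invalidate the
    # independence assumption behind the reported mc_se, so it is linear-only
    if (config.design == "factorial" and config.couple_noise and config.reuse_p
            and outcome_fit.family == "linear"):
        sampler = _CoupledSampler(rng, n_cells)
    g = None
    needs_g = outcome_fit.confounder is not None or any(
        f.confounder is not None for f in mediator_fits)
    if needs_g:
        if genotype_prevalence is None:
            raise ValueError("models include a confounder; supply its prevalence "
                             "so it can be drawn in the simulated world")
        g = (sampler.uniform(len(a)) < genotype_prevalence).astype(float)
    p_med = p
    if not reuse_p:
        p_med = rng.integers(0, scheme.n_period, len(p)).astype(np.int64)
        p = p_med  # regenerated period draws feed both steps coherently
    med = simulate_mediators(mediator_fits, p_med, scheme, rng, a=a, c=c, g=g,
                             sampler=sampler)
    y = simulate_outcomes(outcome_fit, med, a, p, c, scheme, rng, g=g,
                          extra_columns_fn=extra_columns_fn, sampler=sampler)
    df = pd.DataFrame({"a_idx": a, "p_idx": p, "c_idx": c, **med, "outcome": y})
    family = outcome_fit.family
    return SimulatedWorld(df=df, scheme=scheme, family=family,
                          mediators=tuple(f.name for f in mediator_fits))


def _world_design(world: SimulatedWorld) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    idx = {"age": world.df["a_idx"], "period": world.df["p_idx"], "cohort": world.df["c_idx"]}
    for dim in DIMENSIONS:
        vals = idx[dim].to_numpy()
        for k in range(1, world.scheme.n_categories(dim)):
            cols[f"{dim}_{k}"] = (vals == k).astype(float)
    return pd.DataFrame(cols)


def fit_apc_on_simulated(world: SimulatedWorld) -> APCEstimates:
    """Step 5: ordinary APC dummy regression on the simulated draws.

    The design must be full rank — a deficiency would mean the identity was
    not actually broken, and is treated as a hard failure.
    """
    design = _world_design(world)
    unique = design.drop_duplicates().to_numpy()
    X_unique = np.column_stack([np.ones(len(unique)), unique])
    if np.linalg.matrix_rank(X_unique) < X_unique.shape[1]:
        raise RuntimeError("APC design on simulated draws is rank deficient; "
                           "the identity was not broken (draws not independent?)")
    X = sm.add_constant(design, has_constant="add")
    y = world.df["outcome"].to_numpy(dtype=float)
    if world.family == "linear":
        res = sm.OLS(y, X).fit()
    else:
        res = sm.GLM(y, X, family=_sm_family(world.family)).fit()
    per_dim = {}
    mc_se = {}
    for dim in DIMENSIONS:
        n_cat = world.scheme.n_categories(dim)
        per_dim[dim] = _coef_vector(res.params, dim, n_cat)
        ses = res.bse
        mc_se[dim] = np.array([0.0] + [float(ses.get(f"{dim}_{k}", np.nan))
                                       for k in range(1, n_cat)])
    table = _make_table(world.scheme, per_dim)
    table["mc_se"] = np.concatenate([mc_se[d] for d in DIMENSIONS])
    return APCEstimates(table=table, tag="mcfrontdoor", scale=world.family)


def estimate(
    dataset: APCDataset,
    mediators: Sequence[str] | None = None,
    config: MCConfig = MCConfig(),
    confounder: str | None = None,
    exposures: Mapping[str, Sequence[str]] | None = None,
    family: str | None = None,
    extra_columns_fn: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> APCEstimates:
    """Steps 1-5 end to end; deterministic given ``config.seed``.

    ``extra_columns_fn`` may add product terms or other constructed
    covariates to the outcome model; the same function is applied when
    simulating potential outcomes, so nonlinear outcome models are handled
    transparently.
    """
    mediators = list(mediators if mediators is not None else dataset.mediators)
    if not mediators:
        raise ValueError("no mediators supplied: the front-door estimator has "
                         "nothing to integrate over")
    med_fits = fit_mediator_models(dataset, mediators, exposures, binary_family=family)
    extra = None
    if extra_columns_fn is not None:
        base = pd.DataFrame({
            "a_idx": dataset.indices("age"), "p_idx": dataset.indices("period"),
            "c_idx": dataset.indices("cohort"),
            **{m: dataset.df[m].to_numpy() for m in mediators}})
        extra = extra_columns_fn(base)
    out_fit = fit_outcome_model(dataset, mediators, confounder=confounder,
                                family=family, extra_columns=extra)
    prevalence = None
    if confounder is not None:
        prevalence = float(dataset.df[confounder].mean())
    world = simulate_world(
        med_fits, out_fit, dataset.scheme, n_draws=config.n_draws, seed=config.seed,
        design=config.design, reuse_p=config.reuse_p,
        genotype_prevalence=prevalence, extra_columns_fn=extra_columns_fn)
    return fit_apc_on_simulated(world)


def bootstrap_mc(
    dataset: APCDataset,
    mediators: Sequence[str] | None = None,
    config: MCConfig = MCConfig(),
    B: int = 100,
    seed: int = 0,
    confounder: str | None = None,
    exposures: Mapping[str, Sequence[str]] | None = None,
    family: str | None = None,
) -> BootstrapResult:
    """Step 6: nonparametric bootstrap wrapping Steps 1-5.

    The Monte Carlo draw seed is held fixed across replicates (common random
    numbers), so the replicate spread reflects sampling variability of the
    original data rather than simulation noise.
    """
    def closure(ds: APCDataset) -> APCEstimates:
        return estimate(ds, mediators, config, confounder=confounder,
                        exposures=exposures, family=family)

    return _bootstrap(dataset, closure, B=B, seed=seed)
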