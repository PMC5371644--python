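"""Mechanism-based APC estimation by path tracing (product of coefficients).

The front-door idea: if the entire period effect runs through a measured set
of mediators, fit (1) one regression per mediator on period and (2) one
outcome regression on age, cohort and the mediators.  Age and cohort effects
are the outcome-model coefficients; the period effect for category ``k`` is
the sum over mediators of (period->mediator coefficient) x (mediator->outcome
coefficient) — Wright's path-tracing rule, generalised here to dummy-coded
categorical exposures (one product per mediator per non-reference category).

The rule is exact for linear models and is applied on the latent scale for
probit models (an approximation flagged on the output).  For logistic models
or models with product terms it is invalid and the estimator refuses,
pointing to :mod:`apcmech.mcfrontdoor`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import APCDataset, CategoryScheme, DIMENSIONS, dummy_encode

FAMILIES = ("linear", "probit", "logit")


class PathTracingError(RuntimeError):
    """The path-tracing rule is invalid for the supplied model families."""


class FitError(RuntimeError):
    pass


def _sm_family(family: str):
    links = {"probit": sm.families.links.Probit(), "logit": sm.families.links.Logit()}
    return sm.families.Binomial(link=links[family])


@dataclass
class MediatorModelFit:
    """First-step fit: one mediator regressed on its exposure dummies."""

    name: str
    family: str  # linear | probit | logit
    params: Mapping[str, float]
    exposures: tuple[str, ...] = ("period",)
    confounder: str | None = None
    sigma: float | None = None  # residual SD, continuous mediators only
    cov: pd.DataFrame | None = None
    nobs: int = 0

    def __post_init__(self) -> None:
        if self.family == "linear" and self.sigma is None:
            raise ValueError(f"continuous mediator {self.name!r} requires a residual SD")
        if self.family != "linear":
            self.sigma = None

    def coef(self, key: str) -> float:
        return float(self.params.get(key, 0.0))


@dataclass
class OutcomeModelFit:
    """Second-step fit: outcome on age/cohort dummies, mediators, confounder."""

    family: str
    params: Mapping[str, float]
    mediators: tuple[str, ...]
    direct_dims: tuple[str, ...] = ("age", "cohort")
    confounder: str | None = None
    sigma: float | None = None
    cov: pd.DataFrame | None = None
    nobs: int = 0

    def coef(self, key: str) -> float:
        return float(self.params.get(key, 0.0))


@dataclass
class APCEstimates:
    """Per-category APC effect estimates on the fitting model's link scale.

    ``table`` is tidy with columns ``dimension, category, estimate`` (and,
    after bootstrapping, ``se, ci_lo, ci_hi``).  Reference categories are
    included with estimate exactly 0.
    """

    table: pd.DataFrame
    tag: str
    scale: str  # linear | probit | logit
    notes: tuple[str, ...] = ()

    def values(self, dim: str) -> np.ndarray:
        sub = self.table[self.table["dimension"] == dim].sort_values("category")
        return sub["estimate"].to_numpy()

    def series(self, dim: str) -> pd.Series:
        sub = self.table[self.table["dimension"] == dim].sort_values("category")
        return pd.Series(sub["estimate"].to_numpy(), index=sub["category"].to_numpy())

    def aligned(self) -> pd.Series:
        t = self.table.set_index(["dimension", "category"]).sort_index()
        return t["estimate"]


def _make_table(scheme: CategoryScheme, per_dim: Mapping[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for dim in DIMENSIONS:
        vals = per_dim[dim]
        assert len(vals) == scheme.n_categories(dim)
        for k, v in enumerate(vals):
            rows.append({"dimension": dim, "category": k, "estimate": float(v)})
    return pd.DataFrame(rows)


def _resolve_family(dataset: APCDataset, family: str | None, values: np.ndarray) -> str:
    if family is not None:
        if family == "logistic":
            family = "logit"
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        return family
    binary = set(np.unique(values)).issubset({0.0, 1.0})
    if not binary:
        return "linear"
    variant = dataset.provenance.get("variant")
    if variant == "probit":
        return "probit"
    if variant == "logistic":
        return "logit"
    if variant == "linear":
        # fully linear setting: binary mediators as saturated linear
        # probability models, keeping the path-tracing rule exact
        return "linear"
    raise ValueError("binary variable but no family given and none recorded in provenance")


def _fit(endog: np.ndarray, design: pd.DataFrame, family: str):
    X = sm.add_constant(design, has_constant="add")
    try:
        if family == "linear":
            res = sm.OLS(endog, X).fit()
            sigma = float(np.sqrt(res.scale))
        else:
            res = sm.GLM(endog, X, family=_sm_family(family)).fit()
            sigma = None
    except Exception as exc:  # singular design, separation, non-convergence
        raise FitError(f"{family} fit failed ({type(exc).__name__}: {exc}); "
                       "check for singular design or perfect separation") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError(f"{family} fit produced non-finite coefficients")
    return res, sigma


def fit_mediator_models(
    dataset: APCDataset,
    mediators: Sequence[str] | None = None,
    exposures: Mapping[str, Sequence[str]] | None = None,
    binary_family: str | None = None,
) -> list[MediatorModelFit]:
    """Step 1: regress each mediator on dummy-coded exposures.

    ``exposures`` maps mediator name to the time dimensions (plus optionally
    the confounder column name) it is modelled on; default is period only.
    Continuous mediators use OLS, binary ones a probit/logit GLM.
    """
    mediators = list(mediators if mediators is not None else dataset.mediators)
    exposures = exposures or {}
    fits = []
    for name in mediators:
        if name not in dataset.mediators:
            raise KeyError(f"mediator {name!r} not in dataset")
        expo = list(exposures.get(name, ("period",)))
        dims = [e for e in expo if e in DIMENSIONS]
        extra = [e for e in expo if e not in DIMENSIONS]
        design = dummy_encode(dataset, dims)
        for col in extra:
            design[col] = dataset.df[col].to_numpy()
        kind = dataset.mediator_kind(name)
        endog = dataset.df[name].to_numpy(dtype=float)
        family = "linear" if kind == "continuous" else _resolve_family(
            dataset, binary_family, endog)
        res, sigma = _fit(endog, design, family)
        fits.append(MediatorModelFit(
            name=name, family=family, params=dict(res.params),
            exposures=tuple(dims), confounder=(extra[0] if extra else None),
            sigma=sigma, cov=res.cov_params(), nobs=int(res.nobs)))
    return fits


def fit_outcome_model(
    dataset: APCDataset,
    mediators: Sequence[str] | None = None,
    direct_dims: Sequence[str] = ("age", "cohort"),
    confounder: str | None = None,
    family: str | None = None,
    extra_columns: pd.DataFrame | None = None,
) -> OutcomeModelFit:
    """Step 2: outcome on direct-dimension dummies, mediators and confounder.

    Period dummies are excluded whenever the period effect is fully mediated
    (the default ``direct_dims``).  ``extra_columns`` allows product terms or
    other constructed covariates (these invalidate path tracing but are
    handled by the Monte Carlo estimator).
    """
    mediators = list(mediators if mediators is not None else dataset.mediators)
    design = dummy_encode(dataset, list(direct_dims))
    for m in mediators:
        if m not in dataset.df.columns:
            raise KeyError(f"mediator column {m!r} not in dataset")
        design[m] = dataset.df[m].to_numpy(dtype=float)
    if confounder is not None:
        design[confounder] = dataset.df[confounder].to_numpy(dtype=float)
    if extra_columns is not None:
        for col in extra_columns.columns:
            design[col] = extra_columns[col].to_numpy(dtype=float)
    endog = dataset.df["outcome"].to_numpy(dtype=float)
    family = _resolve_family(dataset, family, endog)
    res, sigma = _fit(endog, design, family)
    return OutcomeModelFit(
        family=family, params=dict(res.params), mediators=tuple(mediators),
        direct_dims=tuple(direct_dims), confounder=confounder,
        sigma=sigma, cov=res.cov_params(), nobs=int(res.nobs))


def path_trace(
    mediator_fits: Sequence[MediatorModelFit],
    outcome_fit: OutcomeModelFit,
    scheme: CategoryScheme,
) -> APCEstimates:
    """Combine Steps 1-2 by the product-of-coefficients rule.

    For each dimension the per-category effect is the outcome model's direct
    dummy coefficient (zero if the dimension has none) plus, for every
    mediator exposed to that dimension, the product of the mediator model's
    dummy coefficient and the mediator's outcome coefficient.
    """
    bad = [f.name for f in mediator_fits if f.family == "logit"]
    if outcome_fit.family == "logit" or bad:
        raise PathTracingError(
            "path tracing is invalid for logistic-family fits "
            f"(outcome={outcome_fit.family}, mediators={bad}); "
            "use apcmech.mcfrontdoor.estimate instead")
    if any(":" in k or "*" in k for k in outcome_fit.params):
        raise PathTracingError(
            "path tracing is invalid with product terms in the outcome model; "
            "use apcmech.mcfrontdoor.estimate instead")
    for f in mediator_fits:
        if f.name not in outcome_fit.mediators:
            raise ValueError(f"mediator {f.name!r} missing from the outcome model")

    per_dim: dict[str, np.ndarray] = {}
    for dim in DIMENSIONS:
        vals = np.zeros(scheme.n_categories(dim))
        if dim in outcome_fit.direct_dims:
            for k in range(1, len(vals)):
                vals[k] = outcome_fit.coef(f"{dim}_{k}")
        for f in mediator_fits:
            if dim not in f.exposures:
                continue
            delta = outcome_fit.coef(f.name)
            for k in range(1, len(vals)):
                vals[k] += f.coef(f"{dim}_{k}") * delta
        per_dim[dim] = vals

    notes = ()
    if outcome_fit.family == "probit" or any(f.family == "probit" for f in mediator_fits):
        notes = ("probit products are latent-scale approximations",)
    return APCEstimates(table=_make_table(scheme, per_dim), tag="pathtrace",
                        scale=outcome_fit.family, notes=notes)


def delta_method_se(mediator_fit: MediatorModelFit, outcome_fit: OutcomeModelFit) -> pd.Series:
    """First-order delta-method SE of a single-pathway product, per category.

    ``SE(g*d) = sqrt(g^2 Var(d) + d^2 Var(g))``; valid only for linear
    mediator and outcome models with a single mediated pathway.
    """
    if mediator_fit.family != "linear" or outcome_fit.family != "linear":
        raise PathTracingError("delta-method SEs are provided for linear models only; "
                               "use the bootstrap")
    if len(outcome_fit.mediators) != 1:
        raise PathTracingError("delta-method SEs cover a single pathway only; "
                               "use the bootstrap for multi-mediator settings")
    if mediator_fit.cov is None or outcome_fit.cov is None:
        raise ValueError("fits carry no coefficient covariance")
    delta = outcome_fit.coef(mediator_fit.name)
    var_delta = float(outcome_fit.cov.loc[mediator_fit.name, mediator_fit.name])
    out = {}
    for key, gamma in mediator_fit.params.items():
        if key == "const" or key == mediator_fit.confounder:
            continue
        var_gamma = float(mediator_fit.cov.loc[key, key])
        out[key] = float(np.sqrt(gamma**2 * var_delta + delta**2 * var_gamma))
    return pd.Series(out)


def product_se(gamma: float, se_gamma: float, delta: float, se_delta: float) -> float:
    """Scalar delta-method SE for a product of two independent estimates."""
    return float(np.sqrt(gamma**2 * se_delta**2 + delta**2 * se_gamma**2))


@dataclass
class BootstrapResult:
    estimates: APCEstimates  # point estimates with se / percentile CI columns
    replicates: pd.DataFrame  # one column per (dimension, category), one row per replicate
    n_requested: int
    n_failed: int


def bootstrap(
    dataset: APCDataset,
    estimator: Callable[[APCDataset], APCEstimates],
    B: int = 500,
    seed: int = 0,
    ci_level: float = 0.95,
    max_failure_rate: float = 0.10,
) -> BootstrapResult:
    """Nonparametric bootstrap around a full estimator closure.

    Resamples records with replacement at the original size, reruns the
    estimator, and reports the SD across replicates as the standard error
    plus percentile confidence intervals.  Replicates in which the estimator
    fails are dropped and counted; more than ``max_failure_rate`` failures
    aborts.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    point = estimator(dataset)
    rng = np.random.default_rng(seed)
    n = len(dataset)
    draws = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = APCDataset(
            df=dataset.df.iloc[idx].reset_index(drop=True),
            scheme=dataset.scheme, mediators=dataset.mediators,
            mediator_kinds=dict(dataset.mediator_kinds),
            confounder=dataset.confounder, provenance=dict(dataset.provenance))
        try:
            draws.append(estimator(boot).aligned())
        except (FitError, PathTracingError) as exc:
            n_failed += 1
            warnings.warn(f"bootstrap replicate failed: {exc}")
            if n_failed > max_failure_rate * B:
                raise RuntimeError(
                    f"{n_failed}/{B} bootstrap replicates failed; aborting") from exc
    reps = pd.DataFrame(draws).reset_index(drop=True)
    alpha = (1.0 - ci_level) / 2.0
    se = reps.std(ddof=1)
    lo = reps.quantile(alpha)
    hi = reps.quantile(1.0 - alpha)
    table = point.table.copy()
    key = list(zip(table["dimension"], table["category"]))
    table["se"] = se.reindex(key).to_numpy()
    table["ci_lo"] = lo.reindex(key).to_numpy()
    table["ci_hi"] = hi.reindex(key).to_numpy()
    est = APCEstimates(table=table, tag=point.tag, scale=point.scale, notes=point.notes)
    return BootstrapResult(estimates=est, replicates=reps, n_requested=B, n_failed=n_failed)


def estimate(
    dataset: APCDataset,
    mediators: Sequence[str] | None = None,
    exposures: Mapping[str, Sequence[str]] | None = None,
    confounder: str | None = None,
    family: str | None = None,
) -> APCEstimates:
    """Convenience wrapper: Steps 1-2 plus path tracing in one call."""
    med_fits = fit_mediator_models(dataset, mediators, exposures, binary_family=family)
    out_fit = fit_outcome_model(dataset, mediators, confounder=confounder, family=family)
    return path_trace(med_fits, out_fit, dataset.scheme)
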