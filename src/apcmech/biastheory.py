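"""Closed-form expected-coefficient algebra for omitted APC dimensions.

In a linear associational model ``Y = eta + alpha*A + beta*P + theta*C + e``
the identity ``P = A + C`` lets the contribution of any omitted time
dimension be rewritten into the retained two.  Dropping period gives an
age-cohort model with expected coefficients ``(alpha + beta, theta + beta)``
— the period effect is attributed to age and cohort in equal parts.
Dropping age gives a period-cohort model with ``(beta + alpha, theta -
alpha)``; dropping cohort an age-period model with ``(alpha - theta, beta +
theta)``.

The same reattribution drives the bias of the mechanism-based estimator when
period mediators are *omitted*: each omitted pathway's slope product
(period->mediator x mediator->outcome) is added to both the age and the
cohort coefficient and lost from the recovered period effect.

These closed forms are written for scalar slopes (continuous A, P, C).  In
the categorical setting with equal-width bins they apply to the linear
component of each dummy profile.  They are exposed as a calculator and used
as the oracle for the simulation harness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import statsmodels.api as sm

TWO_DIM_MODELS = ("age-cohort", "period-cohort", "age-period")


@dataclass(frozen=True)
class TrueEffects:
    """Slopes of the (unidentified) linear associational APC model."""

    alpha: float  # age
    beta: float  # period
    theta: float  # cohort
    eta: float = 0.0  # intercept

    def __post_init__(self) -> None:
        for v in (self.alpha, self.beta, self.theta, self.eta):
            if not np.isfinite(v):
                raise ValueError("effects must be finite")


@dataclass(frozen=True)
class OmittedModelExpectation:
    """Expected coefficients of the two retained dimensions."""

    model: str
    retained: tuple[str, str]
    coefficients: tuple[float, float]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.retained, self.coefficients))


def expected_coeffs(true: TrueEffects, model: str) -> OmittedModelExpectation:
    """Expected two-dimension coefficients when one dimension is omitted."""
    a, b, t = true.alpha, true.beta, true.theta
    if model == "age-cohort":
        return OmittedModelExpectation(model, ("age", "cohort"), (a + b, t + b))
    if model == "period-cohort":
        return OmittedModelExpectation(model, ("period", "cohort"), (b + a, t - a))
    if model == "age-period":
        return OmittedModelExpectation(model, ("age", "period"), (a - t, b + t))
    raise ValueError(f"unknown model {model!r}; expected one of {TWO_DIM_MODELS}")


@dataclass(frozen=True)
class OmittedMediatorBias:
    """Additive bias from omitting period mediators in the front-door estimator."""

    age: float
    cohort: float
    period: float


def omitted_mediator_bias(
    path_coeffs: dict[str, tuple[float, float]],
    omitted: Iterable[str],
) -> OmittedMediatorBias:
    """Bias on directly-estimated age/cohort slopes from omitted mediators.

    ``path_coeffs`` maps mediator name to ``(gamma, delta)`` — the
    period->mediator and mediator->outcome slopes of a *linear* model.  Each
    omitted pathway contributes its product ``gamma * delta`` to both the age
    and the cohort slope, and the recovered period slope loses it (bias
    ``-gamma * delta``).  Opposite-sign products cancel.
    """
    omitted = list(omitted)
    unknown = [m for m in omitted if m not in path_coeffs]
    if unknown:
        raise KeyError(f"unknown mediator(s): {unknown}")
    s = float(sum(path_coeffs[m][0] * path_coeffs[m][1] for m in omitted))
    return OmittedMediatorBias(age=s, cohort=s, period=-s)


@dataclass
class OLSComparison:
    model: str
    expected: tuple[float, float]
    fitted: tuple[float, float]
    se: tuple[float, float]
    within_3se: bool


def verify_against_ols(
    true: TrueEffects,
    n: int = 100_000,
    noise_sd: float = 1.0,
    seed: int = 0,
    models: Iterable[str] = TWO_DIM_MODELS,
) -> list[OLSComparison]:
    """Check the closed forms against OLS on identity-constrained data.

    Simulates ``A`` and ``C`` independently, sets ``P = A + C``, draws ``Y``
    from the full three-slope model, fits each requested two-dimension
    regression, and reports whether the fitted coefficients land within 3
    standard errors of the closed-form expectation (exact at zero noise).
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.0, 10.0, n)
    C = rng.uniform(0.0, 10.0, n)
    P = A + C
    Y = (true.eta + true.alpha * A + true.beta * P + true.theta * C
         + rng.normal(0.0, noise_sd, n))
    regressors = {"age": A, "period": P, "cohort": C}
    out = []
    for model in models:
        exp = expected_coeffs(true, model)
        X = sm.add_constant(np.column_stack([regressors[d] for d in exp.retained]))
        res = sm.OLS(Y, X).fit()
        fitted = tuple(float(v) for v in res.params[1:])
        se = tuple(float(v) for v in res.bse[1:])
        ok = all(abs(f - e) <= max(3.0 * s, 1e-8)
                 for f, e, s in zip(fitted, exp.coefficients, se))
        out.append(OLSComparison(model=model, expected=exp.coefficients,
                                 fitted=fitted, se=se, within_3se=ok))
    return out
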