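"""Simulation-study harness: scenario x variant x mis-specification grids.

Reproduces the package's simulation experiments at configurable scale:
generate data under a scenario, estimate the APC effects under the correct
specification and under named mis-specifications, replicate, and summarise.
Bias is always computed against the *correctly specified* cell's mean
estimate — at large n the correctly specified estimates serve as the truth,
which keeps probit and logistic variants on their own (non-comparable) link
scales.

Mis-specification steps
-----------------------
``correct``                        all mediators, all paths, confounder controlled
``drop_unmeasured``                remove the unmeasured mediator from estimation
``drop_unmeasured_bmi``            ... then BMI
``drop_unmeasured_bmi_smoking``    ... then smoking
``drop_all``                       age-cohort model, no period mediators
``omit_extra_paths``               (more_causes) ignore age->BMI and cohort->smoking
``omit_confounder``                (confounding) do not control for genotype

The default scale (reps = 20, n = 20,000) is a desk preset; the full-scale
design (reps = 1,000, n = 100,000) is available via
:meth:`ExperimentSpec.paper_scale`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import mcfrontdoor, pathtrace
from .core import APCDataset, DIMENSIONS
from .datagen import ScenarioConfig, calibrate, generate
from .pathtrace import APCEstimates, FitError

log = logging.getLogger(__name__)

REMOVAL_SEQUENCE = ("correct", "drop_unmeasured", "drop_unmeasured_bmi",
                    "drop_unmeasured_bmi_smoking", "drop_all")
_DROP = {
    "correct": (),
    "drop_unmeasured": ("unmeasured",),
    "drop_unmeasured_bmi": ("unmeasured", "bmi"),
    "drop_unmeasured_bmi_smoking": ("unmeasured", "bmi", "smoking"),
    "drop_all": ("unmeasured", "bmi", "smoking", "statin"),
    "omit_extra_paths": (),
    "omit_confounder": (),
}

AUTO_MISSPECS = {
    "simple": REMOVAL_SEQUENCE,
    "more_causes": ("correct", "omit_extra_paths"),
    "confounding": ("correct", "omit_confounder"),
}


@dataclass(frozen=True)
class ExperimentSpec:
    """Declarative description of a simulation experiment."""

    scenarios: tuple[str, ...] = ("simple",)
    variants: tuple[str, ...] = ("probit",)
    misspecs: tuple[str, ...] | str = "auto"
    reps: int = 20
    n: int = 20_000
    estimator: str = "auto"  # pathtrace | mcfrontdoor | auto
    seed: int = 0
    mc_draws: int = 150_000
    shares: tuple[float, float, float] = (0.70, 0.20, 0.10)
    failure_threshold: float = 0.2

    @classmethod
    def paper_scale(cls, **kw) -> "ExperimentSpec":
        """Full-scale design: 1,000 replications of n = 100,000."""
        return cls(reps=1_000, n=100_000, **kw)

    def misspecs_for(self, scenario: str) -> tuple[str, ...]:
        if self.misspecs == "auto":
            return AUTO_MISSPECS[scenario]
        return tuple(self.misspecs)

    def estimator_for(self, variant: str) -> str:
        if self.estimator != "auto":
            return self.estimator
        return "mcfrontdoor" if variant == "logistic" else "pathtrace"


@dataclass
class ExperimentResult:
    """Per-cell means/SDs across replications, with bias vs the correct cell."""

    spec: ExperimentSpec
    table: pd.DataFrame  # scenario, variant, misspec, dimension, category, mean, sd, nreps, bias
    failures: pd.DataFrame

    def cell(self, scenario: str, variant: str, misspec: str) -> pd.DataFrame:
        t = self.table
        return t[(t.scenario == scenario) & (t.variant == variant)
                 & (t.misspec == misspec)].copy()

    def bias_slope(self, scenario: str, variant: str, misspec: str, dimension: str) -> float:
        """Linear trend of the bias across a dimension's categories.

        The identity-driven reattribution of an omitted pathway is linear in
        the category index, so a fitted slope is a stable one-number summary
        of the bias in that dimension.
        """
        sub = self.cell(scenario, variant, misspec)
        sub = sub[sub.dimension == dimension].sort_values("category")
        if len(sub) < 2:
            return 0.0
        return float(np.polyfit(sub["category"], sub["bias"], 1)[0])

    def to_csv(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out_dir / "cells.csv", index=False)
        self.failures.to_csv(out_dir / "failures.csv", index=False)


def _exposures_for(scenario: str, misspec: str) -> dict[str, tuple[str, ...]]:
    if scenario == "more_causes" and misspec != "omit_extra_paths":
        return {"bmi": ("period", "age"), "smoking": ("period", "cohort")}
    if scenario == "confounding" and misspec != "omit_confounder":
        return {"bmi": ("period", "genotype"), "smoking": ("period", "genotype")}
    return {}


def _confounder_for(scenario: str, misspec: str) -> str | None:
    if scenario == "confounding" and misspec != "omit_confounder":
        return "genotype"
    return None


def estimate_cell(
    dataset: APCDataset,
    scenario: str,
    misspec: str,
    estimator: str,
    mc_draws: int = 150_000,
    mc_seed: int = 0,
    _fit_cache: dict | None = None,
) -> APCEstimates:
    """Run one estimator under one (mis-)specification of one dataset."""
    drop = _DROP[misspec]
    mediators = [m for m in dataset.mediators if m not in drop]
    exposures = _exposures_for(scenario, misspec)
    confounder = _confounder_for(scenario, misspec)
    family = {"probit": "probit", "logistic": "logit", "linear": "linear"}.get(
        dataset.provenance.get("variant"), None)

    if not mediators:
        # age-cohort model: no mediated pathway, period effect forced to zero
        out_fit = pathtrace.fit_outcome_model(dataset, mediators=[], family=family)
        est = pathtrace.path_trace([], out_fit, dataset.scheme)
        est.tag = "direct"
        return est

    if estimator == "pathtrace":
        cache = _fit_cache if _fit_cache is not None else {}
        key = tuple(sorted(exposures.items()))
        if key not in cache:
            cache[key] = {f.name: f for f in pathtrace.fit_mediator_models(
                dataset, dataset.mediators, exposures, binary_family=family)}
        med_fits = [cache[key][m] for m in mediators]
        out_fit = pathtrace.fit_outcome_model(
            dataset, mediators, confounder=confounder, family=family)
        return pathtrace.path_trace(med_fits, out_fit, dataset.scheme)

    if estimator == "mcfrontdoor":
        config = mcfrontdoor.MCConfig(n_draws=mc_draws, seed=mc_seed)
        return mcfrontdoor.estimate(dataset, mediators, config, confounder=confounder,
                                    exposures=exposures, family=family)
    raise ValueError(f"unknown estimator {estimator!r}")


def run(spec: ExperimentSpec) -> ExperimentResult:
    """Execute the full grid; deterministic given ``spec.seed``."""
    rows = []
    failures = []
    cells = list(itertools.product(spec.scenarios, spec.variants))
    for cell_idx, (scenario, variant) in enumerate(cells):
        misspecs = spec.misspecs_for(scenario)
        estimator = spec.estimator_for(variant)
        base_cfg = ScenarioConfig(scenario=scenario, variant=variant, n=spec.n,
                                  seed=0, shares=spec.shares)
        params = calibrate(base_cfg)
        n_failed = 0
        for rep in range(spec.reps):
            rep_seed = int(np.random.SeedSequence(
                [spec.seed, cell_idx, rep]).generate_state(1)[0] % (2**31))
            cfg = replace(base_cfg, seed=rep_seed)
            dataset = generate(cfg, replace(params, config=cfg))
            fit_cache: dict = {}
            for misspec in misspecs:
                try:
                    est = estimate_cell(dataset, scenario, misspec, estimator,
                                        spec.mc_draws, mc_seed=rep_seed,
                                        _fit_cache=fit_cache)
                except FitError as exc:
                    n_failed += 1
                    failures.append({"scenario": scenario, "variant": variant,
                                     "misspec": misspec, "rep": rep, "error": str(exc)})
                    log.warning("replication failed: %s", exc)
                    continue
                t = est.table
                for _, r in t.iterrows():
                    rows.append({"scenario": scenario, "variant": variant,
                                 "misspec": misspec, "rep": rep,
                                 "dimension": r["dimension"],
                                 "category": int(r["category"]),
                                 "estimate": r["estimate"]})
        if n_failed > spec.failure_threshold * spec.reps * len(misspecs):
            log.error("cell (%s, %s) invalidated: %d failures", scenario, variant, n_failed)
            rows = [r for r in rows
                    if not (r["scenario"] == scenario and r["variant"] == variant)]

    raw = pd.DataFrame(rows)
    if raw.empty:
        return ExperimentResult(spec, pd.DataFrame(columns=[
            "scenario", "variant", "misspec", "dimension", "category",
            "mean", "sd", "nreps", "bias"]), pd.DataFrame(failures))
    agg = (raw.groupby(["scenario", "variant", "misspec", "dimension", "category"])
           ["estimate"].agg(["mean", "std", "count"]).reset_index()
           .rename(columns={"std": "sd", "count": "nreps"}))
    correct = agg[agg.misspec == "correct"].set_index(
        ["scenario", "variant", "dimension", "category"])["mean"]
    key = list(zip(agg.scenario, agg.variant, agg.dimension, agg.category))
    agg["bias"] = agg["mean"].to_numpy() - correct.reindex(key).to_numpy()
    return ExperimentResult(spec, agg, pd.DataFrame(failures))


# ------------------------------------------------------------- effect sweeps
def sweep_shares(swept: str, increment: float) -> tuple[float, float, float] | None:
    """APC shares for one increment of an effect-size sweep.

    Period sweep: cohort pinned at 10 % (0 at the final increment), age
    absorbs the rest.  Cohort sweep: period pinned at 20 % (reduced at the
    final increments), age absorbs the rest.  Returns None if infeasible.
    """
    s = float(increment)
    if not 0.0 <= s <= 1.0:
        return None
    if swept == "period":
        cohort = min(0.10, 1.0 - s)
        age = 1.0 - s - cohort
        shares = (age, s, cohort)
    elif swept == "cohort":
        period = min(0.20, 1.0 - s)
        age = 1.0 - s - period
        shares = (age, period, s)
    else:
        raise ValueError(f"swept dimension must be 'period' or 'cohort', got {swept!r}")
    return shares if min(shares) >= -1e-12 else None


def vary_effect_sizes(
    swept: str = "period",
    increments: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8),
    omitted: Sequence[str] = ("unmeasured",),
    variant: str = "probit",
    reps: int = 10,
    n: int = 20_000,
    seed: int = 0,
    estimator: str = "auto",
    mc_draws: int = 150_000,
) -> pd.DataFrame:
    """Bias from dropping a mediator while sweeping one dimension's share.

    For each increment the simple scenario is re-calibrated with the swept
    share, data are generated ``reps`` times, and the estimator is run
    correctly specified and with ``omitted`` dropped.  Returns one row per
    (increment, dimension) with the mean bias slope across categories.
    """
    rows = []
    drop_step = {("unmeasured",): "drop_unmeasured"}.get(tuple(omitted))
    for inc_idx, inc in enumerate(increments):
        shares = sweep_shares(swept, inc)
        if shares is None:
            log.warning("skipping infeasible increment %s", inc)
            continue
        cfg0 = ScenarioConfig(scenario="simple", variant=variant, n=n, seed=0,
                              shares=shares)
        params = calibrate(cfg0)
        est_name = ExperimentSpec(estimator=estimator).estimator_for(variant)
        diffs: dict[str, list[np.ndarray]] = {d: [] for d in DIMENSIONS}
        for rep in range(reps):
            rep_seed = int(np.random.SeedSequence(
                [seed, inc_idx, rep]).generate_state(1)[0] % (2**31))
            cfg = replace(cfg0, seed=rep_seed)
            ds = generate(cfg, replace(params, config=cfg))
            cache: dict = {}
            correct = estimate_cell(ds, "simple", "correct", est_name,
                                    mc_draws, rep_seed, cache)
            if drop_step is not None:
                dropped = estimate_cell(ds, "simple", drop_step, est_name,
                                        mc_draws, rep_seed, cache)
            else:
                sub = ds.drop_mediators(list(omitted))
                dropped = estimate_cell(sub, "simple", "correct", est_name,
                                        mc_draws, rep_seed, {})
            for d in DIMENSIONS:
                diffs[d].append(dropped.values(d) - correct.values(d))
        for d in DIMENSIONS:
            mean_diff = np.mean(diffs[d], axis=0)
            slope = float(np.polyfit(np.arange(len(mean_diff)), mean_diff, 1)[0])
            rows.append({"swept": swept, "increment": inc,
                         "share_age": shares[0], "share_period": shares[1],
                         "share_cohort": shares[2], "dimension": d,
                         "bias_slope": slope,
                         "bias_magnitude": abs(slope),
                         "max_abs_bias": float(np.max(np.abs(mean_diff)))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- reporting
def report(result: ExperimentResult) -> str:
    """Human-readable per-cell summary tables."""
    if result.table.empty:
        return "no results\n"
    lines = []
    for (scenario, variant), sub in result.table.groupby(["scenario", "variant"]):
        lines.append(f"== scenario={scenario} variant={variant} "
                     f"(reps={result.spec.reps}, n={result.spec.n}) ==")
        pivot = sub.pivot_table(index=["dimension", "category"],
                                columns="misspec", values="bias")
        lines.append(pivot.round(4).to_string())
        lines.append("")
    if len(result.failures):
        lines.append(f"{len(result.failures)} replication failure(s) logged")
    return "\n".join(lines) + "\n"


def plot_estimates(result: ExperimentResult, out_path: str | Path,
                   scenario: str, variant: str) -> None:
    """Estimate-vs-category curves per mis-specification (one panel per dimension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=False)
    for ax, dim in zip(axes, DIMENSIONS):
        sub = result.cell(scenario, variant, "correct")
        for misspec in result.table[(result.table.scenario == scenario)
                                    & (result.table.variant == variant)].misspec.unique():
            cell = result.cell(scenario, variant, misspec)
            cell = cell[cell.dimension == dim].sort_values("category")
            ax.plot(cell["category"], cell["mean"], marker="o", ms=3, label=misspec)
        ax.set_title(dim)
        ax.set_xlabel("category")
    axes[0].set_ylabel("mean estimate (link scale)")
    axes[0].legend(fontsize=7)
    fig.suptitle(f"{scenario} / {variant}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
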