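import numpy as np
import pandas as pd
import pytest

from apcmech import datagen, pathtrace
from apcmech.pathtrace import (APCEstimates, MediatorModelFit, OutcomeModelFit,
                               PathTracingError, bootstrap, delta_method_se,
                               fit_mediator_models, fit_outcome_model, path_trace,
                               product_se)

from conftest import make_tiny_dataset


def _fit(name, coefs, sigma=1.0, family="linear", exposures=("period",)):
    return MediatorModelFit(name=name, family=family, params=coefs,
                            exposures=exposures, sigma=sigma)


class TestMediatorFits:
    def test_one_fit_per_mediator_with_period_dummies(self, simple_probit):
        ds, _ = simple_probit
        fits = fit_mediator_models(ds)
        assert len(fits) == 4
        for f in fits:
            period_keys = [k for k in f.params if k.startswith("period_")]
            assert len(period_keys) == 4
            if f.family == "linear":
                assert f.sigma > 0
            else:
                assert f.sigma is None

    def test_null_mediator_recovers_zero(self, scheme):
        rng = np.random.default_rng(3)
        ds = make_tiny_dataset(scheme, n=4000, seed=3,
                               mediator=("noise", rng.normal(size=4000)))
        (fit,) = fit_mediator_models(ds, ["noise"])
        for k in range(1, 5):
            se = np.sqrt(fit.cov.loc[f"period_{k}", f"period_{k}"])
            assert abs(fit.params[f"period_{k}"]) < 3 * se

    def test_more_causes_bmi_age_coefficients_negative(self):
        cfg = datagen.ScenarioConfig(scenario="more_causes", n=30_000, seed=21)
        ds = datagen.generate(cfg)
        (fit,) = fit_mediator_models(ds, ["bmi"], exposures={"bmi": ("period", "age")})
        age_coefs = [fit.params[f"age_{k}"] for k in range(1, 11)]
        assert age_coefs[-1] < 0 and np.mean(age_coefs) < 0


class TestOutcomeFit:
    def test_probit_coefficient_layout(self, simple_probit):
        ds, _ = simple_probit
        fit = fit_outcome_model(ds)
        assert fit.family == "probit"
        keys = set(fit.params)
        assert sum(k.startswith("age_") for k in keys) == 10
        assert sum(k.startswith("cohort_") for k in keys) == 14
        assert not any(k.startswith("period_") for k in keys)
        assert {"unmeasured", "bmi", "smoking", "statin", "const"} <= keys

    def test_linear_variant_recovers_generator_deltas(self, simple_linear):
        ds, params = simple_linear
        fit = fit_outcome_model(ds)
        for name, m in params.mediators.items():
            se = np.sqrt(fit.cov.loc[name, name])
            assert abs(fit.params[name] - m.delta) < 3.5 * se

    def test_unrelated_mediator_delta_near_zero(self, scheme):
        rng = np.random.default_rng(4)
        n = 5000
        noise = rng.normal(size=n)
        ds = make_tiny_dataset(scheme, n=n, seed=4, mediator=("noise", noise),
                               outcome=rng.normal(size=n))
        fit = fit_outcome_model(ds, ["noise"])
        se = np.sqrt(fit.cov.loc["noise", "noise"])
        assert abs(fit.params["noise"]) < 3 * se


class TestPathTrace:
    def test_single_product(self, scheme):
        med = _fit("m1", {"const": 0.0, "period_1": 0.5})
        out = OutcomeModelFit(family="linear", params={"const": 0, "m1": 0.4},
                              mediators=("m1",), sigma=1.0)
        est = path_trace([med], out, scheme)
        assert est.values("period")[1] == pytest.approx(0.5 * 0.4)
        assert est.values("period")[0] == 0.0

    def test_two_pathways_sum(self, scheme):
        m1 = _fit("m1", {"const": 0.0, "period_1": 0.5})
        m2 = _fit("m2", {"const": 0.0, "period_1": -0.6})
        out = OutcomeModelFit(family="linear", params={"m1": 0.4, "m2": 0.5},
                              mediators=("m1", "m2"), sigma=1.0)
        est = path_trace([m1, m2], out, scheme)
        assert est.values("period")[1] == pytest.approx(0.5 * 0.4 + (-0.6) * 0.5)

    def test_linear_variant_recovers_generator_truth(self, simple_linear):
        """Complete mediators + correct families: the correct-specification baseline."""
        ds, params = simple_linear
        est = pathtrace.estimate(ds)
        truth = datagen.linear_truth(params)
        boot = bootstrap(ds, pathtrace.estimate, B=40, seed=5)
        t = boot.estimates.table.set_index(["dimension", "category"])
        for dim in ("age", "period", "cohort"):
            for k in range(1, ds.scheme.n_categories(dim)):
                se = t.loc[(dim, k), "se"]
                assert abs(est.values(dim)[k] - truth[dim][k]) < 3.5 * se

    def test_logistic_fits_refused(self, scheme, simple_logistic):
        ds, _ = simple_logistic
        med_fits = fit_mediator_models(ds)
        out_fit = fit_outcome_model(ds)
        assert out_fit.family == "logit"
        with pytest.raises(PathTracingError, match="mcfrontdoor"):
            path_trace(med_fits, out_fit, scheme)

    def test_product_terms_refused(self, scheme):
        med = _fit("m1", {"const": 0.0, "period_1": 0.5})
        out = OutcomeModelFit(family="linear", params={"m1": 0.4, "m1:age_1": 0.1},
                              mediators=("m1",), sigma=1.0)
        with pytest.raises(PathTracingError, match="product terms"):
            path_trace([med], out, scheme)

    def test_probit_output_flagged_as_approximation(self, simple_probit):
        ds, _ = simple_probit
        est = pathtrace.estimate(ds)
        assert any("approximation" in n for n in est.notes)


class TestDeltaMethod:
    def test_closed_form(self):
        assert product_se(0.5, 0.1, 0.4, 0.2) == pytest.approx(
            np.sqrt(0.25 * 0.04 + 0.16 * 0.01))
        assert product_se(0.5, 0.1, 0.4, 0.2) == pytest.approx(0.1077, abs=1e-4)

    def test_zero_se_degenerates_to_surviving_term(self):
        assert product_se(0.5, 0.0, 0.4, 0.2) == pytest.approx(0.5 * 0.2)
        assert product_se(0.5, 0.1, 0.4, 0.0) == pytest.approx(0.4 * 0.1)

    def test_nonlinear_or_multipath_refused(self, simple_probit):
        ds, _ = simple_probit
        med_fits = fit_mediator_models(ds)
        out_fit = fit_outcome_model(ds)
        with pytest.raises(PathTracingError):
            delta_method_se(med_fits[0], out_fit)

    def test_agrees_with_bootstrap_on_linear_data(self, scheme):
        """Single linear pathway: analytic SE within 15 % of the bootstrap SE."""
        rng = np.random.default_rng(8)
        n = 10_000
        ds = make_tiny_dataset(scheme, n=n, seed=8, mediator=("m", np.zeros(n)))
        med = 1.0 + 0.3 * ds.df.p_idx.to_numpy() + rng.normal(0, 1, n)
        ds.df["m"] = med
        ds.df["outcome"] = 0.5 * med + rng.normal(0, 1, n)

        (med_fit,) = fit_mediator_models(ds, ["m"])
        out_fit = fit_outcome_model(ds, ["m"], direct_dims=())
        analytic = delta_method_se(med_fit, out_fit)

        def estimator(d):
            (mf,) = fit_mediator_models(d, ["m"])
            of = fit_outcome_model(d, ["m"], direct_dims=())
            return path_trace([mf], of, d.scheme)

        boot = bootstrap(ds, estimator, B=500, seed=9)
        t = boot.estimates.table.set_index(["dimension", "category"])
        for k in range(1, 5):
            boot_se = t.loc[("period", k), "se"]
            assert analytic[f"period_{k}"] == pytest.approx(boot_se, rel=0.15)


class TestBootstrap:
    def test_seed_reproducibility(self, simple_linear):
        ds, _ = simple_linear
        sub = ds.df.sample(3000, random_state=0).reset_index(drop=True)
        small = type(ds)(df=sub, scheme=ds.scheme, mediators=ds.mediators,
                         mediator_kinds=dict(ds.mediator_kinds),
                         provenance=dict(ds.provenance))
        b1 = bootstrap(small, pathtrace.estimate, B=10, seed=3)
        b2 = bootstrap(small, pathtrace.estimate, B=10, seed=3)
        pd.testing.assert_frame_equal(b1.replicates, b2.replicates)

    def test_degenerate_dataset_zero_se(self, scheme):
        n = 200
        ds = make_tiny_dataset(scheme, n=4, seed=1, mediator=("m", np.ones(4)))
        df = pd.concat([ds.df.iloc[[0]]] * n, ignore_index=True)
        df["m"] = 1.0 + 0.001 * np.arange(n)  # break exact singularity only in m
        degen = type(ds)(df=df, scheme=ds.scheme, mediators=("m",),
                         provenance={"variant": "linear"})

        def estimator(d):
            of = fit_outcome_model(d, ["m"], direct_dims=())
            table = pd.DataFrame([{"dimension": "period", "category": 0,
                                   "estimate": of.params["m"]}])
            return APCEstimates(table=table, tag="direct", scale="linear")

        # all rows identical in (a, p, c): resampling cannot change the fit
        # beyond the m-column, whose relationship to outcome is constant
        boot = bootstrap(degen, estimator, B=10, seed=2)
        assert boot.estimates.table["se"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_percentile_ci_covers_linear_truth(self, simple_linear):
        """95 % percentile intervals cover the generator truth for the large
        majority of parameters on correctly specified linear data."""
        ds, params = simple_linear
        sub = ds.df.sample(6000, random_state=2).reset_index(drop=True)
        small = type(ds)(df=sub, scheme=ds.scheme, mediators=ds.mediators,
                         mediator_kinds=dict(ds.mediator_kinds),
                         provenance=dict(ds.provenance))
        boot = bootstrap(small, pathtrace.estimate, B=200, seed=4)
        truth = datagen.linear_truth(params)
        t = boot.estimates.table.set_index(["dimension", "category"])
        covered = total = 0
        for dim in ("age", "period", "cohort"):
            for k in range(1, ds.scheme.n_categories(dim)):
                lo, hi = t.loc[(dim, k), ["ci_lo", "ci_hi"]]
                covered += lo <= truth[dim][k] <= hi
                total += 1
        assert covered / total >= 0.85

    def test_requires_at_least_two_replicates(self, simple_linear):
        ds, _ = simple_linear
        with pytest.raises(ValueError):
            bootstrap(ds, pathtrace.estimate, B=1)
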