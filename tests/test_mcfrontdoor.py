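import numpy as np
import pytest
from scipy.special import expit

from apcmech import mcfrontdoor, pathtrace
from apcmech.mcfrontdoor import (MCConfig, draw_categories, estimate,
                                 fit_apc_on_simulated, simulate_mediators,
                                 simulate_outcomes, simulate_world)
from apcmech.pathtrace import MediatorModelFit, OutcomeModelFit


def _linear_fit(name="m", const=1.0, slopes=(0.5, 1.0, 1.5, 2.0), sigma=0.0):
    params = {"const": const}
    params.update({f"period_{k + 1}": s for k, s in enumerate(slopes)})
    return MediatorModelFit(name=name, family="linear", params=params, sigma=sigma)


class TestSimulateMediators:
    def test_zero_noise_linear_is_exact(self, scheme):
        fit = _linear_fit(const=1.0, slopes=(0.5, 1.0, 1.5, 2.0), sigma=0.0)
        rng = np.random.default_rng(0)
        p = np.array([0, 2, 4])
        out = simulate_mediators([fit], p, scheme, rng)["m"]
        assert out == pytest.approx([1.0, 2.0, 3.0], abs=1e-12)

    def test_null_logistic_mediator_mean_half(self, scheme):
        fit = MediatorModelFit(name="b", family="logit", params={"const": 0.0})
        rng = np.random.default_rng(1)
        p = np.zeros(20_000, dtype=int)
        out = simulate_mediators([fit], p, scheme, rng)["b"]
        assert set(np.unique(out)) <= {0.0, 1.0}
        assert out.mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(len(p)))

    def test_binary_mean_matches_closed_form_link_inversion(self, scheme):
        fit = MediatorModelFit(name="b", family="logit",
                               params={"const": -0.4, "period_3": 0.9})
        rng = np.random.default_rng(2)
        n = 100_000
        p = np.full(n, 3)
        out = simulate_mediators([fit], p, scheme, rng)["b"]
        want = expit(-0.4 + 0.9)
        assert out.mean() == pytest.approx(want, abs=3 * np.sqrt(want * (1 - want) / n))

    def test_out_of_range_period_rejected(self, scheme):
        with pytest.raises(ValueError, match="range"):
            simulate_mediators([_linear_fit()], np.array([5]), scheme,
                               np.random.default_rng(0))


class TestSimulateOutcomes:
    def _draws(self, scheme, n, seed=0):
        rng = np.random.default_rng(seed)
        return (rng.integers(0, scheme.n_age, n), rng.integers(0, scheme.n_period, n),
                rng.integers(0, scheme.n_cohort, n), rng)

    def test_null_logistic_outcome_mean_half(self, scheme):
        a, p, c, rng = self._draws(scheme, 20_000)
        fit = OutcomeModelFit(family="logit", params={"const": 0.0}, mediators=())
        y = simulate_outcomes(fit, {}, a, p, c, scheme, rng)
        assert y.mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(len(y)))

    def test_zero_noise_linear_equals_linear_predictor(self, scheme):
        a, p, c, rng = self._draws(scheme, 500)
        fit = OutcomeModelFit(family="linear",
                              params={"const": 0.3, "age_1": 0.2, "m": 0.5},
                              mediators=("m",), sigma=0.0)
        m_vals = np.ones(500)
        y = simulate_outcomes(fit, {"m": m_vals}, a, p, c, scheme, rng)
        want = 0.3 + 0.2 * (a == 1) + 0.5
        assert y == pytest.approx(want, abs=1e-12)

    def test_identity_constrained_draws_rejected(self, scheme):
        rng = np.random.default_rng(3)
        a = rng.integers(0, scheme.n_age, 100)
        p = rng.integers(0, scheme.n_period, 100)
        c = p - a + scheme.n_age - 1
        fit = OutcomeModelFit(family="linear", params={"const": 0.0},
                              mediators=(), sigma=1.0)
        with pytest.raises(ValueError, match="independent"):
            simulate_outcomes(fit, {}, a, p, c, scheme, rng)

    def test_independence_of_draws(self, scheme):
        """Factorial and random designs break the a = p - c relationship."""
        for design in ("factorial", "random"):
            cfg = MCConfig(n_draws=50_000, design=design, seed=4)
            a, p, c = draw_categories(scheme, cfg, np.random.default_rng(4))
            r = np.corrcoef(a, p - c)[0, 1]
            assert abs(r) < 0.02


class TestStepFive:
    def test_rank_deficient_world_fails_hard(self, scheme):
        import pandas as pd
        rng = np.random.default_rng(5)
        a = rng.integers(0, scheme.n_age, 2000)
        p = rng.integers(0, scheme.n_period, 2000)
        c = p - a + scheme.n_age - 1  # identity kept: rank deficient by design
        world = mcfrontdoor.SimulatedWorld(
            df=pd.DataFrame({"a_idx": a, "p_idx": p, "c_idx": c,
                             "outcome": rng.normal(size=2000)}),
            scheme=scheme, family="linear", mediators=())
        with pytest.raises(RuntimeError, match="rank"):
            fit_apc_on_simulated(world)

    def test_null_mediator_effects_give_null_period(self, scheme):
        med = _linear_fit(slopes=(0, 0, 0, 0), sigma=1.0)
        out = OutcomeModelFit(family="linear",
                              params={"const": 0.0, "m": 0.0, "age_1": 1.0},
                              mediators=("m",), sigma=0.5)
        world = simulate_world([med], out, scheme, n_draws=100_000, seed=6)
        est = fit_apc_on_simulated(world)
        assert np.allclose(est.values("period"), 0.0, atol=0.02)


class TestEstimate:
    def test_linear_setting_equals_path_tracing(self, simple_linear):
        ds, _ = simple_linear
        pt = pathtrace.estimate(ds)
        mc = estimate(ds, config=MCConfig(n_draws=200_000, seed=7))
        for dim in ("age", "period", "cohort"):
            assert np.max(np.abs(mc.values(dim) - pt.values(dim))) < 1e-9

    def test_doubling_draws_changes_little(self, simple_logistic):
        ds, _ = simple_logistic
        e1 = estimate(ds, config=MCConfig(n_draws=120_000, seed=8))
        e2 = estimate(ds, config=MCConfig(n_draws=240_000, seed=8))
        se1 = e1.table["mc_se"].fillna(0.0).to_numpy()
        se2 = e2.table["mc_se"].fillna(0.0).to_numpy()
        diff = np.abs(e1.table["estimate"].to_numpy() - e2.table["estimate"].to_numpy())
        # the two runs draw independently: their difference carries both errors
        assert np.all(diff <= 3.5 * np.sqrt(se1**2 + se2**2) + 1e-6)
        assert np.median(se2[se2 > 0]) < np.median(se1[se1 > 0])  # error shrinks in R

    def test_reused_vs_regenerated_period_draws(self, simple_linear):
        ds, _ = simple_linear
        e1 = estimate(ds, config=MCConfig(n_draws=400_000, seed=9, reuse_p=True))
        e2 = estimate(ds, config=MCConfig(n_draws=400_000, seed=9, reuse_p=False))
        tol = 3 * np.nanmax(np.where(e2.table["mc_se"] > 0, e2.table["mc_se"], np.nan))
        diff = np.abs(e1.table["estimate"].to_numpy() - e2.table["estimate"].to_numpy())
        assert np.max(diff) < max(tol, 0.05)

    def test_no_mediators_refused(self, simple_probit):
        ds, _ = simple_probit
        with pytest.raises(ValueError, match="mediator"):
            estimate(ds.drop_mediators(list(ds.mediators)))

    def test_seed_determinism(self, simple_logistic):
        ds, _ = simple_logistic
        cfg = MCConfig(n_draws=60_000, seed=10)
        t1 = estimate(ds, config=cfg).table
        t2 = estimate(ds, config=cfg).table
        assert np.array_equal(t1["estimate"], t2["estimate"])

    def test_interaction_terms_supported(self, scheme):
        """A mediator x age product term in the generating and fitted outcome
        model: estimation proceeds and recovers the marginal APC effects."""
        rng = np.random.default_rng(11)
        n = 30_000
        from conftest import make_tiny_dataset
        ds = make_tiny_dataset(scheme, n=n, seed=11, mediator=("m", np.zeros(n)))
        p = ds.df.p_idx.to_numpy(float)
        a = ds.df.a_idx.to_numpy(float)
        c = ds.df.c_idx.to_numpy(float)
        m = 1.0 - 0.3 * p + rng.normal(0, 1, n)
        y = (0.1 * a - 0.05 * c + 0.4 * m + 0.02 * m * a + rng.normal(0, 1, n))
        ds.df["m"], ds.df["outcome"] = m, y

        def fn(base):
            import pandas as pd
            return pd.DataFrame({"m_x_age": base["m"] * base["a_idx"]})

        est = estimate(ds, ["m"], MCConfig(n_draws=300_000, seed=12),
                       extra_columns_fn=fn)
        # estimand oracle: the same integration run from the true coefficients
        true_med = MediatorModelFit(
            name="m", family="linear", sigma=1.0,
            params={"const": 1.0, **{f"period_{k}": -0.3 * k for k in range(1, 5)}})
        true_out = OutcomeModelFit(
            family="linear", mediators=("m",), sigma=1.0,
            params={"const": 0.0, "m": 0.4, "m_x_age": 0.02,
                    **{f"age_{k}": 0.1 * k for k in range(1, 11)},
                    **{f"cohort_{k}": -0.05 * k for k in range(1, 15)}})
        world = simulate_world([true_med], true_out, scheme, n_draws=300_000,
                               seed=13, extra_columns_fn=fn)
        truth = fit_apc_on_simulated(world)
        for dim in ("age", "period", "cohort"):
            assert np.max(np.abs(est.values(dim) - truth.values(dim))) < 0.06


class TestBootstrapMC:
    def test_seed_fixed_reproducibility(self, simple_logistic):
        ds, _ = simple_logistic
        sub = ds.df.sample(4000, random_state=1).reset_index(drop=True)
        small = type(ds)(df=sub, scheme=ds.scheme, mediators=ds.mediators,
                         mediator_kinds=dict(ds.mediator_kinds),
                         provenance=dict(ds.provenance))
        cfg = MCConfig(n_draws=30_000, seed=1)
        b1 = mcfrontdoor.bootstrap_mc(small, config=cfg, B=3, seed=2)
        b2 = mcfrontdoor.bootstrap_mc(small, config=cfg, B=3, seed=2)
        assert b1.replicates.equals(b2.replicates)
        assert (b1.estimates.table["se"] >= 0).all()
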