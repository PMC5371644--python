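import numpy as np
import pandas as pd
import pytest

from apcmech import core, datagen


@pytest.fixture(scope="session")
def scheme():
    """The default study design: ages 40-95, years 1990-2015, 5-year bins."""
    return core.DEFAULT_SCHEME


@pytest.fixture(scope="session")
def simple_probit():
    """Simple-scenario probit dataset plus its generator params (n = 20,000)."""
    cfg = datagen.ScenarioConfig(scenario="simple", variant="probit", n=20_000, seed=101)
    params = datagen.calibrate(cfg)
    return datagen.generate(cfg, params), params


@pytest.fixture(scope="session")
def simple_linear():
    """Simple-scenario linear-variant dataset (continuous outcome, n = 30,000)."""
    cfg = datagen.ScenarioConfig(scenario="simple", variant="linear", n=30_000, seed=202)
    params = datagen.calibrate(cfg)
    return datagen.generate(cfg, params), params


@pytest.fixture(scope="session")
def simple_logistic():
    cfg = datagen.ScenarioConfig(scenario="simple", variant="logistic", n=30_000, seed=303)
    params = datagen.calibrate(cfg)
    return datagen.generate(cfg, params), params


def make_tiny_dataset(scheme, n=500, seed=0, mediator=None, outcome=None):
    """Hand-rolled APCDataset for unit tests that need full control."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(scheme.age_edges[0], scheme.age_edges[-1], n)
    period = rng.uniform(scheme.period_edges[0], scheme.period_edges[-1], n)
    a, p, c = core.categorize(age, period, scheme)
    df = pd.DataFrame({
        "age": age, "period": period, "cohort": period - age,
        "a_idx": a, "p_idx": p, "c_idx": c,
    })
    mediators = ()
    if mediator is not None:
        name, values = mediator
        df[name] = values
        mediators = (name,)
    df["outcome"] = outcome if outcome is not None else rng.normal(size=n)
    return core.APCDataset(df=df, scheme=scheme, mediators=mediators,
                           provenance={"variant": "linear"})
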