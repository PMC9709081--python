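import numpy as np
import pandas as pd
import pytest

from stillburden import cohort_builder as cb
from stillburden import synthetic_data as sd


def small_config(seed: int = 3, **overrides) -> sd.SimConfig:
    """A fast cohort configuration for unit tests."""
    defaults = dict(
        n_mothers=800,
        n_countries=4,
        n_locations=12,
        years=(2000, 2012),
        n_pixels=60,
        seed=seed,
    )
    defaults.update(overrides)
    return sd.SimConfig(**defaults)


@pytest.fixture(scope="session")
def cfg():
    return small_config()


@pytest.fixture(scope="session")
def environment(cfg):
    return sd.simulate_environment(cfg)


@pytest.fixture(scope="session")
def records(cfg, environment):
    return sd.simulate_pregnancy_histories(cfg, environment)


@pytest.fixture(scope="session")
def stillbirth_sets(records, environment):
    return cb.build_matched_sets(records, environment, "stillbirth")


@pytest.fixture(scope="session")
def risk_inputs(cfg):
    return sd.simulate_risk_inputs(cfg)


def make_sets(rows) -> cb.MatchedSets:
    """Hand-build a MatchedSets from (set_id, is_case, pm25) tuples."""
    df = pd.DataFrame(rows, columns=["set_id", "is_case", "pm25"])
    df["mother_id"] = df["set_id"]
    df["htw_months"] = 7
    for col, val in [
        ("maternal_age", 25.0),
        ("multiparous", 0),
        ("temperature", 22.0),
        ("month", 6),
        ("year", 2005),
        ("nightlight", 3.0),
        ("country_id", 0),
    ]:
        df[col] = val
    return cb.MatchedSets(df)


def enumerate_conditional_loglik(eta_by_set, case_pos) -> float:
    """Independent brute-force oracle for the matched-set likelihood.

    Plain-Python enumeration of the softmax probability that the case is
    the observed member, per set.
    """
    import math

    total = 0.0
    for etas, cpos in zip(eta_by_set, case_pos):
        denom = sum(math.exp(e) for e in etas)
        total += math.log(math.exp(etas[cpos]) / denom)
    return total
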