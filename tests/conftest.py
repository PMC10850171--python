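import datetime as dt

import pytest

import apclaims as ap
from apclaims.cohort import apply_inclusion
from apclaims import exposure as exp_mod


@pytest.fixture(scope="session")
def small_config() -> ap.GeneratorConfig:
    return ap.validated_config(n_patients=300, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return ap.generate_population(small_config)


@pytest.fixture(scope="session")
def edge_bundle(small_bundle):
    return ap.inject_edge_cases(small_bundle)


@pytest.fixture(scope="session")
def edge_cohort(edge_bundle, small_config):
    cohort, attrition = apply_inclusion(edge_bundle, small_config.index_window)
    return cohort, attrition


@pytest.fixture(scope="session")
def edge_exposure(edge_bundle, edge_cohort):
    cohort, _ = edge_cohort
    return exp_mod.exposure_table(edge_bundle, cohort)


@pytest.fixture(scope="session")
def big_config() -> ap.GeneratorConfig:
    return ap.validated_config(n_patients=5000, seed=11)


@pytest.fixture(scope="session")
def big_bundle(big_config):
    return ap.generate_population(big_config)


@pytest.fixture(scope="session")
def big_cohort(big_bundle, big_config):
    cohort, attrition = apply_inclusion(big_bundle, big_config.index_window)
    return cohort, attrition


@pytest.fixture(scope="session")
def big_exposure(big_bundle, big_cohort):
    cohort, _ = big_cohort
    return exp_mod.exposure_table(big_bundle, cohort)


def day_set_oracle(fills, window=(0, 364)):
    """Per-day boolean enumeration of covered days: the independent oracle
    the interval-algebra implementations are checked against."""
    lo, hi = window
    days = set()
    for day, supply in fills:
        for d in range(day, day + supply):
            if lo <= d <= hi:
                days.add(d)
    return days


def stay_day_oracle(stays, window=(0, 364)):
    lo, hi = window
    days = set()
    for adm, dis in stays:
        for d in range(adm, dis + 1):
            if lo <= d <= hi:
                days.add(d)
    return days
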