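"""Shared fixtures: one full-size and one scaled-down synthetic population."""

import warnings

import pytest

import twophase as tp


@pytest.fixture(autouse=True)
def _quiet_runtime_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def full_config():
    return tp.default_config(seed=1234)


@pytest.fixture(scope="session")
def full_population(full_config):
    """82,887-registrant population with outcomes; generated once per session."""
    patients, model = tp.simulate_population(full_config)
    return patients, model


@pytest.fixture(scope="session")
def small_config():
    """~6,200-registrant version of the default scenario for cheap tests."""
    return tp.scaled_config(0.075, seed=77)


@pytest.fixture(scope="session")
def small_population(small_config):
    patients, model = tp.simulate_population(small_config)
    return patients, model


@pytest.fixture(scope="session")
def small_cohorts(small_population):
    patients, _ = small_population
    return tp.aggregate_cohorts(patients)
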