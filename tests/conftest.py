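import numpy as np
import pandas as pd
import pytest

from segflow import EventTable, SamplerConfig, default_gateset
from segflow.orchestrator import ExperimentSpec, ReactorSpec, run_experiment
from segflow.popdyn import sample_events, scenario


@pytest.fixture(scope="session")
def gateset():
    return default_gateset()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_table(n=100, seed=7, time_h=None):
    """Synthetic 4-channel table drawn from a mid-chemostat culture state."""
    state = scenario("chemostat_pulses").initial_state()
    table = sample_events(state, n, seed=seed)
    if time_h is not None:
        table = table.with_meta(time_h=time_h)
    return table


@pytest.fixture
def small_table():
    return make_table(100, seed=7)


@pytest.fixture(scope="session")
def chemostat_pulses_result():
    """One full chemostat->pulses pipeline run, shared across tests."""
    spec = ExperimentSpec(
        reactors=(ReactorSpec("r1", scenario("chemostat_pulses")),),
        duration_h=14.0,
        seed=11,
    )
    result = run_experiment(spec, keep_events=False)
    assert not result.failures
    return result


@pytest.fixture(scope="session")
def unimodal_result():
    spec = ExperimentSpec(
        reactors=(ReactorSpec("u", scenario("unimodal_control")),),
        duration_h=2.0,
        seed=5,
    )
    result = run_experiment(spec, keep_events=False)
    assert not result.failures
    return result
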