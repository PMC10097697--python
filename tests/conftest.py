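import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from lhvalence import (
    Dataset,
    NeuronRecording,
    TaskConfig,
    build_session_schedule,
    get_window,
)


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def small_config():
    # 4 trials per CS, 2 per uncued type: 16-trial blocks for fast tests
    return TaskConfig(trials_per_cs=4, trials_per_uncued_type=2)


@pytest.fixture(scope="session")
def schedule(config):
    return build_session_schedule(config, seed=11)


@pytest.fixture(scope="session")
def small_schedule(small_config):
    return build_session_schedule(small_config, seed=11)


def make_deterministic_neuron(schedule, window_name, rate_fn, neuron_id="d0",
                              baseline_hz=0.0):
    """A neuron with an exact spike count in one analysis window per trial.

    ``rate_fn(trial_row) -> Hz`` sets the rate in the named window (counts
    are placed on a regular grid, so they are exact, not Poisson).
    """
    win = get_window(window_name)
    starts, ends = win.resolve(schedule)
    dur_s = win.duration_ms / 1000.0
    lists = []
    for (s, row) in zip(starts, schedule.itertuples()):
        if np.isnan(s):
            lists.append([])
            continue
        n = int(round(rate_fn(row) * dur_s))
        step = win.duration_ms / max(n, 1)
        lists.append([int(s + i * step) for i in range(n)])
    return NeuronRecording.from_trial_lists(
        neuron_id, list(schedule["trial_id"]), lists)


def dataset_from_neurons(schedule, neurons, config, behavior=None,
                         labels=None):
    return Dataset(trials=schedule, neurons={n.neuron_id: n for n in neurons},
                   behavior=behavior, labels=labels, config=config)
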