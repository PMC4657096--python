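import numpy as np
import pytest

from bgselect import (
    DopamineSchedule,
    LesionSpec,
    TrainingConfig,
    default_params,
    default_weights,
    run_training,
    simulate_trial,
)
from bgselect.experiments import STIMULI


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def weights():
    return default_weights()


@pytest.fixture(scope="session")
def rest_trace(params, weights):
    """Steady state with no stimulus (tonic dopamine 0.45)."""
    return simulate_trial(weights, np.zeros(4), p=params)


@pytest.fixture(scope="session")
def default_trace(params, weights):
    """The single-peaked default stimulus trial."""
    return simulate_trial(weights, np.array(STIMULI["default"]), p=params)


@pytest.fixture(scope="session")
def conflict_traces(params, weights):
    """Conflicting stimulus with intact vs lesioned STN."""
    s = np.array(STIMULI["conflict"])
    intact = simulate_trial(weights, s, p=params)
    lesioned = simulate_trial(weights, s, p=params,
                              lesions=LesionSpec(stn_off=True))
    return intact, lesioned


@pytest.fixture(scope="session")
def feedback_traces(params, weights):
    """Reward and punishment trials (intact and ChI-clamped)."""
    s = np.array(STIMULI["feedback"])
    out = {}
    for kind in ("reward", "punishment"):
        sched = DopamineSchedule(event_kind=kind)
        out[kind] = simulate_trial(weights, s, sched, params, 300.0)
        out[kind + "_nochi"] = simulate_trial(
            weights, s, sched, params, 300.0, LesionSpec(chi_clamped=True))
    return out


@pytest.fixture(scope="session")
def training_history(params, weights):
    """One full intact training run (seed 0) on the training stimulus."""
    return run_training(weights, np.array(STIMULI["training"]),
                        TrainingConfig(seed=0), p=params)


@pytest.fixture(scope="session")
def training_history_nochi(params, weights):
    """The same run with the cholinergic unit pinned at its tonic level."""
    return run_training(weights, np.array(STIMULI["training"]),
                        TrainingConfig(seed=0, chi_clamped=True), p=params)
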