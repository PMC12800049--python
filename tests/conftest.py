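import numpy as np
import pandas as pd
import pytest

from navlearn import synthetic_world as sw
from navlearn import trajectory_metrics as tm
from navlearn.config import AgentProfile, BlockSpec, EnvironmentConfig


@pytest.fixture(scope="session")
def env1() -> EnvironmentConfig:
    return EnvironmentConfig.for_experiment(1)


@pytest.fixture(scope="session")
def env2() -> EnvironmentConfig:
    return EnvironmentConfig.for_experiment(2)


@pytest.fixture(scope="session")
def small_exp1():
    """A small experiment-1 dataset (6 mixed-strategy participants, no gaze)."""
    return sw.generate_experiment(1, n_participants=6, seed=11, with_gaze=False)


@pytest.fixture(scope="session")
def small_exp1_metrics(small_exp1):
    return tm.compute_trial_metrics(small_exp1["tracker"], small_exp1["trials"])


@pytest.fixture(scope="session")
def small_exp2():
    """A small experiment-2 dataset (8 participants, no gaze)."""
    return sw.generate_experiment(2, n_participants=8, seed=13, with_gaze=False)
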