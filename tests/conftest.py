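import numpy as np
import pytest

from stopstate.mep import preprocess
from stopstate.simulate import simulate_dataset
from stopstate.task import TaskSpec

# Scaled-down blocks for unit tests: same structure as the full protocol
# (1-in-4 stop trials, 7 timepoints, catch/baseline trials) at a third of
# the MEP count.
SMALL_SST = TaskSpec(task_label="SST", n_go=21, n_stop=7, n_catch=6, meps_per_timepoint=3)
SMALL_GO = TaskSpec(task_label="GoOnly", n_go=21, n_stop=0, n_catch=6, meps_per_timepoint=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(6, specs=(SMALL_SST, SMALL_GO), seed=11)


@pytest.fixture(scope="session")
def full_dataset():
    """One full-protocol synthetic experiment (16 participants)."""
    return simulate_dataset(16, seed=5)


@pytest.fixture(scope="session")
def full_preprocessed(full_dataset):
    cue, resp, norm, report = preprocess(full_dataset)
    return {"cue": cue, "resp": resp, "norm": norm, "report": report}
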