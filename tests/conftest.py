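import numpy as np
import pytest

from selfother import fbt_design as fd
from selfother.learning_models import ModelSpec


@pytest.fixture(scope="session")
def hi_share_train_seq():
    """One accepted Hi-Share training sequence (448 trials, probes)."""
    return fd.generate_sequence("hi_share", "train", seed=42)


@pytest.fixture(scope="session")
def lo_share_train_seq():
    return fd.generate_sequence("lo_share", "train", seed=42)


@pytest.fixture(scope="session")
def short_seq():
    """A small unscreened sequence for fast fitting tests (160 trials)."""
    rng = np.random.default_rng(0)
    schedule = list(rng.permutation(
        [fd.PRIVILEGED] * 50 + [fd.DECOY] * 50 + [fd.SHARED] * 60))
    wa = fd.generate_random_walk(len(schedule), seed=rng)
    wb = fd.generate_random_walk(len(schedule), seed=rng)
    seq = fd.assign_outcomes(schedule, wa, wb, rng)
    return fd.insert_probes(seq, rng)


@pytest.fixture(scope="session")
def leak_spec():
    return ModelSpec("single", "single", 1, 1, id="leak")


@pytest.fixture(scope="session")
def noleak_spec():
    return ModelSpec("single", "single", 1, 0, id="noleak")
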