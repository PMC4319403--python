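import numpy as np
import pandas as pd
import pytest

from worddecode import (
    ExperimentDesign,
    GeneratorConfig,
    build_schedule,
    simulate_cohort,
    simulate_subject,
)


@pytest.fixture(scope="session")
def default_design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def default_schedule(default_design):
    return build_schedule(default_design, seed=7)


@pytest.fixture(scope="session")
def small_design():
    """Reduced session: 6 trials/noun/language, 6 channels.

    2 runs x 3 repetitions per block keeps every word x speaker pairing
    balanced (2 trials per word, language and speaker), so speaker folds
    stay well formed."""
    return ExperimentDesign.scaled(6, n_channels=6)


@pytest.fixture(scope="session")
def small_schedule(small_design):
    return build_schedule(small_design, seed=11)


@pytest.fixture(scope="session")
def small_epochs(small_schedule):
    """One subject simulated at default (weak-signal) amplitudes."""
    return simulate_subject(small_schedule, GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def nosignal_epochs(small_schedule):
    cfg = GeneratorConfig(seed=13, amp_wordform=0.0, amp_speaker=0.0,
                          amp_concept=0.0)
    return simulate_subject(small_schedule, cfg)


def toy_epochs(data, meta=None, sfreq=250.0, tmin=-1000.0, tmax=1000.0):
    """Wrap a raw array as an EpochedDataset with placeholder metadata."""
    from worddecode import EpochedDataset

    data = np.asarray(data, dtype=float)
    if meta is None:
        meta = pd.DataFrame({"trial": np.arange(data.shape[0])})
    return EpochedDataset(data=data, meta=meta, sampling_rate=sfreq,
                          tmin_ms=tmin, tmax_ms=tmax)
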