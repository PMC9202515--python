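import numpy as np
import pandas as pd
import pytest

from excesstrends import PRESETS, fit_baseline, generate_series

TRAIN = ("2017-01-01", "2019-12-31")
TARGET = ("2020-01-01", "2020-12-31")


def replicate_seeds(master: int, n: int) -> list[int]:
    """Independent 31-bit integer seeds derived from one master seed."""
    state = np.random.SeedSequence(master).generate_state(n, np.uint32)
    return [int(s) for s in state >> np.uint32(1)]


def null_split(seed: int, preset: str = "child_abuse"):
    """One synthetic series split into training and target windows."""
    series = generate_series(PRESETS[preset].replace(seed=seed))
    return series.window(*TRAIN), series.window(*TARGET)


@pytest.fixture(scope="session")
def fitted_null():
    """A fitted baseline plus its training/target series (fixed seed)."""
    train, target = null_split(20_170_101)
    return fit_baseline(train), train, target


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
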