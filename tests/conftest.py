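import numpy as np
import pandas as pd
import pytest

import megrsa as m


@pytest.fixture(scope="session")
def design16():
    """Full factorial crossing, one exemplar per combination."""
    return m.generate_design(1)


@pytest.fixture(scope="session")
def design48():
    """The experimental design: 16 combinations x 3 exemplars."""
    return m.generate_design(3)


@pytest.fixture(scope="session")
def small_noise():
    return m.NoiseSpec(n_channels=20, scale=100.0, cov_rank=3)


@pytest.fixture(scope="session")
def null_epochs(design16, small_noise):
    """One subject of noise-only epochs on a coarse grid."""
    return m.generate_epochs(
        design16, m.SignalSpec.null(), small_noise,
        n_trials_per_condition=20, subject_seed=11, step_ms=10.0,
    )


@pytest.fixture(scope="session")
def size_effect_signal():
    """A strong scene-size effect rising at 140 ms, peaking at 200 ms."""
    return m.SignalSpec(
        effects=(m.EffectSpec("size", 140.0, 200.0, 300.0, 200.0),),
        subject_jitter_sd=0.15,
    )


def make_group_timecourse(values, times=None, chance=0.0):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(values.shape[1], dtype=float)
    return m.GroupTimeCourse(values, times, np.arange(values.shape[0]) + 1, chance=chance)


@pytest.fixture
def toy_rdm_series():
    """Deterministic 16-condition random RDM series, 5 time points."""
    rng = np.random.default_rng(3)
    n = 16
    acc = np.empty((5, n, n))
    for t in range(5):
        a = rng.uniform(40, 80, (n, n))
        a = (a + a.T) / 2
        acc[t] = a
    i = np.arange(n)
    acc[:, i, i] = np.nan
    return m.RDMSeries(acc, np.arange(5, dtype=float) * 10, np.arange(1, n + 1), subject_id=1)
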