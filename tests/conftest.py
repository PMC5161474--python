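import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mimeg.preprocessing import EpochSet
from mimeg.simulate import SimConfig, generate_session


def make_epochs(data, sfreq=250.0, t0=-5.0, labels=None, **kw):
    data = np.asarray(data, float)
    if labels is None:
        labels = ["LEFT" if i % 2 == 0 else "RIGHT"
                  for i in range(data.shape[0])]
    return EpochSet(data=data, sfreq=sfreq, t0=t0,
                    labels=np.asarray(labels, dtype=object), **kw)


@pytest.fixture(scope="session")
def small_config():
    """Fast 40-trial, 16-channel session configuration."""
    return SimConfig(n_channels=16, n_trials_per_class=20)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config, seed=11)


@pytest.fixture(scope="session")
def default_session():
    """One full-size session under the default study conditions."""
    return generate_session(SimConfig(), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def sine_epochs(freqs, sfreq=250.0, t0=-1.0, dur=6.0, n_trials=4,
                amps=None, phase=0.0):
    """Trials x channels of pure sinusoids, one frequency per channel."""
    n = int(dur * sfreq)
    t = t0 + np.arange(n) / sfreq
    amps = amps or [1.0] * len(freqs)
    chans = np.stack([a * np.sin(2 * np.pi * f * t + phase)
                      for f, a in zip(freqs, amps)])
    data = np.tile(chans, (n_trials, 1, 1))
    return make_epochs(data, sfreq=sfreq, t0=t0)
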