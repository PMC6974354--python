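import numpy as np
import pytest

from cacoupling import SynthConfig, Trace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_config():
    """Small, near-noiseless session for recovery tests."""
    return SynthConfig(duration=300.0, fs=5.0, soma_event_rate=4.0,
                       tuft_initiated_rate=0.0, noise_sd=0.001, seed=7)


def make_dff(values, fs=5.0, **kw):
    kw.setdefault("kind", "dff")
    return Trace(values=np.asarray(values, dtype=float), fs=fs, **kw)


def make_raw(values, fs=5.0, **kw):
    kw.setdefault("kind", "raw")
    return Trace(values=np.asarray(values, dtype=float), fs=fs, **kw)


@pytest.fixture
def trace_factory():
    return make_dff


@pytest.fixture
def raw_factory():
    return make_raw
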