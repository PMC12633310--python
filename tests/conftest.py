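import numpy as np
import pytest

from fretpharm.synthetic import (
    AcquisitionConfig,
    PhotophysicsTruth,
    TwoStateTruth,
    simulate_trace_set,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_photo():
    """Noise-free, bleach-free, leakage-free photophysics."""
    return PhotophysicsTruth(snr=1e12, leakage=0.0, gamma_sigma=0.0,
                             donor_bleach_rate=0.0, acceptor_bleach_rate=0.0)


@pytest.fixture
def small_acq():
    return AcquisitionConfig(n_donor_frames=100, n_red_frames=5,
                             image_shape=(64, 64), seed=7)


def make_ideal_trace(E_path, gamma=1.0, I0=1000.0, leakage=0.0,
                     acceptor_bleach=None, donor_bleach=None):
    """Hand-built noiseless donor/acceptor channels for a known E path."""
    E_path = np.asarray(E_path, dtype=float)
    n = len(E_path)
    f_a = n if acceptor_bleach is None else acceptor_bleach
    f_d = n if donor_bleach is None else donor_bleach
    frames = np.arange(n)
    E_eff = np.where(frames < f_a, E_path, 0.0)
    Id = np.where(frames < f_d, I0 * (1 - E_eff), 0.0)
    Ia = np.where((frames < f_d) & (frames < f_a), I0 * E_eff * gamma, 0.0)
    return Id, Ia + leakage * Id
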