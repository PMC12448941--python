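import numpy as np
import pytest

from tractgain import ChannelInfo, RecordingSession


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_session(samples, fs=1000.0, regions=("GPi",), subject="S01", hemi="L"):
    """Session with one lead per region, contacts numbered 0..k-1 per lead."""
    samples = np.asarray(samples, dtype=float)
    n_per_lead = samples.shape[0] // len(regions)
    channels = []
    for li, region in enumerate(regions):
        for c in range(n_per_lead):
            channels.append(ChannelInfo(subject=subject, hemisphere=hemi,
                                        lead=f"L{li}", region=region, contact=c))
    return RecordingSession(samples=samples, fs=fs, channels=channels)


@pytest.fixture
def sine_session():
    """Three-contact single-lead session carrying distinct sinusoids."""
    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    a = np.sin(2 * np.pi * 7 * t)
    b = 0.5 * np.sin(2 * np.pi * 13 * t)
    c = 0.25 * np.sin(2 * np.pi * 29 * t)
    return make_session(np.vstack([a, b, c]), fs=fs)
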