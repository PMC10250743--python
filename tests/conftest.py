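import numpy as np
import pytest

from texeeg import DeviceProfile, Recording, SubjectProfile
from texeeg.synthetic import default_device_profiles


@pytest.fixture(scope="session")
def subject():
    return SubjectProfile()


@pytest.fixture(scope="session")
def devices():
    return default_device_profiles()


@pytest.fixture()
def sine_recording():
    """60 s of a pure 10 Hz, 20 uV sinusoid in weak white noise."""
    fs = 256.0
    t = np.arange(int(60 * fs)) / fs
    rng = np.random.default_rng(0)
    x = 20 * np.sin(2 * np.pi * 10 * t) + 0.1 * rng.standard_normal((4, len(t)))
    return Recording(data=x, fs=fs)


def make_recording(data, fs=256.0, **kw):
    return Recording(data=np.atleast_2d(data), fs=fs,
                     channel_names=kw.pop("channel_names",
                                          ("F7", "Fp1", "Fp2", "F8")[:np.atleast_2d(data).shape[0]]),
                     **kw)
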