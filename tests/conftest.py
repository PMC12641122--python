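import numpy as np
import pytest
from scipy.signal import lfilter

from lfpei.signal import ChannelMeta, Recording


def pink_noise(n: int, rng: np.random.Generator, scale: float = 20.0) -> np.ndarray:
    """Stationary ~1/f noise (Voss-style IIR approximation)."""
    b = [0.049922035, -0.095993537, 0.050612699, -0.004408786]
    a = [1.0, -2.494956002, 2.017265875, -0.522189400]
    return scale * lfilter(b, a, rng.standard_normal(n))


FIVE_CHANNELS = (
    ChannelMeta("PFC1", "PFC", None, "left"),
    ChannelMeta("PTC_L", "PTC", None, "left"),
    ChannelMeta("PTC_R", "PTC", None, "right"),
    ChannelMeta("HC_L", "HC", "pyramidal", "left"),
    ChannelMeta("HC_R", "HC", "pyramidal", "right"),
)


def make_pink_recording(seed: int, fs: float = 1000.0, duration_s: float = 600.0,
                        channels=FIVE_CHANNELS) -> Recording:
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    data = np.vstack([pink_noise(n, rng) for _ in channels])
    return Recording(data, fs, list(channels))


@pytest.fixture(scope="session")
def pink_recording():
    """600-s five-channel stationary pink-noise recording (event substrate)."""
    return make_pink_recording(seed=1)
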