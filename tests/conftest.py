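import numpy as np
import pytest

from memdkit import MultichannelRecording, SurrogateSpec, gen_surrogate, segment_motion


@pytest.fixture(scope="session")
def fs() -> float:
    return 1000.0


@pytest.fixture(scope="session")
def two_tone(fs):
    """Well-separated two-tone signal: 200 Hz + 25 Hz over 2 s."""
    t = np.arange(int(2 * fs)) / fs
    return {
        "high": np.sin(2 * np.pi * 200 * t),
        "low": np.sin(2 * np.pi * 25 * t),
        "t": t,
    }


@pytest.fixture(scope="session")
def shared_tone_recording(fs) -> MultichannelRecording:
    """4 channels sharing a 100 Hz tone plus weak independent noise."""
    rng = np.random.default_rng(42)
    t = np.arange(int(2 * fs)) / fs
    tone = np.sin(2 * np.pi * 100 * t)
    X = np.outer(tone, np.ones(4)) + 0.1 * rng.normal(size=(t.size, 4))
    return MultichannelRecording(samples=X, sampling_rate=fs)


@pytest.fixture(scope="session")
def surrogate_segment() -> MultichannelRecording:
    """The active 2 s window of one default EMG surrogate."""
    rec = gen_surrogate(SurrogateSpec(seed=0))
    return segment_motion(rec)[0]
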