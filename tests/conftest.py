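import numpy as np
import pytest

import pupcalls as pc
from pupcalls.pipeline import analyze_audio

FS = 250_000


@pytest.fixture(scope="session")
def wt8():
    return pc.preset("WT", 8)


@pytest.fixture(scope="session")
def ko8():
    return pc.preset("KO", 8)


@pytest.fixture(scope="session")
def short_recording(wt8):
    """One 20 s wild-type recording rendered to audio, with ground truth."""
    meta = pc.RecordingMeta("short", "WT", 8, duration=20.0)
    wave, truth = pc.synth_recording(wt8, meta, seed=2)
    return meta, wave, truth


@pytest.fixture(scope="session")
def short_analysis(short_recording):
    meta, wave, truth = short_recording
    return analyze_audio(wave, FS, meta)


def render_tone(
    freq_hz: float = 70_000.0,
    duration_s: float = 0.05,
    total_s: float = 0.3,
    onset_s: float = 0.1,
    amplitude: float = 0.25,
    snr_db: float = 20.0,
    fs: int = FS,
    seed: int = 0,
    ramp_s: float = 0.002,
):
    """A single FM-free tone burst on Gaussian noise, with known boundaries."""
    rng = np.random.default_rng(seed)
    sigma = (amplitude / np.sqrt(2.0)) * 10 ** (-snr_db / 20.0)
    x = rng.standard_normal(int(total_s * fs)).astype(np.float64) * sigma
    n = int(duration_s * fs)
    i0 = int(onset_s * fs)
    tt = np.arange(n) / fs
    env = np.ones(n)
    nr = int(ramp_s * fs)
    if nr:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = r
        env[-nr:] = r[::-1]
    x[i0 : i0 + n] += amplitude * env * np.sin(2 * np.pi * freq_hz * tt)
    return x
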