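"""File formats: WAV audio, CSV tables, YAML configuration.

Interchange conventions: time coordinates are seconds from recording start,
intervals half-open [onset, offset); call and frame indices are 0-based; CSVs
carry a header row; scalar results are JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .params import SAMPLE_RATE

CALLS_COLUMNS = ["recording_id", "call_index", "onset_s", "offset_s", "duration_s"]


def read_audio(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a mono PCM WAV file; returns (int16 samples, sampling rate Hz).

    Rates other than 250 kHz are accepted with a warning (the analysis band is
    clipped to Nyquist downstream).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", wavfile.WavFileWarning)
        fs, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if fs != SAMPLE_RATE:
        warnings.warn(
            f"{path}: sampling rate {fs} Hz differs from the nominal {SAMPLE_RATE} Hz; "
            "band edges will be clipped to Nyquist",
            stacklevel=2,
        )
    return data, int(fs)


def write_audio(path: str | Path, samples: np.ndarray, fs: int = SAMPLE_RATE) -> None:
    if samples.dtype != np.int16:
        raise ValueError("samples must be int16 PCM")
    wavfile.write(str(path), fs, samples)


def calls_to_frame(recording_id: str, intervals: np.ndarray) -> pd.DataFrame:
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    return pd.DataFrame(
        {
            "recording_id": recording_id,
            "call_index": np.arange(iv.shape[0]),
            "onset_s": iv[:, 0],
            "offset_s": iv[:, 1],
            "duration_s": iv[:, 1] - iv[:, 0],
        }
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def load_config_file(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
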