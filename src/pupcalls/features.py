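"""Per-call pitch tracking, pitch-jump detection and call power spectra.

Pitch is the dominant (argmax-power) frequency of each sonogram frame within
a call; frames whose spectral purity falls below a dropout threshold carry no
pitch.  A pitch jump is an abrupt change of the dominant frequency between
neighbouring tracked frames exceeding a threshold; jumps are evaluated on the
standard grid 500, 1000, 3000, 5000, 10000, 15000 and 20000 Hz, split by
sign, and the largest |change| per call is kept as its max jump.  Brief
dropouts (<= 10 ms by default) are bridged so a jump straddling a short energy
dip still counts; jumps are never measured across call boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detection import CallSegment, FrameFeatures, Sonogram, frame_features
from .params import JUMP_THRESHOLDS

DEFAULT_BRIDGE = 0.010
# Dropout when tonality is truly lost: background-noise purity sits near
# 1/N_bins (~0.02 at 257 bins) while even fast FM chirps that smear power over
# several bins stay above ~0.15; 0.10 separates the two regimes.
DEFAULT_DROPOUT_PURITY = 0.10


@dataclass(frozen=True)
class PitchTrack:
    """Dominant-frequency contour of one call; dropouts are NaN."""

    times: np.ndarray
    freqs: np.ndarray  # Hz, NaN at dropouts
    call_index: int = -1

    @property
    def n_tracked(self) -> int:
        return int(np.isfinite(self.freqs).sum())


@dataclass(frozen=True)
class PitchJump:
    time: float
    magnitude: float  # signed, Hz; positive = upward

    @property
    def sign(self) -> int:
        return 1 if self.magnitude > 0 else -1


def pitch_track(
    son: Sonogram,
    call: CallSegment,
    features: FrameFeatures | None = None,
    dropout_purity: float = DEFAULT_DROPOUT_PURITY,
    call_index: int = -1,
) -> PitchTrack:
    """Extract the dominant-frequency track of a detected call."""
    if features is None:
        features = frame_features(son)
    i0, i1 = call.first_frame, call.last_frame + 1
    sub = son.power[i0:i1]
    freqs = son.freqs[np.argmax(sub, axis=1)].astype(float)
    freqs[features.purity[i0:i1] < dropout_purity] = np.nan
    return PitchTrack(times=son.times[i0:i1].copy(), freqs=freqs, call_index=call_index)


def track_from_annotation(call, call_index: int = -1) -> PitchTrack:
    """Build a PitchTrack directly from a synthetic call annotation."""
    return PitchTrack(
        times=np.asarray(call.pitch_times, dtype=float),
        freqs=np.asarray(call.pitch_hz, dtype=float),
        call_index=call_index,
    )


def _adjacent_steps(track: PitchTrack, bridge: float):
    """(times, signed df) over neighbouring tracked frames, bridging short dropouts."""
    ok = np.isfinite(track.freqs)
    t = track.times[ok]
    f = track.freqs[ok]
    if f.size < 2:
        return np.empty(0), np.empty(0)
    dt = np.diff(t)
    df = np.diff(f)
    keep = dt <= bridge + 1e-9
    return t[1:][keep], df[keep]


def detect_jumps(
    track: PitchTrack, threshold: float, bridge: float = DEFAULT_BRIDGE
) -> list[PitchJump]:
    """Pitch jumps exceeding ``threshold`` Hz within one call."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    times, steps = _adjacent_steps(track, bridge)
    return [
        PitchJump(time=float(t), magnitude=float(d))
        for t, d in zip(times, steps)
        if abs(d) > threshold
    ]


def max_jump(track: PitchTrack, bridge: float = DEFAULT_BRIDGE) -> float:
    """Largest |pitch change| between neighbouring tracked frames (Hz).

    Returns NaN when fewer than two tracked frames are available (the call is
    then excluded from jump statistics).
    """
    _, steps = _adjacent_steps(track, bridge)
    if steps.size == 0:
        return float("nan")
    return float(np.max(np.abs(steps)))


def jump_count_row(
    track: PitchTrack,
    thresholds: Sequence[float] = JUMP_THRESHOLDS,
    bridge: float = DEFAULT_BRIDGE,
) -> dict[str, float]:
    """Per-call feature row: signed jump counts per threshold plus max jump."""
    _, steps = _adjacent_steps(track, bridge)
    row: dict[str, float] = {}
    for th in thresholds:
        row[f"jump_pos_{int(th)}"] = int(np.sum(steps > th))
        row[f"jump_neg_{int(th)}"] = int(np.sum(steps < -th))
    row["max_jump_hz"] = float(np.max(np.abs(steps))) if steps.size else float("nan")
    return row


def call_feature_table(
    tracks: Iterable[PitchTrack],
    durations: Sequence[float],
    thresholds: Sequence[float] = JUMP_THRESHOLDS,
    bridge: float = DEFAULT_BRIDGE,
) -> pd.DataFrame:
    """One row per call: duration plus the jump features of :func:`jump_count_row`."""
    rows = []
    for i, (track, dur) in enumerate(zip(tracks, durations)):
        row = {"call_index": i, "duration_s": float(dur)}
        row.update(jump_count_row(track, thresholds, bridge))
        rows.append(row)
    return pd.DataFrame(rows)


def call_power_spectrum(
    son: Sonogram, calls: Sequence[CallSegment]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Subject-level power spectrum over all call frames.

    All frames belonging to calls are pooled; the mean per-frequency power
    vector over those frames is the subject's spectrum.  Returns
    ``(freqs, spectrum, total_power)`` where total power is the spectrum sum.
    """
    if not calls:
        raise ValueError("no calls: subject excluded from spectral analysis")
    mask = np.zeros(son.power.shape[0], dtype=bool)
    for c in calls:
        mask[c.first_frame : c.last_frame + 1] = True
    spectrum = son.power[mask].mean(axis=0).astype(float)
    return son.freqs.copy(), spectrum, float(spectrum.sum())
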