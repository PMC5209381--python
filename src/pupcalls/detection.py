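"""Sonogram computation and call/click detection.

Calls are identified from a short-time power spectrogram (512 samples per
block, half overlap; at 250 kHz this gives the conventional 1.02 ms time
resolution and 0.98 kHz reported frequency resolution) using three per-frame
statistics:

* **spectral purity** — fraction of a frame's total power concentrated in its
  single strongest frequency bin (near 1 for tonal calls, ~1/N for noise);
* **mean frequency** — power-weighted mean frequency, required to sit inside
  the 25–110 kHz band;
* **spectral discontinuity** — 1 minus the cosine similarity between the
  normalized power allocations of adjacent frames, used to split runs that
  straddle distinct events.

Clicks (broadband millisecond transients) are flagged when fewer than 200 of
512 spectrogram cells — proportionally rescaled to the actual number of
frequency cells — fall below a noise-floor threshold; click frames are
excluded from call segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .params import BAND_HIGH, BAND_LOW


@dataclass(frozen=True)
class Sonogram:
    """Time x frequency power matrix with its axes and analysis parameters."""

    power: np.ndarray  # (n_times, n_freqs), non-negative
    times: np.ndarray  # frame centers, seconds
    freqs: np.ndarray  # bin centers, Hz
    fs: float
    block: int

    @property
    def time_step(self) -> float:
        """Hop between frame centers: block/2 samples."""
        return (self.block // 2) / self.fs

    @property
    def reported_time_resolution_ms(self) -> float:
        """Time resolution in ms, rounded to 3 significant figures."""
        return float(f"{self.time_step * 1e3:.3g}")

    @property
    def reported_freq_resolution_khz(self) -> float:
        """Frequency resolution under the fs/(block/2) reporting convention, kHz."""
        return round(self.fs / (self.block // 2) / 1e3, 2)


@dataclass(frozen=True)
class FrameFeatures:
    purity: np.ndarray        # in [0, 1], per frame
    mean_freq: np.ndarray     # Hz per frame (nan for silent frames)
    discontinuity: np.ndarray  # per adjacent frame pair, length n_times - 1


@dataclass(frozen=True)
class CallSegment:
    """A detected vocalization interval; frame indices are inclusive."""

    onset: float
    offset: float
    first_frame: int
    last_frame: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class ClickEvent:
    time: float
    occupied_bins: int
    first_frame: int
    last_frame: int


def bandpass(
    waveform: np.ndarray,
    fs: float,
    low: float = BAND_LOW,
    high: float = BAND_HIGH,
    numtaps: int = 401,
) -> np.ndarray:
    """Zero-phase band-pass filter.

    A linear-phase FIR (Hamming-windowed sinc) is applied by overlap-add
    convolution and its constant group delay removed exactly, so call onsets
    are unshifted.  Stopband attenuation exceeds 50 dB a short transition
    width beyond the band edges.
    """
    if fs <= 2 * high:
        raise ValueError(f"sampling rate {fs} Hz cannot represent a {high} Hz band edge")
    if numtaps % 2 == 0:
        raise ValueError("numtaps must be odd (symmetric FIR, integer group delay)")
    taps = sps.firwin(numtaps, [low, high], pass_zero=False, fs=fs).astype(np.float32)
    # float32 throughout: ample precision for 16-bit audio, much faster FFTs
    x = np.asarray(waveform, dtype=np.float32)
    delay = (numtaps - 1) // 2
    # explicit overlap-add with bounded chunk size keeps memory flat on long
    # recordings (a 3.5 min file is 52.5 M samples)
    chunk = 1 << 21
    y = np.zeros(x.size + numtaps - 1, dtype=np.float32)
    for start in range(0, x.size, chunk):
        seg = sps.fftconvolve(x[start : start + chunk], taps, mode="full")
        y[start : start + seg.size] += seg
    return y[delay : delay + x.size]


def compute_sonogram(waveform: np.ndarray, fs: float, block: int = 512) -> Sonogram:
    """Hann-windowed power spectrogram with half-overlapping blocks."""
    x = np.asarray(waveform, dtype=np.float32)
    if x.size < block:
        raise ValueError(f"waveform ({x.size} samples) shorter than one block ({block})")
    hop = block // 2
    n_frames = (x.size - block) // hop + 1
    n_bins = block // 2 + 1
    power = np.empty((n_frames, n_bins), dtype=np.float32)
    freqs = None
    # frame-aligned chunks keep peak memory flat on 52.5 M-sample recordings
    frames_per_chunk = 1 << 14
    for f0 in range(0, n_frames, frames_per_chunk):
        f1 = min(f0 + frames_per_chunk, n_frames)
        seg = x[f0 * hop : (f1 - 1) * hop + block]
        freqs, _, p = sps.spectrogram(
            seg,
            fs=fs,
            window="hann",
            nperseg=block,
            noverlap=hop,
            detrend=False,
            scaling="spectrum",
            mode="psd",
        )
        power[f0:f1] = p.T
    times = (hop + np.arange(n_frames) * hop) / fs
    return Sonogram(
        power=power,
        times=times,
        freqs=freqs,
        fs=float(fs),
        block=block,
    )


def frame_features(son: Sonogram) -> FrameFeatures:
    """Per-frame purity / mean frequency and adjacent-frame discontinuity."""
    p = son.power
    totals = p.sum(axis=1, dtype=np.float64)
    nonzero = totals > 0
    safe_tot = np.where(nonzero, totals, 1.0)
    purity = np.where(nonzero, p.max(axis=1) / safe_tot, 0.0)
    mean_freq = np.where(nonzero, (p @ son.freqs.astype(p.dtype)) / safe_tot, np.nan)
    # discontinuity: 1 - cosine similarity of adjacent power allocations
    norms = np.sqrt(np.einsum("ij,ij->i", p, p, dtype=np.float64))
    safe = np.where(norms > 0, norms, 1.0).astype(p.dtype)
    unit = p / safe[:, None]
    cos = np.einsum("ij,ij->i", unit[:-1], unit[1:], dtype=np.float64)
    disc = 1.0 - np.clip(cos, -1.0, 1.0)
    disc[(norms[:-1] == 0) | (norms[1:] == 0)] = 1.0
    return FrameFeatures(purity=purity, mean_freq=mean_freq, discontinuity=disc)


def detect_clicks(
    son: Sonogram,
    empty_factor: float = 2.0,
    max_empty: int = 200,
    reference_cells: int = 512,
    merge_frames: int = 2,
) -> list[ClickEvent]:
    """Flag broadband frames as clicks and group consecutive ones into events.

    A frequency cell is *empty* when its power is below ``empty_factor`` times
    the median cell power of the recording; a frame is a click frame when its
    empty-cell count is below ``max_empty`` rescaled from the 512-cell
    convention to the actual number of cells.
    """
    p = son.power
    threshold = float(np.median(p)) * empty_factor
    n_f = p.shape[1]
    limit = max_empty * n_f / reference_cells
    n_empty = (p < threshold).sum(axis=1)
    is_click = n_empty < limit
    events: list[ClickEvent] = []
    runs: list[list[int]] = []
    for start, stop in _runs(is_click):
        # a single millisecond transient can straddle frame boundaries; merge
        # click frames separated by no more than merge_frames quiet frames
        if runs and start - runs[-1][1] - 1 <= merge_frames:
            runs[-1][1] = stop
        else:
            runs.append([start, stop])
    for start, stop in runs:
        occ = int(n_f - n_empty[start : stop + 1].min())
        mid = (start + stop) // 2
        events.append(
            ClickEvent(
                time=float(son.times[mid]), occupied_bins=occ, first_frame=start, last_frame=stop
            )
        )
    return events


def _runs(mask: np.ndarray):
    """Yield (start, stop) inclusive index pairs of True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    yield from zip(starts.tolist(), stops.tolist())


def detect_calls(
    son: Sonogram,
    features: FrameFeatures | None = None,
    purity_threshold: float = 0.25,
    min_duration: float = 0.005,
    merge_gap: float = 0.010,
    band: tuple[float, float] = (BAND_LOW, BAND_HIGH),
    exclude_clicks: bool = True,
    clicks: list[ClickEvent] | None = None,
    discontinuity_threshold: float | None = None,
) -> list[CallSegment]:
    """Segment voiced frames into disjoint, sorted call intervals.

    A frame is voiced when its purity reaches ``purity_threshold`` and its
    mean frequency lies inside ``band``.  Voiced runs separated by gaps of at
    most ``merge_gap`` are merged; runs shorter than ``min_duration`` are
    dropped.  Click frames are never voiced.  If ``discontinuity_threshold``
    is given, a merged run is split where the spectral discontinuity exceeds
    it *and* the frame purity falls below the voicing threshold (secondary
    criterion; off by default).
    """
    if purity_threshold <= 0 or min_duration <= 0:
        raise ValueError("thresholds must be positive")
    if features is None:
        features = frame_features(son)
    voiced = (
        (features.purity >= purity_threshold)
        & (features.mean_freq >= band[0])
        & (features.mean_freq <= band[1])
    )
    if exclude_clicks:
        for ev in detect_clicks(son) if clicks is None else clicks:
            voiced[ev.first_frame : ev.last_frame + 1] = False

    dt = son.time_step
    gap_frames = int(round(merge_gap / dt))
    runs = list(_runs(voiced))
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] - 1 <= gap_frames:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    if discontinuity_threshold is not None:
        split: list[list[int]] = []
        for start, stop in merged:
            cur = start
            for i in range(start, stop):
                if (
                    features.discontinuity[i] > discontinuity_threshold
                    and features.purity[i + 1] < purity_threshold
                ):
                    split.append([cur, i])
                    cur = i + 1
            split.append([cur, stop])
        merged = split

    half = dt / 2
    out = []
    for start, stop in merged:
        onset = float(son.times[start] - half)
        offset = float(son.times[stop] + half)
        if offset - onset >= min_duration:
            out.append(CallSegment(onset=onset, offset=offset, first_frame=start, last_frame=stop))
    return out


def filter_clicks_outside_calls(
    clicks: list[ClickEvent], calls: list[CallSegment]
) -> list[ClickEvent]:
    """Drop click candidates that fall inside detected call segments.

    Abrupt within-call pitch jumps place a broadband transition frame in the
    middle of a half-overlapped window; such frames satisfy the occupancy rule
    but are part of a tonal call, not a click.  Calls and clicks are treated
    as mutually exclusive event classes.
    """
    out = []
    for c in clicks:
        inside = any(
            seg.first_frame <= c.last_frame and c.first_frame <= seg.last_frame
            for seg in calls
        )
        if not inside:
            out.append(c)
    return out


def include_recording(calls: list[CallSegment] | int, min_calls: int = 10) -> bool:
    """Inclusion rule: a recording enters the analysis only with >= 10 calls."""
    n = calls if isinstance(calls, int) else len(calls)
    return n >= min_calls
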