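"""Synthetic pup isolation-call recordings with exact ground truth.

The generator is a two-level hierarchy.  For each animal, per-animal means
(call duration, pause durations, calls per bout, isolated-call probability,
max-jump size, weight) are drawn around the group-level values in
:class:`~pupcalls.params.GenotypeParams`.  Within a recording, vocal output is
an alternation of bouts (runs of calls separated by short intra-bout pauses)
and long inter-bout pauses; each call carries a frequency contour built from a
syllable-shape recipe, optionally with abrupt pitch jumps.  Everything emitted
is recorded in a :class:`SynthGroundTruth` so detectors and downstream
statistics can be validated against a known answer.

Timing and contour shaping use independent random streams derived from one
seed, so the annotation-only path produces identical call intervals whether or
not contours are rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (
    BAND_HIGH,
    BAND_LOW,
    COHORT_SIZES,
    MAX_JUMP_HZ,
    MAX_RAMP_STEP_HZ,
    MIN_JUMP_HZ,
    N_JUMPS_GIVEN_JUMPY,
    SAMPLE_RATE,
    GenotypeParams,
    RecordingMeta,
    calibrate_jump_size_mean,
    preset,
)

#: Contour sample step: one sonogram frame (half a 512-sample block) at 250 kHz.
FRAME_DT = 256 / SAMPLE_RATE

_MIN_CALL = 0.015
_MAX_CALL = 0.150
_MIN_INTRA = 0.020
_MAX_INTRA = 0.230
_MIN_INTER = 0.350
_EDGE_PAD = 0.25  # silence kept at both ends of the recording
_CLICK_DURATION = 0.002
_ONSET_RAMP = 0.002  # raised-cosine on/off ramp


@dataclass(frozen=True)
class CallAnnotation:
    """One synthesized call: interval, shape label, contour and planted jumps."""

    onset: float
    offset: float
    label: str
    bout: int
    pitch_times: np.ndarray  # absolute seconds, one per contour frame
    pitch_hz: np.ndarray
    jumps: tuple[tuple[float, float], ...]  # (time s, signed magnitude Hz)
    amplitude_scale: float = 1.0

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class SynthGroundTruth:
    """Complete event record of one synthetic recording."""

    calls: list[CallAnnotation]
    click_times: list[float]
    animal: "AnimalParams"

    @property
    def n_calls(self) -> int:
        return len(self.calls)

    @property
    def call_intervals(self) -> np.ndarray:
        return np.array([(c.onset, c.offset) for c in self.calls]).reshape(-1, 2)

    @property
    def bout_memberships(self) -> np.ndarray:
        return np.array([c.bout for c in self.calls], dtype=int)

    @property
    def syllable_labels(self) -> list[str]:
        return [c.label for c in self.calls]

    @property
    def jump_events(self) -> list[tuple[int, float, float]]:
        """(call index, time s, signed magnitude Hz) for every planted jump."""
        return [(i, t, m) for i, c in enumerate(self.calls) for t, m in c.jumps]


@dataclass(frozen=True)
class AnimalParams:
    """Concrete per-animal means realized from a group-level parameter set."""

    call_duration_mean: float
    call_duration_sd: float
    intra_pause_mean: float
    intra_pause_sd: float
    inter_pause_mean: float
    bout_size_lambda: float  # bout size = 2 + Poisson(lambda) for non-isolated bouts
    isolated_prob: float
    jump_prob: float
    jump_size_mean: float
    jump_size_sd: float
    weight: float


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Vectorized rejection sampler; bounds are strict truncation, not clipping."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,)).copy()
    out = rng.normal(mean, sd)
    bad = (out < lo) | (out > hi)
    for _ in range(200):
        if not bad.any():
            return out
        out[bad] = rng.normal(mean[bad], sd)
        bad = (out < lo) | (out > hi)
    out[bad] = np.clip(out[bad], lo, hi)
    return out


def draw_animal(params: GenotypeParams, rng: np.random.Generator) -> AnimalParams:
    """Draw one animal's means around the group-level values."""
    z_w = rng.standard_normal()
    weight = params.weight_mean + params.weight_sd_between * z_w
    rho = params.pause_weight_corr
    z_pause = rho * (-z_w) + np.sqrt(max(1.0 - rho * rho, 0.0)) * rng.standard_normal()

    dur = float(
        _truncated_normal(
            rng, params.mean_call_duration, params.duration_sd_between, 0.020, 0.120, 1
        )[0]
    )
    intra = float(
        np.clip(
            params.intra_bout_pause_mean + params.intra_sd_between * z_pause, 0.045, 0.205
        )
    )
    inter = float(
        max(
            rng.normal(params.inter_bout_pause_mean, params.inter_sd_between),
            _MIN_INTER + 0.15,
        )
    )
    cpb = float(max(rng.normal(params.calls_per_bout_mean, params.calls_per_bout_sd_between), 1.05))
    iso = float(np.clip(rng.normal(params.isolated_call_prob, params.isolated_sd_between), 0.003, 0.6))
    # isolated_call_prob is the fraction of *calls* that are isolated; the
    # per-bout singleton probability is therefore q = iso * mean bout size.
    # Non-isolated bouts are 2 + Poisson(lam), with lam solved for the target
    # mean bout size.
    q = float(np.clip(iso * cpb, 0.002, 1.0))
    lam = max((cpb - q) / (1.0 - q) - 2.0, 0.01) if q < 1.0 else 0.0
    max_jump_target = float(
        max(rng.normal(params.max_jump_mean, params.max_jump_sd_between), 1_500.0)
    )
    mu_jump = calibrate_jump_size_mean(max_jump_target, params.jump_prob_per_call)

    return AnimalParams(
        call_duration_mean=dur,
        call_duration_sd=params.call_duration_sd,
        intra_pause_mean=intra,
        intra_pause_sd=params.intra_bout_pause_sd,
        inter_pause_mean=inter,
        bout_size_lambda=lam,
        isolated_prob=q,
        jump_prob=params.jump_prob_per_call,
        jump_size_mean=mu_jump,
        jump_size_sd=params.jump_size_sd,
        weight=float(weight),
    )


# ---------------------------------------------------------------------------
# contour recipes


def _dip_curve(rng, n):
    """U-shaped (down-then-up) contour; frame steps stay below the smallest
    jump threshold so this shape never contributes spurious jump counts."""
    half = max((n - 1) // 2, 1)
    rest = max(n - 1 - half, 1)
    cap = MAX_RAMP_STEP_HZ * min(half, rest)
    depth = rng.uniform(min(2_900.0, 0.95 * cap), max(min(6_000.0, cap), 2_950.0))
    steps = np.concatenate([np.full(half, -depth / half), np.full(rest, depth / rest)])
    return np.concatenate([[0.0], np.cumsum(steps)])[:n]


def _contour_for_label(rng, label: str, n: int, f_lo: float, f_hi: float,
                       jump_sizes: np.ndarray) -> tuple[np.ndarray, list[tuple[int, float]]]:
    """Frequency contour (Hz, length n) and planted jumps [(frame idx, signed Hz)]."""
    jumps: list[tuple[int, float]] = []
    if label in ("one-jump-up", "one-jump-down", "multi-jump"):
        signs = []
        if label == "one-jump-up":
            signs = [1.0]
        elif label == "one-jump-down":
            signs = [-1.0]
        else:
            s0 = 1.0 if rng.random() < 0.5 else -1.0
            signs = [s0 * (-1.0) ** k for k in range(len(jump_sizes))]
        sizes = jump_sizes * np.array(signs)
        # jump frame positions: inside the call, >= 3 frames apart, away from edges
        k = len(sizes)
        lo_i = max(2, int(0.2 * n))
        hi_i = min(max(max(3, int(0.8 * n)), lo_i + 3 * k), n - 2)
        candidates = np.arange(lo_i, max(hi_i, lo_i + k))
        positions = np.sort(rng.choice(candidates, size=k, replace=False))
        for _ in range(50):
            if not np.any(np.diff(positions) < 3):
                break
            positions = np.sort(rng.choice(candidates, size=k, replace=False))
        # base: gentle slope segments between jumps
        slope = rng.uniform(-180.0, 180.0)
        base = np.cumsum(np.full(n, slope))
        contour = base.copy()
        for pos, sz in zip(positions, sizes):
            contour[pos:] += sz
            jumps.append((int(pos), float(sz)))
        # anchor inside band, honouring total excursion
        span_lo, span_hi = contour.min(), contour.max()
        f0_lo = f_lo - span_lo
        f0_hi = f_hi - span_hi
        if f0_hi <= f0_lo:  # excursion larger than range: centre it
            f0 = (f_lo + f_hi) / 2 - (span_lo + span_hi) / 2
        else:
            f0 = rng.uniform(f0_lo, f0_hi)
        return contour + f0, jumps

    if label == "flat":
        f0 = rng.uniform(f_lo, f_hi)
        return f0 + rng.normal(0.0, 50.0, size=n), jumps
    if label in ("up-fm", "down-fm"):
        cap = MAX_RAMP_STEP_HZ * (n - 1)
        rise = rng.uniform(min(5_000.0, 0.8 * cap), min(12_000.0, cap))
        ramp = np.linspace(0.0, rise, n)
        if label == "down-fm":
            ramp = -ramp
        lo0 = f_lo - min(ramp.min(), 0.0)
        hi0 = f_hi - max(ramp.max(), 0.0)
        f0 = rng.uniform(lo0, max(hi0, lo0))
        return f0 + ramp, jumps
    if label == "chevron":
        half = n // 2
        cap = MAX_RAMP_STEP_HZ * max(half - 1, 1)
        rise = rng.uniform(min(2_800.0, 0.8 * cap), min(10_000.0, cap))
        up = np.linspace(0.0, rise, half)
        down = np.linspace(rise, 0.0, n - half)
        shape = np.concatenate([up, down])
        f0 = rng.uniform(f_lo, max(f_hi - rise, f_lo))
        return f0 + shape, jumps
    # "other": U-shaped dip (single minimum; outside the chevron/FM classes)
    shape = _dip_curve(rng, n)
    f0 = rng.uniform(f_lo - shape.min(), max(f_hi - shape.max(), f_lo - shape.min()))
    return f0 + shape, jumps


_NJ_KS = np.array([k for k, _ in N_JUMPS_GIVEN_JUMPY])
_NJ_CUM = np.cumsum([p for _, p in N_JUMPS_GIVEN_JUMPY])


def _draw_label(rng, animal: AnimalParams, params: GenotypeParams, prev: str | None) -> str:
    if prev is not None and rng.random() < params.label_persistence:
        return prev
    if rng.random() < animal.jump_prob:
        k = int(_NJ_KS[np.searchsorted(_NJ_CUM, rng.random())])
        if k >= 2:
            return "multi-jump"
        return "one-jump-up" if rng.random() < 0.55 else "one-jump-down"
    labels = [l for l, _ in params.nonjump_type_probs]
    cum = np.cumsum([p for _, p in params.nonjump_type_probs])
    return labels[int(np.searchsorted(cum / cum[-1], rng.random()))]


# ---------------------------------------------------------------------------
# event process


def synth_events(
    params: GenotypeParams,
    meta: RecordingMeta,
    seed: int,
    with_contours: bool = True,
) -> SynthGroundTruth:
    """Generate the full event stream (calls, contours, jumps, clicks) of one recording.

    ``with_contours=False`` skips contour/jump synthesis (tracks empty) but
    leaves call intervals, labels and bout structure bit-identical for the
    same seed — convenient for timing-only studies on large cohorts.
    """
    if meta.duration < 2 * _EDGE_PAD + _MAX_CALL:
        raise ValueError(f"duration {meta.duration} s too short to fit a call")
    ss = np.random.SeedSequence(seed)
    timing_rng, contour_rng, click_rng, animal_rng = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    animal = draw_animal(params, animal_rng)

    calls: list[CallAnnotation] = []
    if params.calls_per_bout_mean > 0:
        t = _EDGE_PAD + timing_rng.uniform(0.0, 1.0)
        t_max = meta.duration - _EDGE_PAD
        bout = 0
        prev_label: str | None = None
        f_lo, f_hi = params.base_freq_range
        done = False
        while not done:
            if timing_rng.random() < animal.isolated_prob:
                size = 1
            else:
                size = 2 + int(timing_rng.poisson(animal.bout_size_lambda))
            durs = _truncated_normal(
                timing_rng,
                animal.call_duration_mean,
                animal.call_duration_sd,
                _MIN_CALL,
                _MAX_CALL,
                size,
            )
            intra_gaps = (
                _truncated_normal(
                    timing_rng,
                    animal.intra_pause_mean,
                    animal.intra_pause_sd,
                    _MIN_INTRA,
                    _MAX_INTRA,
                    size - 1,
                )
                if size > 1
                else np.empty(0)
            )
            for i in range(size):
                dur = float(durs[i])
                if t + dur > t_max:
                    done = True
                    break
                label = _draw_label(timing_rng, animal, params, prev_label)
                prev_label = label
                n_frames = max(int(round(dur / FRAME_DT)), 6)
                if with_contours:
                    if label == "multi-jump":
                        k = 2 if contour_rng.random() < 0.72 else 3
                    else:
                        k = 1
                    sizes = _truncated_normal(
                        contour_rng,
                        animal.jump_size_mean,
                        animal.jump_size_sd,
                        MIN_JUMP_HZ,
                        MAX_JUMP_HZ,
                        k,
                    )
                    contour, frame_jumps = _contour_for_label(
                        contour_rng, label, n_frames, f_lo, f_hi, sizes
                    )
                    contour = np.clip(contour, BAND_LOW + 2_000.0, BAND_HIGH - 3_000.0)
                    times = t + (np.arange(n_frames) + 0.5) * FRAME_DT
                    jumps = tuple(
                        (float(t + (idx + 0.5) * FRAME_DT), mag) for idx, mag in frame_jumps
                    )
                    amp_scale = float(np.exp(contour_rng.normal(0.0, 0.12)))
                else:
                    contour = np.empty(0)
                    times = np.empty(0)
                    jumps = ()
                    amp_scale = 1.0
                calls.append(
                    CallAnnotation(
                        onset=t,
                        offset=t + dur,
                        label=label,
                        bout=bout,
                        pitch_times=times,
                        pitch_hz=contour,
                        jumps=jumps,
                        amplitude_scale=amp_scale,
                    )
                )
                t += dur
                if i < size - 1:
                    t += float(intra_gaps[i])
            bout += 1
            t += _MIN_INTER + timing_rng.exponential(
                max(animal.inter_pause_mean - _MIN_INTER, 0.05)
            )
            if t >= t_max:
                done = True

    # clicks: Poisson process, rejected if within 10 ms of a call
    click_times: list[float] = []
    n_clicks = click_rng.poisson(params.click_rate * meta.duration)
    intervals = np.array([(c.onset, c.offset) for c in calls]).reshape(-1, 2)
    for _ in range(int(n_clicks)):
        for _try in range(100):
            tc = click_rng.uniform(_EDGE_PAD, meta.duration - _EDGE_PAD)
            if intervals.size == 0 or not np.any(
                (tc > intervals[:, 0] - 0.010) & (tc < intervals[:, 1] + 0.010)
            ):
                click_times.append(float(tc))
                break
    click_times.sort()
    return SynthGroundTruth(calls=calls, click_times=click_times, animal=animal)


def synth_annotation_only(
    params: GenotypeParams, meta: RecordingMeta, seed: int
) -> tuple[pd.DataFrame, SynthGroundTruth]:
    """Fast path: event stream without waveform rendering.

    Returns a call table (one row per call: onset_s, offset_s, duration_s,
    label, bout) alongside the full ground truth (which carries the pitch
    contours).
    """
    truth = synth_events(params, meta, seed, with_contours=True)
    table = pd.DataFrame(
        {
            "onset_s": [c.onset for c in truth.calls],
            "offset_s": [c.offset for c in truth.calls],
            "duration_s": [c.duration for c in truth.calls],
            "label": truth.syllable_labels,
            "bout": truth.bout_memberships if truth.calls else np.empty(0, dtype=int),
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# audio rendering


def _render_call(wave: np.ndarray, call: CallAnnotation, params: GenotypeParams, fs: int) -> None:
    i0 = int(round(call.onset * fs))
    n = int(round(call.duration * fs))
    n = min(n, wave.size - i0)
    if n <= 0:
        return
    # per-sample instantaneous frequency: zero-order hold of the frame-rate
    # contour, so planted pitch jumps are instantaneous steps
    tt = (np.arange(n) + 0.5) / fs
    idx = np.minimum((tt / FRAME_DT).astype(np.intp), call.pitch_hz.size - 1)
    f_inst = call.pitch_hz[idx]
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs
    amp = params.amplitude * call.amplitude_scale
    gain = np.where(f_inst > 65_000.0, np.sqrt(params.high_band_power_scale), 1.0)
    env = np.ones(n)
    ramp_n = min(int(_ONSET_RAMP * fs), n // 2)
    if ramp_n > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        env[:ramp_n] = r
        env[-ramp_n:] = r[::-1]
    wave[i0 : i0 + n] += (amp * gain * env * np.sin(phase)).astype(np.float32)


def synth_recording(
    params: GenotypeParams, meta: RecordingMeta, seed: int, fs: int = SAMPLE_RATE
) -> tuple[np.ndarray, SynthGroundTruth]:
    """Render one recording to 16-bit PCM samples at ``fs`` with ground truth.

    The waveform is frequency-modulated tones (one per call) riding on white
    Gaussian background noise whose level realizes ``params.snr_db``, plus
    broadband click transients.
    """
    truth = synth_events(params, meta, seed, with_contours=True)
    n_total = int(round(meta.duration * fs))
    noise_sigma = (params.amplitude / np.sqrt(2.0)) * 10.0 ** (-params.snr_db / 20.0)
    ss = np.random.SeedSequence([seed, 0x5EED])
    noise_rng = np.random.default_rng(ss)
    wave = noise_rng.standard_normal(n_total, dtype=np.float32) * np.float32(noise_sigma)
    for call in truth.calls:
        _render_call(wave, call, params, fs)
    click_n = int(_CLICK_DURATION * fs)
    click_amp = np.float32(params.amplitude * 0.5)
    for tc in truth.click_times:
        i0 = int(round(tc * fs))
        burst = noise_rng.standard_normal(click_n, dtype=np.float32) * click_amp
        env = np.hanning(click_n).astype(np.float32)
        wave[i0 : i0 + click_n] += burst * env
    np.clip(wave, -0.999, 0.999, out=wave)
    pcm = np.round(wave * 32767.0).astype(np.int16)
    return pcm, truth


# ---------------------------------------------------------------------------
# cohorts


def sample_cohort(
    group_sizes: dict[tuple[str, int], int] | None = None,
    seed: int = 0,
    duration: float = 210.0,
    audio: bool = False,
    params_by_group: dict[tuple[str, int], GenotypeParams] | None = None,
    fs: int = SAMPLE_RATE,
):
    """Generate a reproducible cohort of recordings.

    Parameters
    ----------
    group_sizes
        Mapping (genotype, day) -> number of animals. Defaults to the study
        cohort sizes (40/13 WT/KO on P5, 41/15 on P8).
    audio
        If True, render waveforms; otherwise produce annotation tables only.

    Returns
    -------
    records : list of (RecordingMeta, payload, SynthGroundTruth)
        ``payload`` is a PCM waveform when ``audio`` else a call table.
    meta_table : pandas.DataFrame
        One row per recording (animal_id, genotype, day, weight, sex, n_calls).
    """
    if group_sizes is None:
        group_sizes = dict(COHORT_SIZES)
    if any(n < 0 for n in group_sizes.values()):
        raise ValueError("group sizes must be >= 0")
    root = np.random.SeedSequence(seed)
    records = []
    rows = []
    idx = 0
    for (genotype, day), n in sorted(group_sizes.items()):
        p = (params_by_group or {}).get((genotype, day)) or preset(genotype, day)
        for j in range(n):
            child = root.spawn(1)[0]
            rec_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            sex = "M" if (idx % 2 == 0) else "F"
            meta = RecordingMeta(
                animal_id=f"{genotype}{day}_{j:03d}",
                genotype=genotype,
                day=day,
                duration=duration,
                sex=sex,
            )
            if audio:
                payload, truth = synth_recording(p, meta, rec_seed, fs=fs)
            else:
                payload, truth = synth_annotation_only(p, meta, rec_seed)
            meta = RecordingMeta(
                animal_id=meta.animal_id,
                genotype=genotype,
                day=day,
                weight=round(truth.animal.weight, 3),
                sex=sex,
                duration=duration,
            )
            records.append((meta, payload, truth))
            rows.append(
                {
                    "animal_id": meta.animal_id,
                    "genotype": genotype,
                    "day": day,
                    "weight": meta.weight,
                    "sex": sex,
                    "n_calls": truth.n_calls,
                    "seed": rec_seed,
                }
            )
            idx += 1
    return records, pd.DataFrame(rows)
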