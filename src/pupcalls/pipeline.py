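"""End-to-end orchestration: audio (or annotation tables) to statistics and
genotype classification.

The pipeline runs detect -> features -> bouts -> syllables -> aggregate ->
stats -> classify.  Each recording is reduced to an animal-summary row; the
bout cutoff is estimated per postnatal day over all genotypes pooled; group
comparisons and the matched-resample k-NN classifier run on the summary
table.  All randomness derives from one configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import bouts as bouts_mod
from . import classify as classify_mod
from . import detection, features, io, stats, syllables
from .params import JUMP_THRESHOLDS, RecordingMeta
from .synth import SynthGroundTruth

logger = logging.getLogger("pupcalls")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable analysis settings; validated on construction."""

    block: int = 512
    band_low_hz: float = 25_000.0
    band_high_hz: float = 110_000.0
    purity_threshold: float = 0.25
    dropout_purity: float = 0.10
    min_call_duration_s: float = 0.005
    merge_gap_s: float = 0.010
    min_calls_per_recording: int = 10
    jump_thresholds_hz: tuple[float, ...] = JUMP_THRESHOLDS
    classification_jump_threshold_hz: float = 5_000.0
    jump_bridge_s: float = 0.010
    bout_cutoff: str | float = "auto"  # "auto" or seconds
    knn_k: int = 3
    knn_repeats: int = 10_000
    bootstrap_reps: int = 1000
    equal_var: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block < 64 or self.block % 2:
            raise ValueError("block must be an even sample count >= 64")
        if not 0 < self.purity_threshold <= 1 or not 0 <= self.dropout_purity <= 1:
            raise ValueError("purity thresholds must lie in (0, 1]")
        if self.band_low_hz >= self.band_high_hz:
            raise ValueError("band_low_hz must be below band_high_hz")
        if self.min_call_duration_s <= 0 or self.merge_gap_s < 0:
            raise ValueError("durations must be positive")
        if isinstance(self.bout_cutoff, (int, float)) and self.bout_cutoff <= 0:
            raise ValueError("bout_cutoff must be 'auto' or a positive number of seconds")
        if self.knn_k % 2 == 0:
            raise ValueError("knn_k must be odd")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = io.load_config_file(path)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "jump_thresholds_hz" in raw:
            raw["jump_thresholds_hz"] = tuple(raw["jump_thresholds_hz"])
        return cls(**raw)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RecordingAnalysis:
    """Signal-level results for one recording, ready for bout/cohort stages."""

    meta: RecordingMeta
    intervals: np.ndarray  # (n_calls, 2) seconds
    tracks: list[features.PitchTrack]
    n_clicks: int
    spectrum: np.ndarray | None = None
    spectrum_freqs: np.ndarray | None = None
    total_power: float = float("nan")

    @property
    def n_calls(self) -> int:
        return int(self.intervals.shape[0])

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]


def analyze_audio(
    waveform: np.ndarray, fs: int, meta: RecordingMeta, config: PipelineConfig | None = None
) -> RecordingAnalysis:
    """Full signal chain for one recording: filter, sonogram, calls, clicks, tracks."""
    cfg = config or PipelineConfig()
    high = min(cfg.band_high_hz, 0.45 * fs)
    x = detection.bandpass(waveform, fs, cfg.band_low_hz, high)
    son = detection.compute_sonogram(x, fs, block=cfg.block)
    del x
    feats = detection.frame_features(son)
    clicks = detection.detect_clicks(son)
    calls = detection.detect_calls(
        son,
        feats,
        purity_threshold=cfg.purity_threshold,
        min_duration=cfg.min_call_duration_s,
        merge_gap=cfg.merge_gap_s,
        band=(cfg.band_low_hz, high),
        clicks=clicks,
    )
    clicks = detection.filter_clicks_outside_calls(clicks, calls)
    tracks = [
        features.pitch_track(son, c, feats, dropout_purity=cfg.dropout_purity, call_index=i)
        for i, c in enumerate(calls)
    ]
    if calls:
        freqs, spectrum, total = features.call_power_spectrum(son, calls)
    else:
        freqs, spectrum, total = None, None, float("nan")
    intervals = np.array([(c.onset, c.offset) for c in calls]).reshape(-1, 2)
    logger.info(
        "%s: %d calls, %d clicks", meta.animal_id, intervals.shape[0], len(clicks)
    )
    return RecordingAnalysis(
        meta=meta,
        intervals=intervals,
        tracks=tracks,
        n_clicks=len(clicks),
        spectrum=spectrum,
        spectrum_freqs=freqs,
        total_power=total,
    )


def analyze_annotation(truth: SynthGroundTruth, meta: RecordingMeta) -> RecordingAnalysis:
    """Annotation-only chain: ground-truth events stand in for the signal stages."""
    tracks = [features.track_from_annotation(c, call_index=i) for i, c in enumerate(truth.calls)]
    logger.info("%s: %d calls (annotation mode)", meta.animal_id, truth.n_calls)
    return RecordingAnalysis(
        meta=meta,
        intervals=truth.call_intervals,
        tracks=tracks,
        n_clicks=len(truth.click_times),
    )


def summarize_cohort(
    analyses: Sequence[RecordingAnalysis], config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Reduce recordings to the animal-summary table.

    The bout cutoff is estimated per postnatal day from the pooled pause
    histogram (unless fixed in the config); bout metrics, jump features and
    the two entropies are computed per recording; the >= 10 calls inclusion
    rule is applied.  Returns (summary table, cutoff per day).
    """
    cfg = config or PipelineConfig()
    cutoffs: dict[int, float] = {}
    days = sorted({a.meta.day for a in analyses})
    for day in days:
        if cfg.bout_cutoff != "auto":
            cutoffs[day] = float(cfg.bout_cutoff)
            continue
        pooled = np.concatenate(
            [
                bouts_mod.pause_lengths(a.intervals)
                for a in analyses
                if a.meta.day == day and a.n_calls >= 2
            ]
        )
        cutoffs[day] = bouts_mod.estimate_bout_cutoff(pooled)
        logger.info("day %d: bout cutoff %.3f s from %d pooled pauses", day, cutoffs[day], pooled.size)

    rows = []
    for a in analyses:
        row: dict = {
            "animal_id": a.meta.animal_id,
            "genotype": a.meta.genotype,
            "day": a.meta.day,
            "weight": a.meta.weight,
            "sex": a.meta.sex,
            "n_calls": a.n_calls,
            "n_clicks": a.n_clicks,
            "total_power": a.total_power,
        }
        if a.n_calls:
            row["call_duration"] = float(a.durations.mean())
            part = bouts_mod.partition_bouts(a.intervals, cutoffs[a.meta.day])
            bm = bouts_mod.bout_metrics(part)
            row.update(
                intra_bout_pause=bm.intra_pause_mean,
                inter_bout_pause=bm.inter_pause_mean,
                all_pause=bm.all_pause_mean,
                bouts_per_recording=bm.n_bouts,
                calls_per_bout=bm.calls_per_bout,
                percent_isolated=bm.percent_isolated,
            )
            max_jumps = [features.max_jump(t, cfg.jump_bridge_s) for t in a.tracks]
            max_jumps = [m for m in max_jumps if np.isfinite(m)]
            row["max_jump"] = float(np.mean(max_jumps)) if max_jumps else float("nan")
            labels = [
                syllables.classify_call(
                    t,
                    features.detect_jumps(t, cfg.classification_jump_threshold_hz, cfg.jump_bridge_s),
                )
                for t in a.tracks
            ]
            row["labels"] = labels
            row["usage_entropy"] = syllables.usage_entropy_of_labels(labels)
            try:
                row["markov_entropy"] = syllables.markov_entropy(labels)
            except ValueError:
                row["markov_entropy"] = float("nan")
            for th in cfg.jump_thresholds_hz:
                per_call = [
                    len(features.detect_jumps(t, th, cfg.jump_bridge_s)) for t in a.tracks
                ]
                row[f"jumps_per_call_{int(th)}"] = float(np.mean(per_call))
        rows.append(row)
    summary = stats.aggregate(rows, min_calls=cfg.min_calls_per_recording)
    return summary, cutoffs


_COMPARE_METRICS = (
    "n_calls",
    "n_clicks",
    "call_duration",
    "all_pause",
    "intra_bout_pause",
    "inter_bout_pause",
    "bouts_per_recording",
    "calls_per_bout",
    "percent_isolated",
    "max_jump",
    "usage_entropy",
    "markov_entropy",
)


def run_all(
    records: Sequence[tuple[RecordingMeta, object, object]],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    audio: bool = True,
    fs: int = 250_000,
) -> dict:
    """Execute the full pipeline and write every stage output under ``out_dir``.

    ``records`` is a sequence of (meta, payload, truth-or-None); payloads are
    waveforms when ``audio`` else ground-truth annotation objects.  Returns
    the run manifest (also written as ``manifest.json``).
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    analyses = []
    for meta, payload, truth in records:
        if audio:
            analyses.append(analyze_audio(np.asarray(payload), fs, meta, cfg))
        else:
            analyses.append(analyze_annotation(truth if truth is not None else payload, meta))

    outputs: dict[str, str] = {}
    calls_df = pd.concat(
        [io.calls_to_frame(a.meta.animal_id, a.intervals) for a in analyses],
        ignore_index=True,
    )
    outputs["calls"] = str(io.write_table(calls_df, out / "calls.csv"))

    summary, cutoffs = summarize_cohort(analyses, cfg)
    labels_rows = []
    for _, row in summary.iterrows():
        for i, lab in enumerate(row.get("labels", []) or []):
            labels_rows.append(
                {"recording_id": row["animal_id"], "call_index": i, "label": lab}
            )
    outputs["labels"] = str(io.write_table(pd.DataFrame(labels_rows), out / "labels.csv"))
    summary_out = summary.drop(columns=["labels"], errors="ignore")
    outputs["summaries"] = str(io.write_table(summary_out, out / "summaries.csv"))

    stats_frames = []
    for day in sorted(summary["day"].unique()):
        sub = summary[summary["day"] == day]
        if {"WT", "KO"} <= set(sub["genotype"]):
            metrics = [m for m in _COMPARE_METRICS if m in sub.columns]
            stats_frames.append(
                stats.compare_groups(sub, metrics, "WT", "KO", day=int(day), equal_var=cfg.equal_var)
            )
    if stats_frames:
        outputs["stats"] = str(
            io.write_table(pd.concat(stats_frames, ignore_index=True), out / "stats.csv")
        )

    classification: dict[str, dict] = {}
    for day in sorted(summary["day"].unique()):
        sub = summary[(summary["day"] == day) & summary["genotype"].isin(["WT", "KO"])]
        # recordings lacking a defined feature (e.g. no intra-bout pause when
        # every call is isolated) cannot enter the 5-feature space
        sub = sub.dropna(subset=list(classify_mod.FEATURE_COLUMNS))
        n_ko = int((sub["genotype"] == "KO").sum())
        if n_ko >= cfg.knn_k + 1 and (sub["genotype"] == "WT").sum() >= n_ko:
            res = classify_mod.matched_resample(
                sub.reset_index(drop=True),
                k=cfg.knn_k,
                repeats=cfg.knn_repeats,
                seed=cfg.seed,
            )
            classification[f"P{int(day)}"] = res.to_dict()
    if classification:
        outputs["classification"] = str(
            io.write_json(classification, out / "classification.json")
        )

    manifest = {
        "config_hash": cfg.content_hash(),
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "bout_cutoffs_s": {str(k): v for k, v in cutoffs.items()},
        "n_recordings": len(records),
        "n_included": int(len(summary)),
        "outputs": outputs,
        "elapsed_s": round(time.time() - t0, 2),
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
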