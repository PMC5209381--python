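"""Scoring detected events against synthetic ground truth.

Used to validate the detector on generated cohorts: detected call intervals
are matched one-to-one to true intervals by temporal overlap, and recall /
precision / boundary errors are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DetectionScores:
    recall: float
    precision: float
    n_true: int
    n_detected: int
    n_matched: int
    onset_mae_s: float
    offset_mae_s: float


def match_intervals(
    truth: np.ndarray, detected: np.ndarray, min_overlap_frac: float = 0.5
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detected to true intervals by overlap.

    A pair matches when its overlap exceeds ``min_overlap_frac`` of the
    shorter interval.  Both inputs are (n, 2) onset/offset arrays.
    """
    t = np.asarray(truth, dtype=float).reshape(-1, 2)
    d = np.asarray(detected, dtype=float).reshape(-1, 2)
    if t.shape[0] == 0 or d.shape[0] == 0:
        return []
    overlap = np.minimum(t[:, None, 1], d[None, :, 1]) - np.maximum(t[:, None, 0], d[None, :, 0])
    shorter = np.minimum(t[:, None, 1] - t[:, None, 0], d[None, :, 1] - d[None, :, 0])
    score = np.where(overlap > min_overlap_frac * shorter, overlap, -np.inf)
    pairs: list[tuple[int, int]] = []
    used_d: set[int] = set()
    for i in range(t.shape[0]):
        j = int(np.argmax(score[i]))
        if np.isfinite(score[i, j]) and j not in used_d:
            used_d.add(j)
            pairs.append((i, j))
    return pairs


def detection_scores(truth: np.ndarray, detected: np.ndarray) -> DetectionScores:
    """Recall, precision and mean absolute onset/offset errors."""
    t = np.asarray(truth, dtype=float).reshape(-1, 2)
    d = np.asarray(detected, dtype=float).reshape(-1, 2)
    pairs = match_intervals(t, d)
    if pairs:
        ti = np.array([p[0] for p in pairs])
        di = np.array([p[1] for p in pairs])
        onset_mae = float(np.mean(np.abs(d[di, 0] - t[ti, 0])))
        offset_mae = float(np.mean(np.abs(d[di, 1] - t[ti, 1])))
    else:
        onset_mae = offset_mae = float("nan")
    return DetectionScores(
        recall=len(pairs) / t.shape[0] if t.shape[0] else float("nan"),
        precision=len(pairs) / d.shape[0] if d.shape[0] else float("nan"),
        n_true=t.shape[0],
        n_detected=d.shape[0],
        n_matched=len(pairs),
        onset_mae_s=onset_mae,
        offset_mae_s=offset_mae,
    )
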