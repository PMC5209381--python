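"""Pause analysis and bout structure.

Pup calls arrive in *bouts*: runs of calls separated by brief intra-bout
pauses, with much longer inter-bout pauses between runs.  The intra/inter
cutoff is estimated from the pooled pause-length histogram: for each histogram
bin size from 50 to 300 ms, the minimum-count bin whose center lies in the
absolute window 0.15–0.32 s is located, and the bin centers are averaged over
bin sizes.  Calls are then partitioned at gaps >= the cutoff, and bout-level
metrics (bouts per recording, calls per bout, percent isolated calls, pause
means) are computed per recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_BIN_SIZES = np.arange(0.050, 0.3001, 0.010)
DEFAULT_SEARCH_RANGE = (0.15, 0.32)

#: Cutoffs measured in the study cohorts (seconds), usable as fixed inputs.
STUDY_CUTOFFS = {5: 0.273, 8: 0.239}


@dataclass(frozen=True)
class BoutPartition:
    """Ordered grouping of calls into bouts at a pause cutoff."""

    bouts: tuple[tuple[int, ...], ...]  # call indices per bout
    cutoff: float
    gaps: np.ndarray  # all inter-call gaps, seconds

    @property
    def n_calls(self) -> int:
        return sum(len(b) for b in self.bouts)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(b) for b in self.bouts], dtype=int)

    @property
    def intra_gaps(self) -> np.ndarray:
        return self.gaps[self.gaps < self.cutoff]

    @property
    def inter_gaps(self) -> np.ndarray:
        return self.gaps[self.gaps >= self.cutoff]


@dataclass(frozen=True)
class BoutMetrics:
    n_bouts: int
    calls_per_bout: float
    percent_isolated: float
    intra_pause_mean: float
    inter_pause_mean: float
    all_pause_mean: float


def pause_lengths(intervals: np.ndarray) -> np.ndarray:
    """Offset-to-onset gaps between consecutive calls (empty for < 2 calls)."""
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if iv.shape[0] < 2:
        return np.empty(0)
    gaps = iv[1:, 0] - iv[:-1, 1]
    if np.any(gaps <= 0):
        raise ValueError("call intervals overlap or touch; gaps must be positive")
    return gaps


def estimate_bout_cutoff(
    gaps: np.ndarray,
    bin_sizes: Sequence[float] = DEFAULT_BIN_SIZES,
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
) -> float:
    """Trough of the pause-length histogram, averaged over bin sizes.

    Histograms are anchored at 0 s.  For each bin size the minimum-count bin
    with center inside ``search_range`` is taken (ties broken toward the
    smallest center; empty bins are eligible); bin sizes with no center in
    range are skipped with a warning.
    """
    gaps = np.asarray(gaps, dtype=float)
    if gaps.size == 0:
        raise ValueError("no gaps supplied")
    if gaps.size < 100:
        warnings.warn(
            f"only {gaps.size} gaps; the cutoff estimate may be unstable", stacklevel=2
        )
    lo, hi = search_range
    centers_used = []
    top = max(gaps.max(), hi)
    for bs in bin_sizes:
        edges = np.arange(0.0, top + 2 * bs, bs)
        counts, _ = np.histogram(gaps, bins=edges)
        centers = edges[:-1] + bs / 2
        eligible = (centers >= lo) & (centers <= hi)
        if not eligible.any():
            warnings.warn(f"bin size {bs * 1e3:.0f} ms has no bin center in range; skipped",
                          stacklevel=2)
            continue
        idx = np.flatnonzero(eligible)
        best = idx[np.argmin(counts[idx])]  # argmin returns first => smallest center on ties
        centers_used.append(centers[best])
    if not centers_used:
        raise ValueError("no histogram bin size produced a bin center in the search range")
    return float(np.mean(centers_used))


def partition_bouts(intervals: np.ndarray, cutoff: float) -> BoutPartition:
    """Split the call sequence at gaps >= cutoff (boundary gap is inter-bout)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    n = iv.shape[0]
    if n == 0:
        return BoutPartition(bouts=(), cutoff=cutoff, gaps=np.empty(0))
    gaps = pause_lengths(iv) if n > 1 else np.empty(0)
    bouts: list[tuple[int, ...]] = []
    current = [0]
    for i, g in enumerate(gaps):
        if g >= cutoff:
            bouts.append(tuple(current))
            current = [i + 1]
        else:
            current.append(i + 1)
    bouts.append(tuple(current))
    return BoutPartition(bouts=tuple(bouts), cutoff=cutoff, gaps=gaps)


def bout_metrics(partition: BoutPartition) -> BoutMetrics:
    """Recording-level bout statistics; recording edges count as bout boundaries."""
    sizes = partition.sizes
    n_calls = int(sizes.sum())
    intra = partition.intra_gaps
    inter = partition.inter_gaps
    return BoutMetrics(
        n_bouts=len(sizes),
        calls_per_bout=float(sizes.mean()) if sizes.size else float("nan"),
        percent_isolated=float(100.0 * (sizes == 1).sum() / n_calls) if n_calls else float("nan"),
        intra_pause_mean=float(intra.mean()) if intra.size else float("nan"),
        inter_pause_mean=float(inter.mean()) if inter.size else float("nan"),
        all_pause_mean=float(partition.gaps.mean()) if partition.gaps.size else float("nan"),
    )


def long_pause_curve(gaps: np.ndarray, criteria: Sequence[float]) -> np.ndarray:
    """Proportion of gaps exceeding each criterion (monotone non-increasing)."""
    gaps = np.asarray(gaps, dtype=float)
    if gaps.size == 0:
        raise ValueError("no gaps supplied")
    crit = np.asarray(criteria, dtype=float)
    return (gaps[None, :] > crit[:, None]).mean(axis=1)
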