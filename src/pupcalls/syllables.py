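"""Rule-based syllable classification and vocabulary/sequence entropy.

Calls are assigned one of nine types from their pitch contour and jump
pattern: ``flat``, ``up-fm``, ``down-fm``, ``chevron``, ``one-jump-up``,
``one-jump-down``, ``multi-jump``, ``harmonic`` and ``other``.  The rules are
deterministic and total: jump count/sign takes precedence; jump-free contours
are classified by total excursion, net slope and the number of prominent
direction reversals.  ``harmonic`` is reserved for externally supplied
harmonic flags (the dominant-frequency track alone cannot reveal an
overtone); the default rule set never emits it.

Two entropy measures summarize a recording's repertoire: the Shannon entropy
of the syllable-type proportions (usage entropy) and the conditional entropy
of the next type given the previous one under a first-order Markov model of
the call sequence, H2 = -sum_y p(y) sum_x p(x|y) log2 p(x|y).  Both are
plug-in (maximum-likelihood) estimates in bits.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sst

from .features import PitchJump, PitchTrack

LABELS = (
    "flat",
    "up-fm",
    "down-fm",
    "chevron",
    "one-jump-up",
    "one-jump-down",
    "multi-jump",
    "harmonic",
    "other",
)

FLAT_EXCURSION_HZ = 2_800.0
SLOPE_NET_HZ = 3_000.0
CHEVRON_PROMINENCE_HZ = 2_400.0
REVERSAL_TOL_HZ = 800.0


def _direction_reversals(f: np.ndarray, tol: float) -> tuple[int, int]:
    """Count prominent direction reversals with hysteresis ``tol``.

    Returns (number of reversals, initial direction: +1 up / -1 down / 0 flat).
    """
    direction = 0
    first_direction = 0
    reversals = 0
    anchor = f[0]
    for x in f[1:]:
        if direction == 0:
            if x - anchor > tol:
                direction = 1
                first_direction = 1
                anchor = x
            elif anchor - x > tol:
                direction = -1
                first_direction = -1
                anchor = x
        elif direction == 1:
            if x > anchor:
                anchor = x
            elif anchor - x > tol:
                direction = -1
                reversals += 1
                anchor = x
        else:
            if x < anchor:
                anchor = x
            elif x - anchor > tol:
                direction = 1
                reversals += 1
                anchor = x
    return reversals, first_direction


def classify_call(
    track: PitchTrack,
    jumps: Sequence[PitchJump],
    harmonic: bool = False,
) -> str:
    """Deterministic syllable label for one call."""
    if harmonic:
        return "harmonic"
    if len(jumps) >= 2:
        return "multi-jump"
    if len(jumps) == 1:
        return "one-jump-up" if jumps[0].magnitude > 0 else "one-jump-down"
    f = track.freqs[np.isfinite(track.freqs)]
    if f.size < 3:
        return "other"
    excursion = float(f.max() - f.min())
    if excursion < FLAT_EXCURSION_HZ:
        return "flat"
    reversals, first_dir = _direction_reversals(f, REVERSAL_TOL_HZ)
    imax = int(np.argmax(f))
    if (
        reversals == 1
        and first_dir == 1
        and 0 < imax < f.size - 1
        and f[imax] - f[0] > CHEVRON_PROMINENCE_HZ
        and f[imax] - f[-1] > CHEVRON_PROMINENCE_HZ
    ):
        return "chevron"
    if reversals <= 1:
        net = float(f[-1] - f[0])
        if net >= SLOPE_NET_HZ:
            return "up-fm"
        if net <= -SLOPE_NET_HZ:
            return "down-fm"
    return "other"


def type_distribution(labels: Sequence[str]) -> dict[str, float]:
    """Maximum-likelihood syllable-type proportions."""
    if len(labels) == 0:
        raise ValueError("no labels supplied")
    counts = Counter(labels)
    n = sum(counts.values())
    return {k: v / n for k, v in sorted(counts.items())}


def usage_entropy(dist: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon entropy (bits) of a syllable-type distribution."""
    p = np.asarray(list(dist.values()) if isinstance(dist, Mapping) else dist, dtype=float)
    if p.size == 0 or not np.isclose(p.sum(), 1.0):
        raise ValueError("distribution must be non-empty and sum to 1")
    return float(sst.entropy(p, base=2))


def usage_entropy_of_labels(labels: Sequence[str]) -> float:
    return usage_entropy(type_distribution(labels))


def markov_entropy(sequences: Sequence[str] | Iterable[Sequence[str]]) -> float:
    """First-order Markov sequence entropy H2 in bits.

    Accepts a single label sequence or several (e.g. one per recording);
    transitions are counted within each sequence only, never across
    boundaries.  H2 is the conditional entropy of the successor type given
    the predecessor, weighted by the empirical predecessor marginal.
    """
    if len(sequences) and isinstance(sequences[0], str):  # type: ignore[index]
        sequences = [sequences]  # type: ignore[list-item]
    transitions: Counter[tuple[str, str]] = Counter()
    for seq in sequences:  # type: ignore[union-attr]
        seq = list(seq)
        for a, b in zip(seq[:-1], seq[1:]):
            transitions[(a, b)] += 1
    total = sum(transitions.values())
    if total == 0:
        raise ValueError("need at least one transition (a sequence of length >= 2)")
    pred_counts: Counter[str] = Counter()
    for (a, _b), c in transitions.items():
        pred_counts[a] += c
    h2 = 0.0
    for a, ca in pred_counts.items():
        p_a = ca / total
        cond = np.array([c for (x, _y), c in transitions.items() if x == a], dtype=float)
        cond /= cond.sum()
        h2 += p_a * float(sst.entropy(cond, base=2))
    return h2
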