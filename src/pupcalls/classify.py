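"""Genotype inference from the 5-feature vocal profile.

Each included recording is summarized by five normalized features: intra-bout
pause duration, largest pitch jump per call, bouts per recording, calls per
bout, and percent isolated calls.  Recordings are classified WT vs KO by the
majority identity of their k nearest neighbours (Euclidean distance in the
5-dimensional z-scored space), leaving the recording itself out.  Because WT
groups outnumber KO groups, a random WT subset of size n_KO is drawn without
replacement and the leave-one-out accuracy recorded; repeating this matched
resampling (10,000 times by default) yields a mean accuracy and a 2.5–97.5
percentile interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

FEATURE_COLUMNS = (
    "intra_bout_pause",
    "max_jump",
    "bouts_per_recording",
    "calls_per_bout",
    "percent_isolated",
)


@dataclass(frozen=True)
class KnnResult:
    mean_accuracy: float
    ci: tuple[float, float]
    k: int
    repeats: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "ci": list(self.ci),
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
        }


def normalize_features(
    table: pd.DataFrame, columns: Sequence[str] = FEATURE_COLUMNS, ddof: int = 1
) -> pd.DataFrame:
    """Z-score each feature column over all rows (sample SD by default)."""
    if len(table) < 2:
        raise ValueError("need at least two recordings to normalize")
    out = table.copy()
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        sd = np.std(x, ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"feature {col!r} has zero variance; cannot normalize")
        out[col] = (x - x.mean()) / sd
    return out


def _loocv_from_distances(dist: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Leave-one-out k-NN accuracy given a full pairwise distance matrix.

    Distance ties resolve toward the smallest row index (stable sort), which
    also makes degenerate duplicated points deterministic.
    """
    n = dist.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the table size {n}")
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    votes = labels[nn].sum(axis=1)
    pred = votes * 2 > k  # majority of k (labels are 0/1)
    return float(np.mean(pred == labels.astype(bool)))


def knn_loocv(features: np.ndarray, labels: Sequence[int], k: int = 3) -> float:
    """Leave-one-out k-NN accuracy in feature space (labels: 0 = WT, 1 = KO)."""
    if k % 2 == 0:
        raise ValueError("k must be odd (two-class majority vote)")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    return _loocv_from_distances(dist, y, k)


def matched_resample(
    table: pd.DataFrame,
    k: int = 3,
    repeats: int = 10_000,
    seed: int = 0,
    columns: Sequence[str] = FEATURE_COLUMNS,
    label_column: str = "genotype",
    positive_label: str = "KO",
    renormalize_per_sample: bool = False,
) -> KnnResult:
    """Matched-subsample leave-one-out k-NN classification.

    The table is z-scored once over all included recordings (or per subsample
    with ``renormalize_per_sample``); each repeat draws a WT subset matching
    the KO count without replacement and scores leave-one-out k-NN on the
    balanced table.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    y_all = (table[label_column] == positive_label).to_numpy()
    idx_pos = np.flatnonzero(y_all)
    idx_neg = np.flatnonzero(~y_all)
    n_pos = idx_pos.size
    if n_pos < k + 1 or idx_neg.size < n_pos:
        raise ValueError(
            f"need >= {k + 1} KO and at least as many WT recordings "
            f"(got {n_pos} KO, {idx_neg.size} WT)"
        )
    rng = np.random.default_rng(seed)
    norm = normalize_features(table, columns)
    X_all = norm.loc[:, list(columns)].to_numpy(dtype=float)
    diff = X_all[:, None, :] - X_all[None, :, :]
    dist_all = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))

    accs = np.empty(repeats)
    for r in range(repeats):
        chosen = rng.choice(idx_neg, size=n_pos, replace=False)
        idx = np.concatenate([np.sort(chosen), idx_pos])
        if renormalize_per_sample:
            sub = normalize_features(table.iloc[idx], columns)
            X = sub.loc[:, list(columns)].to_numpy(dtype=float)
            d = X[:, None, :] - X[None, :, :]
            dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        else:
            dist = dist_all[np.ix_(idx, idx)]
        accs[r] = _loocv_from_distances(dist, y_all[idx].astype(int), k)
    return KnnResult(
        mean_accuracy=float(accs.mean()),
        ci=(float(np.percentile(accs, 2.5)), float(np.percentile(accs, 97.5))),
        k=k,
        repeats=repeats,
        seed=seed,
    )
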