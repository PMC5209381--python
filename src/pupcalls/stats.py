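"""Cohort-level statistics: per-animal aggregation, two-tailed comparisons,
bootstrap spectral confidence bands, and weight correlations.

Group comparisons follow the two-stage averaging scheme: every call or pause
contributes to its animal's mean, and animals are the units of the two-sample
test (pooled-variance Student t by default, Welch by flag).  A call-level
variant treating each call as a data point is available for the higher-n
sensitivity analysis.  Power spectra are compared per frequency bin with
subject-level bootstrap percentile intervals (1000 resamples); a bin is
reported significant only when the two groups' 95% intervals are disjoint and
at least one neighbouring bin is significant too (adjacency rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst


@dataclass(frozen=True)
class TestResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class BootstrapBand:
    freqs: np.ndarray
    mean: dict[str, np.ndarray]
    lower: dict[str, np.ndarray]
    upper: dict[str, np.ndarray]
    significant: np.ndarray          # per-bin: group CIs disjoint
    significant_adjacent: np.ndarray  # after the adjacency rule


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def ttest_two_tailed(
    group_a: Sequence[float], group_b: Sequence[float], equal_var: bool = True
) -> TestResult:
    """Two-sample two-tailed t-test on per-animal means.

    Pooled-variance Student t by default (df = n_a + n_b - 2); set
    ``equal_var=False`` for Welch.  Two identical constant groups give
    t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        t, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
    else:
        res = sst.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return TestResult(
        t=t, df=df, p=p,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=_sem(a), sem_b=_sem(b), n_a=len(a), n_b=len(b),
    )


@dataclass(frozen=True)
class CallLevelComparison:
    test: TestResult
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]


def per_call_comparison(
    calls_a: Sequence[float], calls_b: Sequence[float], ci_level: float = 0.95
) -> CallLevelComparison:
    """Group comparison treating each call (not each animal) as a data point."""
    test = ttest_two_tailed(calls_a, calls_b)

    def ci(x: Sequence[float]) -> tuple[float, float]:
        x = np.asarray(x, dtype=float)
        m = x.mean()
        if len(x) < 2 or np.std(x) == 0:
            return (float(m), float(m))
        half = sst.t.ppf(0.5 + ci_level / 2, len(x) - 1) * _sem(x)
        return (float(m - half), float(m + half))

    return CallLevelComparison(test=test, ci_a=ci(calls_a), ci_b=ci(calls_b))


def bootstrap_spectra(
    spectra_by_group: Mapping[str, np.ndarray],
    freqs: np.ndarray,
    reps: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> BootstrapBand:
    """Subject-level bootstrap confidence bands of group-mean power spectra.

    ``spectra_by_group`` maps a group name to a (subjects x frequency bins)
    array.  Subjects are resampled with replacement within group ``reps``
    times; per-bin percentile intervals are formed; with exactly two groups,
    bins whose intervals are disjoint are flagged significant and then
    filtered by the adjacency rule (a significant bin must neighbour another
    significant bin).
    """
    if len(spectra_by_group) < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2 * 100
    mean: dict[str, np.ndarray] = {}
    lower: dict[str, np.ndarray] = {}
    upper: dict[str, np.ndarray] = {}
    for name, spectra in spectra_by_group.items():
        spectra = np.asarray(spectra, dtype=float)
        n = spectra.shape[0]
        if n < 3:
            raise ValueError(f"group {name!r} has {n} subjects; need >= 3")
        draws = rng.integers(0, n, size=(reps, n))
        boot_means = spectra[draws].mean(axis=1)  # (reps, bins)
        mean[name] = spectra.mean(axis=0)
        lower[name] = np.percentile(boot_means, alpha, axis=0)
        upper[name] = np.percentile(boot_means, 100 - alpha, axis=0)
    names = list(spectra_by_group)
    g1, g2 = names[0], names[1]
    significant = (lower[g1] > upper[g2]) | (lower[g2] > upper[g1])
    neighbour = np.zeros_like(significant)
    neighbour[1:] |= significant[:-1]
    neighbour[:-1] |= significant[1:]
    return BootstrapBand(
        freqs=np.asarray(freqs, dtype=float),
        mean=mean,
        lower=lower,
        upper=upper,
        significant=significant,
        significant_adjacent=significant & neighbour,
    )


def weight_correlation(
    summary: pd.DataFrame,
    metric: str,
    genotype: str | None = None,
    day: int | None = None,
) -> tuple[float, float]:
    """Pearson correlation (r, two-tailed p) between body weight and a metric."""
    df = summary
    if genotype is not None:
        df = df[df["genotype"] == genotype]
    if day is not None:
        df = df[df["day"] == day]
    df = df.dropna(subset=["weight", metric])
    if len(df) < 3:
        raise ValueError("need at least three paired observations")
    x = df["weight"].to_numpy(dtype=float)
    y = df[metric].to_numpy(dtype=float)
    if np.std(y) == 0 or np.std(x) == 0:
        raise ValueError(f"metric {metric!r} (or weight) is constant; r undefined")
    r, p = sst.pearsonr(x, y)
    return float(r), float(p)


#: Metrics carried in an animal-summary table (beyond identity columns).
SUMMARY_METRICS = (
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
    "total_power",
    "usage_entropy",
    "markov_entropy",
)


def aggregate(per_recording: Sequence[Mapping], min_calls: int = 10) -> pd.DataFrame:
    """Assemble the animal-summary table, applying the >= 10 calls inclusion rule.

    ``per_recording`` holds one mapping per recording with identity columns
    (animal_id, genotype, day, weight) and whatever summary metrics upstream
    stages produced; recordings with fewer than ``min_calls`` calls are
    dropped.
    """
    df = pd.DataFrame(list(per_recording))
    if "n_calls" not in df.columns:
        raise ValueError("per-recording summaries lack 'n_calls' (detection stage missing)")
    return df[df["n_calls"] >= min_calls].reset_index(drop=True)


def compare_groups(
    summary: pd.DataFrame,
    metrics: Sequence[str],
    group_a: str = "WT",
    group_b: str = "KO",
    day: int | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-tailed t-test per metric between two genotypes (one row per metric)."""
    df = summary if day is None else summary[summary["day"] == day]
    rows = []
    for m in metrics:
        a = df.loc[df["genotype"] == group_a, m].dropna()
        b = df.loc[df["genotype"] == group_b, m].dropna()
        res = ttest_two_tailed(a, b, equal_var=equal_var)
        rows.append(
            {
                "metric": m,
                "day": day,
                "group_a": group_a,
                "group_b": group_b,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "mean_a": res.mean_a,
                "mean_b": res.mean_b,
                "sem_a": res.sem_a,
                "sem_b": res.sem_b,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; group comparisons are unadjusted by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0, 1)
    return out
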