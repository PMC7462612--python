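"""Cohort-level summaries and comparisons of per-unit discharge features.

Robust central moments (median/MAD alongside mean/SEM and skewness),
cumulative firing-rate-vs-isolation curves, the +/-2 SD outlier rule, k = 2
k-means clustering of discharge features with silhouette assessment, and the
two-group tests (Mann-Whitney rank sum, Wilcoxon signed rank, chi-square on
proportions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

#: canonical columns of a per-unit feature table
FEATURE_COLUMNS = [
    "unit_id", "disease", "firing_rate", "cv_isi", "mua_beta", "sta_beta",
    "isolation_score", "stationary", "segment_duration",
]


@dataclass
class SummaryStats:
    median: float
    mad: float  # median absolute deviation, unscaled
    mean: float
    sem: float
    skewness: float
    n: int


@dataclass
class ClusterResult:
    labels: np.ndarray  # values in {1, 2}
    centroids: np.ndarray
    silhouette: np.ndarray  # per point, in [-1, 1]
    mean_silhouette: float
    degenerate: bool = False


@dataclass
class RateIsolationCurve:
    thresholds: np.ndarray
    stats: list[SummaryStats | None]  # None where the threshold bin is empty
    r_median: float
    r_mean: float
    degenerate: bool = False


def central_moments(values: np.ndarray) -> SummaryStats:
    """Median, unscaled MAD, mean, SEM and the biased moment skewness.

    Skewness is m3 / m2^(3/2) (biased moment coefficient); it is undefined
    (NaN) below n = 3.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one value")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan
    skew = float(stats.skew(x, bias=True)) if x.size >= 3 else np.nan
    return SummaryStats(median=med, mad=mad, mean=mean, sem=sem, skewness=skew, n=x.size)


def rate_vs_isolation_curve(
    table: pd.DataFrame, thresholds: np.ndarray | None = None
) -> RateIsolationCurve:
    """Cumulative median/mean firing rate vs isolation-score threshold.

    For each threshold, the summary covers all units with isolation score >=
    that threshold; Pearson r is computed between the populated threshold
    values and their median (and mean) rates. Empty threshold bins are
    excluded and the curve flagged degenerate when fewer than two bins remain.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    if thresholds is None:
        thresholds = np.linspace(0.0, 0.9, 10)
    out: list[SummaryStats | None] = []
    for thr in thresholds:
        sub = table.loc[table["isolation_score"] >= thr, "firing_rate"].to_numpy()
        out.append(central_moments(sub) if sub.size else None)
    ok = [i for i, s in enumerate(out) if s is not None]
    if len(ok) < 2:
        return RateIsolationCurve(thresholds, out, np.nan, np.nan, degenerate=True)
    thr_ok = thresholds[ok]
    r_med = float(stats.pearsonr(thr_ok, [out[i].median for i in ok]).statistic)
    r_mean = float(stats.pearsonr(thr_ok, [out[i].mean for i in ok]).statistic)
    return RateIsolationCurve(thresholds, out, r_med, r_mean,
                              degenerate=len(ok) < len(out))


def find_outliers(values: np.ndarray) -> np.ndarray:
    """Indices of values at or beyond mean +/- 2 SD (empirical 68-95-99.7 rule)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std()
    if sd == 0.0:
        return np.array([], dtype=int)
    m = x.mean()
    return np.flatnonzero((x >= m + 2 * sd) | (x <= m - 2 * sd))


def cluster_units_k2(
    table: pd.DataFrame | np.ndarray,
    features: tuple[str, ...] = ("firing_rate", "cv_isi"),
    seed: int = 0,
    n_init: int = 20,
    standardize: bool = False,
) -> ClusterResult:
    """k = 2 k-means on discharge features with per-point silhouettes.

    Features default to (firing rate, CV of ISI) on their raw scales; 3-4D
    variants add the MUA and STA-LFP beta powers. ``standardize`` rescales
    columns to unit variance first (off by default). The two-point cohort is
    the degenerate limit: one point per cluster, silhouettes 0 by convention.
    """
    X = (
        table[list(features)].to_numpy(dtype=float)
        if isinstance(table, pd.DataFrame)
        else np.asarray(table, dtype=float)
    )
    if X.shape[0] < 2:
        raise ValueError("need at least 2 units")
    if standardize:
        sd = X.std(axis=0)
        X = X / np.where(sd == 0, 1.0, sd)
    if X.shape[0] == 2:
        return ClusterResult(
            labels=np.array([1, 2]), centroids=X.copy(),
            silhouette=np.zeros(2), mean_silhouette=0.0, degenerate=True,
        )
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed).fit(X)
    labels = km.labels_ + 1
    degenerate = np.unique(km.labels_).size < 2 or np.unique(X, axis=0).shape[0] < 2
    if degenerate:
        sil = np.zeros(X.shape[0])
    else:
        sil = silhouette_samples(X, km.labels_)
    return ClusterResult(
        labels=labels, centroids=km.cluster_centers_, silhouette=sil,
        mean_silhouette=float(sil.mean()), degenerate=degenerate,
    )


def compare_groups(a, b, kind: str = "ranksum") -> tuple[float, float]:
    """Two-group comparison: 'ranksum' | 'signedrank' | 'chi2'; returns (stat, p).

    ranksum: Mann-Whitney U on two independent samples. signedrank: Wilcoxon
    signed-rank on paired samples (identical pairs everywhere -> p = 1).
    chi2: chi-square test (no continuity correction) on two proportions given
    as binary arrays.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if kind == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if kind == "signedrank":
        if np.all(a == b):
            return 0.0, 1.0  # all differences zero: no evidence either way
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if kind == "chi2":
        table = np.array(
            [[np.sum(a == 1), np.sum(a != 1)], [np.sum(b == 1), np.sum(b != 1)]]
        )
        res = stats.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test kind {kind!r}")
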