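"""Unit quality control: isolation score and firing-rate/amplitude stationarity.

The isolation score grades how well a unit's spike events separate from noise
events in the 2-PC feature space, from 0 (highly noisy) to 1 (perfect
isolation). Stationarity is assessed from the slopes of linear regression
lines fitted to the z-scored firing rate and mean spike amplitude over 10
equal time bins spanning first-to-last spike; units whose slope reaches the
cohort's 70th percentile on either axis are flagged non-stationary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist


@dataclass
class SortedUnit:
    """One sorted unit with its QC annotations."""

    timestamps: np.ndarray
    amplitudes: np.ndarray
    segment_duration: float
    unit_id: int = 0
    isolation_score: float = np.nan
    m_rate: float = np.nan
    m_amp: float = np.nan
    stationary: bool | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)


def isolation_score(
    spike_events: np.ndarray, noise_events: np.ndarray, lam: float = 10.0
) -> float:
    """Similarity-ratio isolation score in [0, 1].

    With f(x, y) = exp(-d(x, y) * lam / dbar) and dbar the mean pairwise
    distance among spike events, the score is the mean over spike events x of

        sum_{y in spikes, y != x} f(x, y) / sum_{y in all events, y != x} f(x, y)

    i.e. the average fraction of each spike's similarity mass that stays
    inside the spike cluster. An empty noise set returns 1 with a warning; a
    zero-diameter spike cluster is degenerate and rejected.
    """
    S = np.atleast_2d(np.asarray(spike_events, dtype=float))
    N = np.atleast_2d(np.asarray(noise_events, dtype=float)) if len(noise_events) else None
    if S.shape[0] < 2:
        raise ValueError("need at least 2 spike events")
    if N is None or N.shape[0] == 0:
        warnings.warn("empty noise set: isolation score defaults to 1")
        return 1.0
    dbar = float(pdist(S).mean())
    if dbar == 0.0:
        raise ValueError("degenerate spike cluster: zero mean pairwise distance")
    f_ss = np.exp(-cdist(S, S) * lam / dbar)
    np.fill_diagonal(f_ss, 0.0)
    f_sn = np.exp(-cdist(S, N) * lam / dbar)
    num = f_ss.sum(axis=1)
    den = num + f_sn.sum(axis=1)
    return float(np.mean(num / den))


def _zscore(v: np.ndarray) -> np.ndarray:
    # sample SD (ddof=1); zero-variance bins get z = 0 so the slope is 0
    sd = v.std(ddof=1)
    if sd == 0.0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def stationarity_slopes(
    timestamps: np.ndarray, amplitudes: np.ndarray | None = None, n_bins: int = 10
) -> tuple[float, float]:
    """OLS slopes (z-score/bin) of per-bin firing rate and mean spike amplitude.

    The span between the first and last spike is cut into ``n_bins`` equal
    non-overlapping bins; per-bin firing rate and mean amplitude are z-scored
    (sample SD over the bins) and regressed on the bin index 1..n_bins.
    Empty bins contribute rate 0 and are excluded from the amplitude
    regression (no spikes, no amplitude sample).
    """
    t = np.asarray(timestamps, dtype=float)
    if t.size < n_bins:
        raise ValueError(f"need at least {n_bins} spikes")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("zero time span")
    edges = t[0] + span * np.arange(n_bins + 1) / n_bins
    counts, _ = np.histogram(t, bins=edges)  # last bin closed: includes t[-1]
    binwidth = span / n_bins
    rate = counts / binwidth
    idx = np.arange(1, n_bins + 1, dtype=float)
    m_rate = float(np.polyfit(idx, _zscore(rate), 1)[0])

    m_amp = 0.0
    if amplitudes is not None:
        a = np.asarray(amplitudes, dtype=float)
        which = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)
        occupied = np.flatnonzero(counts > 0)
        if occupied.size < 2:
            raise ValueError("fewer than 2 bins contain spikes")
        mean_amp = np.array([a[which == b].mean() for b in occupied])
        m_amp = float(np.polyfit(idx[occupied], _zscore(mean_amp), 1)[0])
    return m_rate, m_amp


def classify_stationarity(
    units: list[SortedUnit], percentile: float = 70.0
) -> tuple[list[SortedUnit], tuple[float, float]]:
    """Flag cohort units whose drift slope reaches the cohort percentile cutoff.

    Cutoffs are the ``percentile``-th percentiles (linear interpolation
    between order statistics) of the rate slopes and amplitude slopes taken
    separately across the cohort; a unit is non-stationary iff either of its
    slopes is >= the corresponding cutoff. A degenerate axis on which every
    unit has the identical slope flags nobody.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 units to set cohort cutoffs")
    mr = np.array([u.m_rate for u in units])
    ma = np.array([u.m_amp for u in units])
    cut_r = float(np.percentile(mr, percentile, method="linear"))
    cut_a = float(np.percentile(ma, percentile, method="linear"))
    flag_r = (mr >= cut_r) if np.ptp(mr) > 0 else np.zeros(len(units), bool)
    flag_a = (ma >= cut_a) if np.ptp(ma) > 0 else np.zeros(len(units), bool)
    for u, fr, fa in zip(units, flag_r, flag_a):
        u.stationary = not (fr or fa)
    return units, (cut_r, cut_a)
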