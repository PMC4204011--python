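"""Interval feature/signal statistics.

Relates genomic interval features (length, CpG density) to a per-interval
signal such as ChIP-seq read counts: equal-count quartile binning,
interval-overlap fractions between two sets, and rank correlation.

Intervals are carried as pandas DataFrames with columns
``chrom, start, end`` (0-based half-open) plus optional ``cpg_density``
and ``signal`` columns; ``length`` is derived as end − start.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "quartile_bin",
    "overlap_fraction",
    "rank_correlation",
]

Feature = Literal["length", "cpg_density"]


def _feature_values(intervals: pd.DataFrame, feature: str) -> np.ndarray:
    if feature == "length":
        return (intervals["end"] - intervals["start"]).to_numpy(dtype=float)
    if feature not in intervals.columns:
        raise KeyError(f"feature column {feature!r} not present")
    return intervals[feature].to_numpy(dtype=float)


def quartile_bin(
    intervals: pd.DataFrame,
    feature: Feature = "length",
    signal_col: str = "signal",
) -> pd.DataFrame:
    """Split intervals into 4 equal-count bins of a feature; summarise signal.

    Intervals are ranked by the feature (stable sort, so ties keep input
    order and lower ranks fill lower bins) and split into four bins whose
    sizes differ by at most one. Returns one row per bin with the feature
    range, interval count, and mean and median signal.

    Raises
    ------
    ValueError
        If fewer than 4 intervals are supplied.
    """
    n = len(intervals)
    if n < 4:
        raise ValueError(f"quartile binning needs ≥4 intervals, got {n}")
    values = _feature_values(intervals, feature)
    signal = intervals[signal_col].to_numpy(dtype=float)
    order = np.argsort(values, kind="stable")
    rows = []
    for bin_index, idx in enumerate(np.array_split(order, 4), start=1):
        rows.append(
            {
                "bin_index": bin_index,
                "feature": feature,
                "feature_min": float(values[idx].min()),
                "feature_max": float(values[idx].max()),
                "n": len(idx),
                "mean_signal": float(signal[idx].mean()),
                "median_signal": float(np.median(signal[idx])),
            }
        )
    return pd.DataFrame(rows)


def overlap_fraction(query: pd.DataFrame, subject: pd.DataFrame) -> float:
    """Fraction of query intervals sharing ≥1 bp with any subject interval.

    Subject intervals are merged per chromosome and each query is tested
    by binary search against the merged set — O((n+m) log m) sweep.

    Raises
    ------
    ValueError
        If the query set is empty (the fraction is undefined).
    """
    if len(query) == 0:
        raise ValueError("overlap fraction undefined for an empty query set")
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in subject.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        m_starts, m_ends = [], []
        for s, e in zip(starts, ends):
            if m_ends and s <= m_ends[-1]:
                m_ends[-1] = max(m_ends[-1], e)
            else:
                m_starts.append(s)
                m_ends.append(e)
        merged[chrom] = (np.asarray(m_starts), np.asarray(m_ends))

    hits = 0
    for chrom, s, e in zip(query["chrom"], query["start"], query["end"]):
        if chrom not in merged:
            continue
        m_starts, m_ends = merged[chrom]
        # rightmost merged interval starting before the query end
        i = int(np.searchsorted(m_starts, e, side="left")) - 1
        if i >= 0 and m_ends[i] > s:
            hits += 1
    return hits / len(query)


def rank_correlation(
    intervals: pd.DataFrame,
    feature: Feature = "cpg_density",
    signal_col: str = "signal",
) -> float:
    """Spearman rank correlation between a feature and the signal.

    Raises
    ------
    ValueError
        If fewer than 3 intervals are supplied or either variable has
        zero variance (the correlation is undefined).
    """
    if len(intervals) < 3:
        raise ValueError("rank correlation needs ≥3 intervals")
    x = _feature_values(intervals, feature)
    y = intervals[signal_col].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined: zero variance")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
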