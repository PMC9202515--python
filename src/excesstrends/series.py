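"""Weekly relative-search-volume series.

The basic data object of the pipeline is a weekly time series of relative
search volumes (probabilities scaled by 10 million), optionally with several
replicate samples per week to capture the sampling variability of the search
API. Weeks follow Google's convention of starting on Sunday; suppressed
(below-threshold) values are carried as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SearchSeries",
    "aggregate_replicates",
    "sunday_week_grid",
    "week_of_year",
]


def sunday_week_grid(start, end) -> pd.DatetimeIndex:
    """All Sunday week-start dates falling within [start, end].

    The first week is the first Sunday on or after ``start``; a week belongs
    to the grid if its start date is on or before ``end``.
    """
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if start >= end:
        raise ValueError(f"start {start.date()} must precede end {end.date()}")
    first = start + pd.Timedelta(days=(6 - start.dayofweek) % 7)
    return pd.date_range(first, end, freq="7D")


def week_of_year(dates) -> np.ndarray:
    """Real-valued week of year in [1, 54): 1 + (day_of_year - 1)/7."""
    d = pd.DatetimeIndex(dates)
    return np.asarray((d.dayofyear - 1) / 7.0 + 1.0, dtype=float)


@dataclass
class SearchSeries:
    """Weekly search-volume observations.

    Parameters
    ----------
    week_start : DatetimeIndex
        Week start dates; strictly increasing, spaced exactly 7 days.
    replicates : ndarray of shape (n_weeks, n_replicates), optional
        Replicate samples per week; NaN marks a suppressed value. ``None``
        for series that carry only aggregated values.
    aggregated : ndarray of shape (n_weeks,), optional
        Per-week aggregated volume (NaN where no usable replicate exists).
    aggregator : str, optional
        Name of the aggregation applied ("mean" or "median"), if any.
    """

    week_start: pd.DatetimeIndex
    replicates: np.ndarray | None = None
    aggregated: np.ndarray | None = None
    aggregator: str | None = None

    def __post_init__(self) -> None:
        self.week_start = pd.DatetimeIndex(self.week_start)
        n = len(self.week_start)
        if n == 0:
            raise ValueError("empty series")
        deltas = np.diff(self.week_start.asi8)
        if n > 1 and not np.all(deltas == 7 * 86400 * 10**9):
            raise ValueError("weeks must be strictly increasing and spaced exactly 7 days")
        if self.replicates is not None:
            self.replicates = np.asarray(self.replicates, dtype=float)
            if self.replicates.ndim != 2 or self.replicates.shape[0] != n:
                raise ValueError("replicates must be (n_weeks, n_replicates)")
            if np.nanmin(self.replicates, initial=0.0) < 0:
                raise ValueError("search volumes must be non-negative")
        if self.aggregated is not None:
            self.aggregated = np.asarray(self.aggregated, dtype=float)
            if self.aggregated.shape != (n,):
                raise ValueError("aggregated must be (n_weeks,)")
            if np.nanmin(self.aggregated, initial=0.0) < 0:
                raise ValueError("search volumes must be non-negative")
        if self.replicates is None and self.aggregated is None:
            raise ValueError("series needs replicates or aggregated values")

    @property
    def n_weeks(self) -> int:
        return len(self.week_start)

    @property
    def week_of_year(self) -> np.ndarray:
        return week_of_year(self.week_start)

    def window(self, start, end) -> "SearchSeries":
        """Sub-series of weeks whose start date lies in [start, end]."""
        mask = (self.week_start >= pd.Timestamp(start)) & (
            self.week_start <= pd.Timestamp(end)
        )
        if not mask.any():
            raise ValueError("window contains no weeks")
        return SearchSeries(
            week_start=self.week_start[mask],
            replicates=None if self.replicates is None else self.replicates[mask],
            aggregated=None if self.aggregated is None else self.aggregated[mask],
            aggregator=self.aggregator,
        )

    def to_frame(self) -> pd.DataFrame:
        data: dict = {"week_start_date": self.week_start}
        if self.aggregated is not None:
            data["value"] = self.aggregated
        return pd.DataFrame(data)


def aggregate_replicates(series: SearchSeries, method: str = "mean") -> SearchSeries:
    """Collapse replicate samples to one value per week.

    Weeks where every replicate is suppressed stay missing (NaN). The
    replicate matrix itself is left untouched on the returned series.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if series.replicates is None:
        raise ValueError("series has no replicates to aggregate")
    reps = series.replicates
    usable = np.sum(~np.isnan(reps), axis=1) > 0
    agg = np.full(series.n_weeks, np.nan)
    func = np.nanmean if method == "mean" else np.nanmedian
    if usable.any():
        agg[usable] = func(reps[usable], axis=1)
    return replace(series, aggregated=agg, aggregator=method)
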