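"""CSV readers and writers for weekly search-volume series.

Two on-disk schemas are supported:

- long (replicate) format: columns ``week_start_date`` (ISO-8601),
  ``replicate_id`` (0-based int), ``value`` (empty for suppressed);
- aggregated format: columns ``week_start_date``, ``value``.

A live search-API client is out of scope; :func:`fetch_search_volumes` is a
stub documenting the schema such a client would have to return.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .series import SearchSeries

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "fetch_search_volumes",
]


def _parse_dates(raw: pd.Series, path) -> pd.DatetimeIndex:
    try:
        return pd.DatetimeIndex(pd.to_datetime(raw, format="%Y-%m-%d"))
    except ValueError as err:
        raise ValueError(f"{path}: non-ISO week_start_date values ({err})") from None


def read_series_csv(path) -> SearchSeries:
    """Read a series CSV, auto-detecting long vs aggregated format."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"week_start_date", "replicate_id", "value"}.issubset(cols):
        return _read_long(df, path)
    if {"week_start_date", "value"}.issubset(cols):
        return _read_aggregated(df, path)
    raise ValueError(
        f"{path}: expected columns (week_start_date, replicate_id, value) "
        f"or (week_start_date, value); found {sorted(cols)}"
    )


def _duplicate_error(path, dup_dates) -> ValueError:
    first = sorted(set(str(pd.Timestamp(d).date()) for d in dup_dates))[0]
    return ValueError(f"{path}: duplicated week {first}")


def _read_aggregated(df: pd.DataFrame, path) -> SearchSeries:
    dates = _parse_dates(df["week_start_date"], path)
    if dates.duplicated().any():
        raise _duplicate_error(path, dates[dates.duplicated()])
    order = np.argsort(dates.asi8)
    return SearchSeries(
        week_start=dates[order],
        aggregated=df["value"].to_numpy(dtype=float)[order],
        aggregator="mean",
    )


def _read_long(df: pd.DataFrame, path) -> SearchSeries:
    df = df.copy()
    df["week_start_date"] = _parse_dates(df["week_start_date"], path)
    dup = df.duplicated(subset=["week_start_date", "replicate_id"])
    if dup.any():
        raise _duplicate_error(path, df.loc[dup, "week_start_date"])
    wide = df.pivot(index="week_start_date", columns="replicate_id", values="value")
    wide = wide.sort_index().reindex(sorted(wide.columns), axis=1)
    return SearchSeries(
        week_start=pd.DatetimeIndex(wide.index),
        replicates=wide.to_numpy(dtype=float),
    )


def write_series_csv(series: SearchSeries, path, fmt: str = "auto") -> None:
    """Write a series as CSV; ``fmt`` is "long", "aggregated" or "auto"
    (long when replicates are present)."""
    if fmt == "auto":
        fmt = "long" if series.replicates is not None else "aggregated"
    dates = series.week_start.strftime("%Y-%m-%d")
    if fmt == "long":
        if series.replicates is None:
            raise ValueError("series has no replicates to write in long format")
        n_weeks, n_reps = series.replicates.shape
        out = pd.DataFrame(
            {
                "week_start_date": np.repeat(dates, n_reps),
                "replicate_id": np.tile(np.arange(n_reps), n_weeks),
                "value": series.replicates.ravel(),
            }
        )
    elif fmt == "aggregated":
        if series.aggregated is None:
            raise ValueError("series has no aggregated values to write")
        out = pd.DataFrame({"week_start_date": dates, "value": series.aggregated})
    else:
        raise ValueError(f"unknown format {fmt!r}")
    out.to_csv(path, index=False)


def fetch_search_volumes(terms, geo, start_date, end_date, n_samples=10):
    """Interface stub for a live search-volume API client (not implemented).

    A real client would return, per sample draw, weekly probabilities of the
    search terms scaled by 1e7 — i.e. a long-format table with columns
    ``week_start_date`` (Sunday-start ISO dates), ``replicate_id`` and
    ``value`` — which :func:`read_series_csv` already consumes. Querying the
    API requires a key and is deliberately out of scope here.
    """
    raise NotImplementedError(
        "live search-volume querying is out of scope; load a CSV in the "
        "documented schema instead"
    )
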