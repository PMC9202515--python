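"""Classify target-year weeks against the prediction band and summarize
exceedances.

A week is "above" when its observed value lies strictly above the upper
bound, "below" when strictly below the lower bound (ties count as within),
"missing" when the observation is suppressed. Under a correctly calibrated
95% band roughly 5% of null weeks (2-3 of 52) fall outside; more than that,
and especially above-weeks arriving in serial runs, is the excess signal the
pipeline looks for.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .prediction import PredictionBand
from .series import SearchSeries

__all__ = ["ExcessReport", "classify_weeks", "detect_runs", "exceedance_vs_null"]


def detect_runs(flags, dates=None) -> list[tuple]:
    """Maximal runs of consecutive "above" flags, as (start, length) pairs.

    Singleton runs are allowed; any non-above flag (including missing)
    breaks a run. ``dates`` defaults to 0-based positions.
    """
    flags = list(flags)
    if dates is None:
        dates = list(range(len(flags)))
    else:
        dates = list(pd.DatetimeIndex(dates))
    if len(dates) != len(flags):
        raise ValueError("flags and dates must align")
    runs: list[tuple] = []
    start, length = None, 0
    for flag, date in zip(flags, dates):
        if flag == "above":
            if start is None:
                start, length = date, 1
            else:
                length += 1
        elif start is not None:
            runs.append((start, length))
            start, length = None, 0
    if start is not None:
        runs.append((start, length))
    return runs


@dataclass
class ExcessReport:
    """Per-week flags plus exceedance totals, runs, and first-excess timing."""

    week_start: pd.DatetimeIndex
    flags: list[str]
    level: float
    runs: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.week_start = pd.DatetimeIndex(self.week_start)
        allowed = {"above", "within", "below", "missing"}
        if set(self.flags) - allowed:
            raise ValueError(f"flags must be in {allowed}")
        if len(self.flags) != len(self.week_start):
            raise ValueError("flags and week_start must align")
        self.runs = detect_runs(self.flags, self.week_start)

    # -- totals -----------------------------------------------------------
    @property
    def n_weeks(self) -> int:
        return len(self.flags)

    def _count(self, kind: str) -> int:
        return sum(f == kind for f in self.flags)

    @property
    def n_above(self) -> int:
        return self._count("above")

    @property
    def n_below(self) -> int:
        return self._count("below")

    @property
    def n_within(self) -> int:
        return self._count("within")

    @property
    def n_missing(self) -> int:
        return self._count("missing")

    @property
    def n_outside(self) -> int:
        return self.n_above + self.n_below

    @property
    def n_observed(self) -> int:
        return self.n_weeks - self.n_missing

    @property
    def fraction_outside(self) -> float:
        return self.n_outside / self.n_observed if self.n_observed else math.nan

    @property
    def expected_fraction(self) -> float:
        return 1.0 - self.level

    @property
    def first_above_date(self):
        for flag, date in zip(self.flags, self.week_start):
            if flag == "above":
                return date
        return None

    def first_above_on_or_after(self, date):
        """First above-flagged week starting on or after ``date`` (detection
        delay anchor for an excess with a known onset)."""
        date = pd.Timestamp(date)
        for flag, d in zip(self.flags, self.week_start):
            if flag == "above" and d >= date:
                return d
        return None

    # -- export -----------------------------------------------------------
    def to_dict(self) -> dict:
        first = self.first_above_date
        return {
            "level": self.level,
            "n_weeks": self.n_weeks,
            "n_above": self.n_above,
            "n_below": self.n_below,
            "n_within": self.n_within,
            "n_missing": self.n_missing,
            "n_outside": self.n_outside,
            "fraction_outside": self.fraction_outside,
            "expected_fraction": self.expected_fraction,
            "first_above_date": None if first is None else str(first.date()),
            "runs": [
                {"start_date": str(pd.Timestamp(s).date()), "length": n}
                for s, n in self.runs
            ],
            "weeks": [
                {"week_start_date": str(d.date()), "flag": f}
                for d, f in zip(self.week_start, self.flags)
            ],
            "summary": exceedance_vs_null(self),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def flags_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week_start_date": self.week_start.strftime("%Y-%m-%d"),
                "flag": self.flags,
            }
        )

    def to_text(self) -> str:
        s = self.to_dict()
        lines = [
            f"weeks: {s['n_weeks']}  (missing {s['n_missing']})",
            f"above: {s['n_above']}   below: {s['n_below']}   within: {s['n_within']}",
            f"outside: {s['n_outside']} "
            f"({100 * s['fraction_outside']:.1f}% vs {100 * s['expected_fraction']:.1f}% expected)",
            f"notable: {s['summary']['notable']}",
            f"first above week: {s['first_above_date']}",
            "above-runs: "
            + (
                ", ".join(f"{r['start_date']} x{r['length']}" for r in s["runs"])
                or "none"
            ),
        ]
        return "\n".join(lines)


def classify_weeks(observed: SearchSeries, band: PredictionBand) -> ExcessReport:
    """Flag each observed week against the prediction band.

    The observed series and the band must cover the identical week grid.
    Strict inequalities at the bounds: a value equal to a bound is within.
    """
    if observed.aggregated is None:
        raise ValueError("observed series must be aggregated")
    if len(observed.week_start) != len(band.week_start) or not (
        observed.week_start == band.week_start
    ).all():
        raise ValueError("observed series and band cover different week grids")
    flags: list[str] = []
    for y, lo, hi in zip(observed.aggregated, band.lower, band.upper):
        if np.isnan(y):
            flags.append("missing")
        elif y > hi:
            flags.append("above")
        elif y < lo:
            flags.append("below")
        else:
            flags.append("within")
    return ExcessReport(week_start=observed.week_start, flags=flags, level=band.level)


def exceedance_vs_null(report: ExcessReport) -> dict:
    """Compare the outside count with its null expectation.

    "Notable" means the outside fraction exceeds 1 - level and the outside
    count exceeds the integer ceiling of the expected count. The binomial
    tail probability P(X >= n_outside) under X ~ Bin(n_observed, 1 - level)
    is descriptive context only, never a decision gate, since weekly
    residuals need not be independent.
    """
    if report.n_observed < 1:
        raise ValueError("report has no non-missing weeks")
    n = report.n_observed
    expected_count = report.expected_fraction * n
    notable = (
        report.fraction_outside > report.expected_fraction
        and report.n_outside > math.ceil(expected_count)
    )
    tail = float(stats.binom.sf(report.n_outside - 1, n, report.expected_fraction))
    return {
        "n_observed": n,
        "n_outside": report.n_outside,
        "fraction_outside": report.fraction_outside,
        "expected_fraction": report.expected_fraction,
        "expected_count": expected_count,
        "notable": bool(notable),
        "binomial_tail_probability": tail,
    }
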