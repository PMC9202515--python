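"""Synthetic weekly search-volume generator.

Emulates the statistical structure of Google Health Trends output so that the
baseline-fit / prediction-interval / excess-detection chain can be exercised
without any API access: a weekly mean curve (level + mild secular trend + a
single-cosine seasonal cycle), a week-level Gaussian deviation shared by all
replicate samples of that week, independent replicate-level Gaussian noise,
optional suppression of small values, and an optional injected excess that
starts at a configurable calendar date.

The seasonal cycle is a cosine peaked at ``seasonal_peak_week`` with its
trough half a cycle (26 weeks) away; real search seasonality need not be
antipodal like that, so presets match the documented peak month and accept an
approximate trough.

Randomness is split into one substream per week (``SeedSequence.spawn``), and
within a week the shared deviation is drawn before the replicate deviations,
so changing ``n_replicates`` never perturbs the week-level noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .series import SearchSeries, aggregate_replicates, sunday_week_grid, week_of_year

__all__ = [
    "GeneratorParams",
    "ExcessSpec",
    "PRESETS",
    "generate_series",
    "mean_curve",
    "aggregate_replicates",
]

_EXCESS_SHAPES = ("step", "linear-ramp", "exponential-decay")


@dataclass(frozen=True)
class ExcessSpec:
    """An excess (or deficit) injected into the weekly mean curve.

    ``magnitude`` is in search-volume units and may be negative. Shapes:

    - ``step``: constant ``magnitude`` from ``start_date`` for
      ``duration_weeks`` weeks (open-ended if ``duration_weeks`` is None);
    - ``linear-ramp``: rises linearly from 0 at ``start_date`` to
      ``magnitude`` after ``duration_weeks`` weeks, then stays there;
    - ``exponential-decay``: ``magnitude`` at onset, decaying with e-folding
      time ``duration_weeks``.
    """

    start_date: pd.Timestamp
    magnitude: float
    shape: str = "step"
    duration_weeks: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_date", pd.Timestamp(self.start_date))
        if self.shape not in _EXCESS_SHAPES:
            raise ValueError(f"shape must be one of {_EXCESS_SHAPES}")
        if not math.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if self.shape == "linear-ramp" and self.duration_weeks is None:
            raise ValueError("linear-ramp needs duration_weeks")
        if self.shape == "exponential-decay" and self.duration_weeks is None:
            raise ValueError("exponential-decay needs duration_weeks (e-folding time)")
        if self.duration_weeks is not None and self.duration_weeks <= 0:
            raise ValueError("duration_weeks must be positive")

    def contribution(self, week_start: pd.DatetimeIndex) -> np.ndarray:
        """Additive excess contribution for each week-start date."""
        dt_weeks = (pd.DatetimeIndex(week_start) - self.start_date).days / 7.0
        out = np.zeros(len(dt_weeks))
        active = dt_weeks >= 0
        if self.shape == "step":
            if self.duration_weeks is not None:
                active &= dt_weeks < self.duration_weeks
            out[active] = self.magnitude
        elif self.shape == "linear-ramp":
            frac = np.minimum(dt_weeks / self.duration_weeks, 1.0)
            out[active] = self.magnitude * frac[active]
        else:  # exponential-decay
            out[active] = self.magnitude * np.exp(-dt_weeks[active] / self.duration_weeks)
        return out

    def to_dict(self) -> dict:
        return {
            "start_date": str(self.start_date.date()),
            "magnitude": self.magnitude,
            "shape": self.shape,
            "duration_weeks": self.duration_weeks,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExcessSpec":
        return cls(**d)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic weekly generator.

    All volumes are in relative-search-volume units (probability x 1e7).
    ``trend_slope`` is per year; ``seasonal_peak_week`` is a week of year in
    [1, 52]. ``suppression_threshold`` emulates the API's withholding of
    small values: anything strictly below it is emitted as missing (default 0,
    i.e. suppression effectively off for realistic magnitudes).
    """

    baseline_mean: float = 82.6
    trend_slope: float = 0.0
    seasonal_amplitude: float = 0.0
    seasonal_peak_week: float = 23.0
    week_noise_sd: float = 0.0
    replicate_noise_sd: float = 0.0
    n_replicates: int = 10
    start_date: pd.Timestamp = pd.Timestamp("2017-01-01")
    end_date: pd.Timestamp = pd.Timestamp("2020-12-31")
    suppression_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_date", pd.Timestamp(self.start_date))
        object.__setattr__(self, "end_date", pd.Timestamp(self.end_date))
        for name in (
            "baseline_mean",
            "trend_slope",
            "seasonal_amplitude",
            "seasonal_peak_week",
            "week_noise_sd",
            "replicate_noise_sd",
            "suppression_threshold",
        ):
            if not math.isfinite(float(getattr(self, name))):
                raise ValueError(f"{name} must be finite")
        if self.week_noise_sd < 0 or self.replicate_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.start_date >= self.end_date:
            raise ValueError("start_date must precede end_date")
        if not 1.0 <= self.seasonal_peak_week <= 52.0:
            raise ValueError("seasonal_peak_week must lie in [1, 52]")

    def replace(self, **kw) -> "GeneratorParams":
        return _dc_replace(self, **kw)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "baseline_mean",
                "trend_slope",
                "seasonal_amplitude",
                "seasonal_peak_week",
                "week_noise_sd",
                "replicate_noise_sd",
                "n_replicates",
                "suppression_threshold",
                "seed",
            )
        }
        d["start_date"] = str(self.start_date.date())
        d["end_date"] = str(self.end_date.date())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        return cls(**d)


#: Per-outcome generator defaults. Levels and year-to-year drifts follow the
#: observed yearly means/SDs of the three violence-related search outcomes;
#: seasonal amplitudes are set so the systematic (trend + seasonal) share of
#: the aggregated weekly variance, A^2/2 / (A^2/2 + sd_w^2 + sd_r^2/n),
#: roughly matches the adjusted R^2 each baseline model attains on the real
#: series (~15%, ~11%, ~2%). Peak weeks follow the documented peak months
#: (June for child abuse, December for child-witnessed IPV).
PRESETS: dict[str, GeneratorParams] = {
    "child_abuse": GeneratorParams(
        baseline_mean=82.6,
        trend_slope=-0.6,
        seasonal_amplitude=4.0,
        seasonal_peak_week=23.0,
        week_noise_sd=6.5,
        replicate_noise_sd=2.0,
    ),
    "child_witnessed_ipv": GeneratorParams(
        baseline_mean=59.0,
        trend_slope=-0.85,
        seasonal_amplitude=3.2,
        seasonal_peak_week=50.0,
        week_noise_sd=6.2,
        replicate_noise_sd=2.0,
    ),
    "ipv": GeneratorParams(
        baseline_mean=82.8,
        trend_slope=0.0,
        seasonal_amplitude=1.3,
        seasonal_peak_week=22.0,
        week_noise_sd=6.5,
        replicate_noise_sd=2.0,
    ),
}


def mean_curve(params: GeneratorParams, week_start: pd.DatetimeIndex,
               excess: ExcessSpec | None = None) -> np.ndarray:
    """Noise-free weekly mean: level + linear trend + cosine seasonality
    + any injected excess."""
    week_start = pd.DatetimeIndex(week_start)
    years = (week_start - params.start_date).days / 365.25
    woy = week_of_year(week_start)
    mu = (
        params.baseline_mean
        + params.trend_slope * years
        + params.seasonal_amplitude
        * np.cos(2.0 * np.pi * (woy - params.seasonal_peak_week) / 52.0)
    )
    if excess is not None:
        mu = mu + excess.contribution(week_start)
    return mu


def generate_series(params: GeneratorParams,
                    excess: ExcessSpec | None = None) -> SearchSeries:
    """Draw one synthetic replicate-level weekly series.

    Each week w has mean mu_w from :func:`mean_curve`; observed replicates are
    mu_w + d_w + e_{w,r} with d_w ~ N(0, week_noise_sd^2) shared across
    replicates and e_{w,r} ~ N(0, replicate_noise_sd^2) independent. Values
    strictly below ``suppression_threshold`` become NaN. Output is
    bit-identical for identical (params, excess).
    """
    grid = sunday_week_grid(params.start_date, params.end_date)
    if excess is not None and not (
        params.start_date <= excess.start_date <= params.end_date
    ):
        raise ValueError("excess start_date falls outside the series window")
    mu = mean_curve(params, grid, excess)

    n_weeks, n_reps = len(grid), params.n_replicates
    values = np.empty((n_weeks, n_reps))
    children = np.random.SeedSequence(params.seed).spawn(n_weeks)
    for w, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        week_dev = rng.normal(0.0, params.week_noise_sd)
        rep_dev = rng.normal(0.0, params.replicate_noise_sd, n_reps)
        values[w] = mu[w] + week_dev + rep_dev
    values[values < params.suppression_threshold] = np.nan
    # relative search volumes are probabilities: never negative
    np.clip(values, 0.0, None, out=values)

    series = SearchSeries(week_start=grid, replicates=values)
    return aggregate_replicates(series, "mean")
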