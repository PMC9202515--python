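"""Out-of-sample prediction intervals for a fitted seasonal baseline.

For a target week with design row x0 the point prediction is x0'beta and the
two-sided prediction interval at level 1 - alpha is

    x0'beta +/- t_{1-alpha/2, df} * s * sqrt(1 + x0' (X'X)^{-1} x0),

the interval expected to contain an individual future observation (not its
mean): the leading 1 under the square root carries the observation noise and
the leverage term x0'(X'X)^{-1}x0 the estimation uncertainty, which grows as
the target date moves away from the training window. Student-t quantiles are
used because the residual variance is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .baseline import FittedBaseline

__all__ = ["PredictionBand", "predict_band"]


@dataclass
class PredictionBand:
    """Per-week point predictions with symmetric prediction-interval bounds."""

    week_start: pd.DatetimeIndex
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95

    def __post_init__(self) -> None:
        self.week_start = pd.DatetimeIndex(self.week_start)
        self.point = np.asarray(self.point, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        n = len(self.week_start)
        if not (self.point.shape == self.lower.shape == self.upper.shape == (n,)):
            raise ValueError("point/lower/upper must align with week_start")
        if np.any(self.lower > self.point) or np.any(self.point > self.upper):
            raise ValueError("band must satisfy lower <= point <= upper")

    @property
    def half_width(self) -> np.ndarray:
        return (self.upper - self.lower) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week_start_date": self.week_start.strftime("%Y-%m-%d"),
                "point": self.point,
                "lower": self.lower,
                "upper": self.upper,
                "level": self.level,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PredictionBand":
        df = pd.read_csv(path)
        need = {"week_start_date", "point", "lower", "upper", "level"}
        if not need.issubset(df.columns):
            raise ValueError(f"band CSV {path} missing columns {sorted(need - set(df.columns))}")
        return cls(
            week_start=pd.DatetimeIndex(pd.to_datetime(df["week_start_date"])),
            point=df["point"].to_numpy(),
            lower=df["lower"].to_numpy(),
            upper=df["upper"].to_numpy(),
            level=float(df["level"].iloc[0]),
        )


def predict_band(
    fit: FittedBaseline, target_weeks, level: float = 0.95
) -> PredictionBand:
    """Point predictions and prediction intervals for the given week dates.

    Target design rows are built with the same knots and date origin as the
    training design, so extrapolating beyond the training window is exactly
    the intended use.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if fit.residual_df <= 0:
        raise ValueError("fit has no residual degrees of freedom")
    dates = pd.DatetimeIndex(target_weeks)
    X0 = fit.design_for(dates)
    point = X0 @ fit.coefficients
    leverage = np.einsum("ij,jk,ik->i", X0, fit.xtx_inverse, X0)
    tcrit = stats.t.ppf(1.0 - (1.0 - level) / 2.0, fit.residual_df)
    half = tcrit * np.sqrt(fit.residual_variance * (1.0 + leverage))
    return PredictionBand(
        week_start=dates, point=point, lower=point - half, upper=point + half,
        level=level,
    )
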