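"""Prepandemic seasonal baseline: OLS on a linear date trend plus a
restricted-cubic-spline expansion of week of year.

The model for the aggregated weekly volume y_w is

    y_w = b0 + b1 * (date_w - origin)/year + spline(week_of_year_w) + e_w

fit by ordinary least squares on the training window. The fit stores
everything needed to form out-of-sample prediction intervals without the
training data: coefficients, residual variance s^2 = RSS/(n-p), residual
degrees of freedom, (X'X)^{-1}, the knots, and the date origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .series import SearchSeries, week_of_year
from .splines import KnotSet, knots_from_percentiles, rcs_design

__all__ = [
    "FittedBaseline",
    "design_matrix",
    "build_design",
    "fit_ols",
    "fit_baseline",
    "residual_diagnostics",
]

DEFAULT_PERCENTILES = (10.0, 50.0, 90.0)


def design_matrix(dates, knots: KnotSet, date_origin) -> np.ndarray:
    """Design rows [1, years since origin, RCS(week of year)] for any dates.

    Used identically for training and prediction so that target rows are
    built with the same knots and origin as the fit.
    """
    dates = pd.DatetimeIndex(dates)
    years = np.asarray((dates - pd.Timestamp(date_origin)).days, dtype=float) / 365.25
    basis = rcs_design(week_of_year(dates), knots)
    return np.column_stack([np.ones(len(dates)), years, basis])


def build_design(
    series: SearchSeries, knots: KnotSet, date_origin=None
) -> tuple[np.ndarray, np.ndarray, pd.DatetimeIndex]:
    """Design matrix and response for the non-missing weeks of a series.

    Returns (X, y, dates); suppressed weeks are dropped, not imputed.
    """
    if series.aggregated is None:
        raise ValueError("series must be aggregated before fitting")
    mask = ~np.isnan(series.aggregated)
    if not mask.any():
        raise ValueError("all weeks are missing")
    dates = series.week_start[mask]
    if date_origin is None:
        date_origin = dates[0]
    X = design_matrix(dates, knots, date_origin)
    return X, series.aggregated[mask], dates


@dataclass
class FittedBaseline:
    """A fitted seasonal baseline, sufficient for prediction intervals."""

    coefficients: np.ndarray
    residual_variance: float
    residual_df: int
    xtx_inverse: np.ndarray
    adjusted_r2: float
    n_train: int
    knots: KnotSet
    date_origin: pd.Timestamp
    training_window: tuple[pd.Timestamp, pd.Timestamp]
    column_names: tuple[str, ...]
    date_unit: str = "years"

    def design_for(self, dates) -> np.ndarray:
        return design_matrix(dates, self.knots, self.date_origin)

    def predict_mean(self, dates) -> np.ndarray:
        return self.design_for(dates) @ self.coefficients

    # -- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "coefficients": [float(c) for c in self.coefficients],
            "column_names": list(self.column_names),
            "date_unit": self.date_unit,
            "residual_variance": float(self.residual_variance),
            "residual_df": int(self.residual_df),
            "xtx_inverse": [[float(v) for v in row] for row in self.xtx_inverse],
            "adjusted_r2": float(self.adjusted_r2),
            "n_train": int(self.n_train),
            "knots": self.knots.to_dict(),
            "date_origin": str(self.date_origin.date()),
            "training_window": [
                str(self.training_window[0].date()),
                str(self.training_window[1].date()),
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedBaseline":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            residual_variance=float(d["residual_variance"]),
            residual_df=int(d["residual_df"]),
            xtx_inverse=np.asarray(d["xtx_inverse"], dtype=float),
            adjusted_r2=float(d["adjusted_r2"]),
            n_train=int(d["n_train"]),
            knots=KnotSet.from_dict(d["knots"]),
            date_origin=pd.Timestamp(d["date_origin"]),
            training_window=(
                pd.Timestamp(d["training_window"][0]),
                pd.Timestamp(d["training_window"][1]),
            ),
            column_names=tuple(d["column_names"]),
            date_unit=d.get("date_unit", "years"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))

    @classmethod
    def load(cls, path) -> "FittedBaseline":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    *,
    knots: KnotSet,
    date_origin,
    training_window,
    column_names=None,
) -> FittedBaseline:
    """Ordinary-least-squares fit of the baseline design.

    Thin wrapper over statsmodels OLS; raises on rank-deficient designs or
    when fewer than p + 2 rows are available.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows to fit {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss > 1e-12 * max(1.0, float(y @ y)):
        adjusted_r2 = float(res.rsquared_adj)
    else:
        # constant response: R^2 is undefined; report 1 for a perfect fit
        adjusted_r2 = 1.0 if res.ssr <= 1e-12 * max(1.0, tss) else 0.0
    if column_names is None:
        column_names = ["intercept", "years_since_origin"] + [
            f"rcs_{i}" for i in range(p - 2)
        ]
    return FittedBaseline(
        coefficients=np.asarray(res.params, dtype=float),
        residual_variance=float(res.scale),
        residual_df=int(res.df_resid),
        xtx_inverse=np.asarray(res.normalized_cov_params, dtype=float),
        adjusted_r2=adjusted_r2,
        n_train=n,
        knots=knots,
        date_origin=pd.Timestamp(date_origin),
        training_window=(
            pd.Timestamp(training_window[0]),
            pd.Timestamp(training_window[1]),
        ),
        column_names=tuple(column_names),
    )


def fit_baseline(
    series: SearchSeries,
    percentiles=DEFAULT_PERCENTILES,
    date_origin=None,
) -> FittedBaseline:
    """Fit the full baseline to an aggregated training series.

    Knots are placed at the given percentiles of the observed week-of-year
    values; the date origin defaults to the first non-missing training week.
    """
    if series.aggregated is None:
        raise ValueError("series must be aggregated before fitting")
    mask = ~np.isnan(series.aggregated)
    if not mask.any():
        raise ValueError("all weeks are missing")
    knots = knots_from_percentiles(week_of_year(series.week_start[mask]), percentiles)
    X, y, dates = build_design(series, knots, date_origin)
    return fit_ols(
        X,
        y,
        knots=knots,
        date_origin=dates[0] if date_origin is None else date_origin,
        training_window=(dates[0], dates[-1]),
    )


def residual_diagnostics(fit: FittedBaseline, X: np.ndarray, y: np.ndarray) -> dict:
    """Summary statistics of the training residuals.

    Reports mean, skewness, excess kurtosis, lag-1 autocorrelation and the
    D'Agostino-Pearson normality statistic, with soft flags (|skewness| > 1,
    |lag-1 autocorrelation| > 0.3). Purely descriptive — never alters the
    fit, which stays plain OLS regardless of what the diagnostics show.
    """
    resid = np.asarray(y, dtype=float) - np.asarray(X, dtype=float) @ fit.coefficients
    out: dict = {"n": int(resid.size), "mean": float(np.mean(resid))}
    degenerate = float(np.var(resid)) < 1e-12
    out["degenerate"] = degenerate
    if degenerate:
        out.update(
            skewness=0.0,
            excess_kurtosis=0.0,
            lag1_autocorrelation=0.0,
            normality_statistic=0.0,
            normality_pvalue=1.0,
        )
    else:
        out["skewness"] = float(stats.skew(resid))
        out["excess_kurtosis"] = float(stats.kurtosis(resid))
        out["lag1_autocorrelation"] = float(
            np.corrcoef(resid[:-1], resid[1:])[0, 1]
        )
        k2, pval = stats.normaltest(resid)
        out["normality_statistic"] = float(k2)
        out["normality_pvalue"] = float(pval)
    out["flags"] = {
        "degenerate": degenerate,
        "skewed": (not degenerate) and abs(out["skewness"]) > 1.0,
        "autocorrelated": (not degenerate)
        and abs(out["lag1_autocorrelation"]) > 0.3,
    }
    return out
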