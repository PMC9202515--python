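"""Restricted cubic spline (natural cubic spline) basis on week of year.

Uses the truncated-power parameterization popularized by Harrell: for knots
t_1 < ... < t_k the basis has k-1 columns — the identity x plus, for
j = 1..k-2,

    B_j(x) = [ (x-t_j)_+^3
               - (x-t_{k-1})_+^3 (t_k - t_j)/(t_k - t_{k-1})
               + (x-t_k)_+^3   (t_{k-1} - t_j)/(t_k - t_{k-1}) ]
             / (t_k - t_1)^2 ,

which is C^2 everywhere and exactly linear outside [t_1, t_k]. Any
rank-equivalent natural-spline basis spans the same function space, so
downstream fitted values and prediction intervals do not depend on this
choice of parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KnotSet", "knots_from_percentiles", "rcs_design"]


@dataclass(frozen=True)
class KnotSet:
    """Ordered spline knot locations (week-of-year units)."""

    knots: tuple[float, ...]
    source_percentiles: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "knots", tuple(float(t) for t in self.knots))
        if len(self.knots) < 1:
            raise ValueError("need at least one knot")
        if any(b <= a for a, b in zip(self.knots, self.knots[1:])):
            raise ValueError("knots must be strictly increasing")
        if not np.all(np.isfinite(self.knots)):
            raise ValueError("knots must be finite")

    def __len__(self) -> int:
        return len(self.knots)

    def to_dict(self) -> dict:
        return {
            "knots": list(self.knots),
            "source_percentiles": None
            if self.source_percentiles is None
            else list(self.source_percentiles),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KnotSet":
        sp = d.get("source_percentiles")
        return cls(tuple(d["knots"]), None if sp is None else tuple(sp))


def knots_from_percentiles(
    week_values, percentiles=(10.0, 50.0, 90.0)
) -> KnotSet:
    """Knots at empirical percentiles of the observed week-of-year values.

    Quantiles use linear interpolation between order statistics (the default
    definition in numpy and R's ``quantile(type=7)``). Requires at least 10
    distinct week values; raises if two requested percentiles land on the
    same value.
    """
    v = np.asarray(week_values, dtype=float)
    if v.ndim != 1 or not np.all(np.isfinite(v)):
        raise ValueError("week_values must be a finite 1-d vector")
    if np.unique(v).size < 10:
        raise ValueError("need at least 10 distinct week-of-year values")
    p = tuple(float(q) for q in percentiles)
    if len(p) == 0:
        raise ValueError("need at least one percentile")
    if any(not 0.0 < q < 100.0 for q in p):
        raise ValueError("percentiles must lie strictly inside (0, 100)")
    if any(b <= a for a, b in zip(p, p[1:])):
        raise ValueError("percentiles must be strictly increasing")
    knots = np.percentile(v, p, method="linear")
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            f"percentiles {p} give coincident knots {tuple(knots)}"
        )
    return KnotSet(tuple(knots), p)


def rcs_design(x, knots: KnotSet) -> np.ndarray:
    """Evaluate the k-1 restricted-cubic-spline basis columns at x.

    Column 0 is x itself; columns 1..k-2 are the normalized truncated-cubic
    combinations above. Requires at least 3 knots.
    """
    if len(knots) < 3:
        raise ValueError("restricted cubic spline needs at least 3 knots")
    t = np.asarray(knots.knots, dtype=float)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    norm = (t[-1] - t[0]) ** 2

    def cube(u: np.ndarray) -> np.ndarray:
        return np.where(u > 0.0, u, 0.0) ** 3

    cols = [x]
    for j in range(len(t) - 2):
        col = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(col / norm)
    return np.column_stack(cols)
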