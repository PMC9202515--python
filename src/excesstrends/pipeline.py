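"""Config-driven end-to-end pipeline and annotated plotting.

``run_pipeline`` ties the stages together: obtain a weekly series (from a
CSV or the synthetic generator), aggregate replicates, fit the seasonal OLS
baseline on the training window, predict the target window with prediction
intervals, classify exceedance weeks, and write every artifact (series CSV,
model JSON, band CSV, flags CSV, report JSON, annotated plot) to an output
directory. Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .baseline import DEFAULT_PERCENTILES, FittedBaseline, fit_baseline
from .detection import ExcessReport, classify_weeks
from .io import read_series_csv, write_series_csv
from .prediction import PredictionBand, predict_band
from .series import SearchSeries, aggregate_replicates
from .synthetic import PRESETS, ExcessSpec, GeneratorParams, generate_series

__all__ = [
    "PolicyEvent",
    "DEFAULT_POLICY_EVENTS",
    "PipelineConfig",
    "run_pipeline",
    "plot_band",
]

log = logging.getLogger("excesstrends")


@dataclass(frozen=True)
class PolicyEvent:
    """A dated policy marker drawn on plots; never enters any computation."""

    name: str
    date: pd.Timestamp
    kind: str = "onset"  # onset | payment | expiry

    def __post_init__(self) -> None:
        object.__setattr__(self, "date", pd.Timestamp(self.date))
        if self.kind not in ("onset", "payment", "expiry"):
            raise ValueError("kind must be onset, payment or expiry")


#: The three 2020 US policy dates annotated on the published figures:
#: state shelter-in-place orders beginning, one-time Economic Impact
#: Payments largely delivered, and Pandemic Unemployment Compensation
#: (+$600/week) expiring.
DEFAULT_POLICY_EVENTS: tuple[PolicyEvent, ...] = (
    PolicyEvent("SIP", "2020-03-19", "onset"),
    PolicyEvent("EIP", "2020-04-17", "payment"),
    PolicyEvent("PUC end", "2020-07-31", "expiry"),
)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; JSON-serializable."""

    train_start: pd.Timestamp = pd.Timestamp("2017-01-01")
    train_end: pd.Timestamp = pd.Timestamp("2019-12-31")
    target_start: pd.Timestamp = pd.Timestamp("2020-01-01")
    target_end: pd.Timestamp = pd.Timestamp("2020-12-31")
    input_csv: str | None = None
    preset: str | None = "child_abuse"
    generator: GeneratorParams | None = None
    excess: ExcessSpec | None = None
    percentiles: tuple = DEFAULT_PERCENTILES
    level: float = 0.95
    aggregator: str = "mean"
    seed: int = 0
    policy_events: tuple = DEFAULT_POLICY_EVENTS

    def __post_init__(self) -> None:
        for name in ("train_start", "train_end", "target_start", "target_end"):
            setattr(self, name, pd.Timestamp(getattr(self, name)))
        if not self.train_start < self.train_end:
            raise ValueError("training window is empty")
        if not self.target_start < self.target_end:
            raise ValueError("target window is empty")
        if self.target_start <= self.train_end:
            raise ValueError("target window must follow the training window")
        if self.input_csv is None and self.preset is None and self.generator is None:
            raise ValueError("config needs an input_csv, a preset or generator params")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}"
            )

    # -- JSON round trip --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "train_start": str(self.train_start.date()),
            "train_end": str(self.train_end.date()),
            "target_start": str(self.target_start.date()),
            "target_end": str(self.target_end.date()),
            "input_csv": self.input_csv,
            "preset": self.preset,
            "generator": None if self.generator is None else self.generator.to_dict(),
            "excess": None if self.excess is None else self.excess.to_dict(),
            "percentiles": list(self.percentiles),
            "level": self.level,
            "aggregator": self.aggregator,
            "seed": self.seed,
            "policy_events": [
                {"name": e.name, "date": str(e.date.date()), "kind": e.kind}
                for e in self.policy_events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = GeneratorParams.from_dict(d["generator"])
        if d.get("excess") is not None:
            d["excess"] = ExcessSpec.from_dict(d["excess"])
        if d.get("percentiles") is not None:
            d["percentiles"] = tuple(d["percentiles"])
        if d.get("policy_events") is not None:
            d["policy_events"] = tuple(
                PolicyEvent(e["name"], e["date"], e.get("kind", "onset"))
                for e in d["policy_events"]
            )
        return cls(**{k: v for k, v in d.items() if v is not None or k in ("input_csv", "preset")})

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def resolve_series(self) -> SearchSeries:
        """Load or generate the full (train + target) weekly series."""
        if self.input_csv is not None:
            series = read_series_csv(self.input_csv)
        else:
            params = self.generator if self.generator is not None else PRESETS[self.preset]
            params = params.replace(
                seed=self.seed,
                start_date=self.train_start,
                end_date=self.target_end,
            )
            series = generate_series(params, self.excess)
        if series.replicates is not None:
            series = aggregate_replicates(series, self.aggregator)
        return series


def run_pipeline(config: PipelineConfig, outdir=None):
    """Run all stages; optionally write artifacts under ``outdir``.

    Returns (fit, band, report). With ``outdir`` set, writes series.csv,
    model.json, band.csv, flags.csv, report.json and plot.png.
    """
    series = config.resolve_series()
    train = series.window(config.train_start, config.train_end)
    target = series.window(config.target_start, config.target_end)
    log.info("fitting baseline on %d training weeks", train.n_weeks)
    fit = fit_baseline(train, percentiles=config.percentiles)
    band = predict_band(fit, target.week_start, level=config.level)
    report = classify_weeks(target, band)
    log.info(
        "target weeks: %d, outside PI: %d (%.1f%%)",
        report.n_weeks,
        report.n_outside,
        100 * report.fraction_outside,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_series_csv(series, outdir / "series.csv", fmt="aggregated")
        fit.save(outdir / "model.json")
        band.to_csv(outdir / "band.csv")
        report.flags_frame().to_csv(outdir / "flags.csv", index=False)
        report.to_json(outdir / "report.json")
        plot_band(
            band,
            observed=series,
            fit=fit,
            events=config.policy_events,
            path=outdir / "plot.png",
        )
    return fit, band, report


def plot_band(
    band: PredictionBand,
    observed: SearchSeries | None = None,
    fit: FittedBaseline | None = None,
    events=(),
    path=None,
    ax=None,
):
    """Observed points, predicted curve, PI ribbon, and policy markers.

    With a fit supplied, the predicted curve is also drawn back over the
    observed (training) period; the ribbon covers only the band's weeks.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4.5))
    if observed is not None and observed.aggregated is not None:
        ax.plot(
            observed.week_start,
            observed.aggregated,
            ".",
            color="0.35",
            ms=4,
            label="observed weekly volume",
        )
        if fit is not None:
            ax.plot(
                observed.week_start,
                fit.predict_mean(observed.week_start),
                color="tab:blue",
                lw=1,
                alpha=0.6,
            )
    ax.plot(band.week_start, band.point, color="tab:blue", lw=1.5, label="predicted")
    ax.fill_between(
        band.week_start,
        band.lower,
        band.upper,
        color="tab:blue",
        alpha=0.2,
        label=f"{band.level:.0%} prediction interval",
    )
    for ev in events:
        ax.axvline(ev.date, color="tab:red", ls="--", lw=0.8)
        ax.annotate(
            ev.name,
            (ev.date, ax.get_ylim()[1]),
            rotation=90,
            va="top",
            ha="right",
            fontsize=8,
            color="tab:red",
        )
    ax.set_xlabel("week")
    ax.set_ylabel("relative search volume (prob. x 1e7)")
    ax.legend(loc="lower left", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
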