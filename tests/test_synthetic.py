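"""Generator: deterministic seeding, exact mean structure, noise anatomy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from excesstrends import (
    ExcessSpec,
    GeneratorParams,
    PRESETS,
    SearchSeries,
    aggregate_replicates,
    generate_series,
    mean_curve,
    sunday_week_grid,
)

NOISELESS = dict(week_noise_sd=0.0, replicate_noise_sd=0.0)


def test_week_grid_reproduces_training_and_target_counts():
    # Sunday-start weeks give 157 prepandemic weeks and 52 target weeks
    assert len(sunday_week_grid("2017-01-01", "2019-12-31")) == 157
    assert len(sunday_week_grid("2020-01-01", "2020-12-31")) == 52


def test_degenerate_noise_free_generator_is_constant():
    params = GeneratorParams(
        baseline_mean=85.0, trend_slope=0.0, seasonal_amplitude=0.0, **NOISELESS
    )
    series = generate_series(params)
    assert np.all(series.replicates == 85.0)
    assert np.all(series.aggregated == 85.0)


def test_noise_free_output_equals_closed_form_mean_curve():
    params = GeneratorParams(
        baseline_mean=80.0, trend_slope=-1.2, seasonal_amplitude=5.0,
        seasonal_peak_week=23.0, **NOISELESS,
    )
    series = generate_series(params)
    np.testing.assert_allclose(
        series.aggregated, mean_curve(params, series.week_start), rtol=0, atol=1e-12
    )


def test_seasonal_peak_lands_in_june_and_trough_half_cycle_away():
    params = GeneratorParams(
        baseline_mean=80.0, seasonal_amplitude=5.0, seasonal_peak_week=23.0,
        start_date="2018-01-01", end_date="2018-12-31", **NOISELESS,
    )
    series = generate_series(params)
    months = series.week_start.month
    assert months[np.argmax(series.aggregated)] == 6
    peak_woy = series.week_of_year[np.argmax(series.aggregated)]
    trough_woy = series.week_of_year[np.argmin(series.aggregated)]
    # cosine trough sits ~26 weeks (half a cycle) from the peak
    assert abs(abs(trough_woy - peak_woy) - 26.0) < 2.0


def test_fixed_seed_is_bit_identical_and_seeds_differ():
    params = PRESETS["child_abuse"].replace(seed=7)
    a, b = generate_series(params), generate_series(params)
    np.testing.assert_array_equal(a.replicates, b.replicates)
    np.testing.assert_array_equal(a.aggregated, b.aggregated)
    c = generate_series(params.replace(seed=8))
    assert not np.array_equal(a.replicates, c.replicates)


def test_adding_replicates_does_not_perturb_week_level_noise():
    base = GeneratorParams(week_noise_sd=4.0, replicate_noise_sd=1.5, n_replicates=5)
    more = base.replace(n_replicates=10)
    a, b = generate_series(base), generate_series(more)
    # per-week substreams: the first 5 replicate draws are unchanged
    np.testing.assert_array_equal(a.replicates, b.replicates[:, :5])


def test_aggregated_variance_decomposition():
    """Var(weekly mean) = week_sd^2 + rep_sd^2 / n within Monte-Carlo error."""
    params = GeneratorParams(
        week_noise_sd=5.0, replicate_noise_sd=2.0, n_replicates=10,
        start_date="2000-01-02", end_date="2019-02-24", seed=99,
    )
    series = generate_series(params)
    assert series.n_weeks == 1000
    noise = series.aggregated - mean_curve(params, series.week_start)
    expected = 5.0**2 + 2.0**2 / 10
    # sample variance of n iid terms has relative sd sqrt(2/n) ~ 4.5%
    assert np.var(noise, ddof=1) == pytest.approx(expected, rel=0.15)


def test_mean_and_median_aggregation_nearly_agree():
    params = GeneratorParams(
        week_noise_sd=5.0, replicate_noise_sd=2.0, n_replicates=10,
        start_date="2000-01-02", end_date="2019-02-24", seed=5,
    )
    series = generate_series(params)
    med = aggregate_replicates(series, "median")
    gap = np.abs(series.aggregated - med.aggregated)
    assert np.mean(gap) < params.replicate_noise_sd


@pytest.mark.parametrize(
    "shape,duration,checker",
    [
        ("step", None, lambda m, dt: np.full_like(dt, m)),
        ("step", 4, lambda m, dt: np.where(dt < 4, m, 0.0)),
        ("linear-ramp", 4, lambda m, dt: m * np.minimum(dt / 4.0, 1.0)),
        ("exponential-decay", 4, lambda m, dt: m * np.exp(-dt / 4.0)),
    ],
)
def test_injected_excess_shifts_noise_free_means_exactly(shape, duration, checker):
    params = GeneratorParams(seasonal_amplitude=2.0, **NOISELESS)
    start = "2020-03-22"
    excess = ExcessSpec(start, magnitude=9.0, shape=shape, duration_weeks=duration)
    base, bumped = generate_series(params), generate_series(params, excess)
    dt = (bumped.week_start - pd.Timestamp(start)).days / 7.0
    expected = np.where(dt >= 0, checker(9.0, dt), 0.0)
    np.testing.assert_allclose(
        bumped.aggregated - base.aggregated, expected, atol=1e-12
    )


def test_negative_magnitude_emulates_a_deficit():
    params = GeneratorParams(**NOISELESS)
    excess = ExcessSpec("2020-06-07", magnitude=-5.0)
    s = generate_series(params, excess)
    post = s.week_start >= pd.Timestamp("2020-06-07")
    assert np.all(s.aggregated[post] < s.aggregated[~post].min())


def test_suppression_threshold_turns_small_values_missing():
    params = GeneratorParams(
        baseline_mean=10.0, week_noise_sd=5.0, suppression_threshold=10.0, seed=3
    )
    series = generate_series(params)
    assert np.isnan(series.replicates).any()
    assert np.all(series.replicates[~np.isnan(series.replicates)] >= 10.0)
    # a fully-suppressed week stays missing after aggregation
    dead = np.isnan(series.replicates).all(axis=1)
    if dead.any():
        assert np.isnan(series.aggregated[dead]).all()


@pytest.mark.parametrize(
    "bad",
    [
        dict(week_noise_sd=-1.0),
        dict(n_replicates=0),
        dict(start_date="2020-01-01", end_date="2019-01-01"),
        dict(seasonal_peak_week=60.0),
        dict(baseline_mean=float("nan")),
    ],
)
def test_invalid_generator_params_rejected(bad):
    with pytest.raises(ValueError):
        GeneratorParams(**bad)


def test_excess_start_outside_series_rejected():
    with pytest.raises(ValueError, match="outside"):
        generate_series(GeneratorParams(), ExcessSpec("2025-01-01", 5.0))


def test_aggregation_examples_and_unknown_method():
    weeks = pd.DatetimeIndex(["2020-01-05"])
    s = SearchSeries(week_start=weeks, replicates=np.array([[10.0, 20.0, 30.0]]))
    assert aggregate_replicates(s, "mean").aggregated[0] == 20.0
    s2 = SearchSeries(week_start=weeks, replicates=np.array([[10.0, 20.0, 90.0]]))
    assert aggregate_replicates(s2, "median").aggregated[0] == 20.0
    with pytest.raises(ValueError, match="unknown"):
        aggregate_replicates(s, "mode")


def test_series_requires_seven_day_spacing():
    with pytest.raises(ValueError, match="7 days"):
        SearchSeries(
            week_start=pd.DatetimeIndex(["2020-01-05", "2020-01-13"]),
            aggregated=np.array([1.0, 2.0]),
        )


@settings(derandomize=True, max_examples=20, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    mean=st.floats(20.0, 200.0),
    amp=st.floats(0.0, 10.0),
    wsd=st.floats(0.0, 8.0),
)
def test_generator_output_is_valid_and_deterministic(seed, mean, amp, wsd):
    params = GeneratorParams(
        baseline_mean=mean, seasonal_amplitude=amp, week_noise_sd=wsd,
        n_replicates=3, start_date="2019-01-01", end_date="2019-06-30", seed=seed,
    )
    a, b = generate_series(params), generate_series(params)
    np.testing.assert_array_equal(a.replicates, b.replicates)
    assert np.all(a.replicates[~np.isnan(a.replicates)] >= 0.0)
    assert np.all(np.diff(a.week_start.asi8) == 7 * 86400 * 10**9)
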