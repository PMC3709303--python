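import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ozonewarn import (
    AirQualityStandard,
    NextDayOzoneModel,
    PolySimConfig,
    SimConfig,
    build_lagged_table,
    exceedance_rate_curve,
    fit_quadratic_model,
    inject_missing,
    screen_predictors,
    simulate_from_polynomial,
    simulate_hourly,
    summarize,
    warning_thresholds,
)
from ozonewarn.early_warning import PREDICTORS, RateCurve, predict


def _summaries(n_days, start="2010-06-01", **overrides):
    dates = pd.date_range(start, periods=n_days, freq="D")
    rng = np.random.default_rng(0)
    data = {p: rng.uniform(0, 1, n_days) for p in PREDICTORS}
    data["o3_1h_max"] = rng.uniform(100, 250, n_days)
    data["o3_8h_max"] = rng.uniform(80, 200, n_days)
    data.update(overrides)
    return pd.DataFrame(data, index=dates)


# -- lagged table ------------------------------------------------------------


def test_lagged_table_row_counting():
    assert len(build_lagged_table(_summaries(3))) == 2
    gap = pd.concat([_summaries(1, "2010-06-01"), _summaries(1, "2010-06-03")])
    with pytest.raises(ValueError, match="consecutive"):
        build_lagged_table(gap)


def test_lagged_table_alignment_and_missing_targets():
    s = _summaries(5)
    s.loc[s.index[3], ["o3_1h_max", "o3_8h_max"]] = np.nan
    table = build_lagged_table(s)
    # day 2's row pairs with day 3's (missing) targets and is dropped
    assert len(table) == 3
    assert table["next_o3_1h_max"].iloc[0] == s["o3_1h_max"].iloc[1]


def test_lagged_table_count_under_injected_missingness():
    series = simulate_hourly(SimConfig(seed=6, n_days=120, missing_fraction=0.0))
    series = inject_missing(series, 0.15, seed=1)
    daily = summarize(series)
    table = build_lagged_table(daily)
    # independent recount: a row survives iff the next day has any target
    expected = 0
    for i in range(len(daily) - 1):
        nxt = daily.iloc[i + 1]
        if not (np.isnan(nxt["o3_1h_max"]) and np.isnan(nxt["o3_8h_max"])):
            expected += 1
    assert len(table) == expected <= 119


# -- screening ---------------------------------------------------------------


def test_screening_perfect_and_anti_correlation():
    s = _summaries(40)
    s["o3_mean"] = s["o3_8h_max"] * 0.5  # but targets are next-day values
    table = build_lagged_table(s)
    table["o3_mean"] = table["next_o3_8h_max"] * 2.0
    table["t_max"] = -table["next_o3_8h_max"]
    result = screen_predictors(table)
    assert result.loc["o3_mean", "r_8h"] == pytest.approx(1.0)
    assert result.loc["o3_mean", "p_8h"] < 1e-10
    assert result.loc["o3_mean", "sig_8h"] == "0.01"
    assert result.loc["t_max", "r_8h"] == pytest.approx(-1.0)


def test_screening_matches_textbook_pearson_formula():
    table = build_lagged_table(_summaries(13))  # 12 rows
    result = screen_predictors(table, min_rows=10)
    for factor in ("t_mean", "o3_mean", "ws_mean"):
        x = table[factor].to_numpy()
        y = table["next_o3_1h_max"].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert result.loc[factor, "r_1h"] == pytest.approx(r_direct, abs=1e-12)


def test_screening_constant_factor_reported_undefined():
    table = build_lagged_table(_summaries(30))
    table["vis_mean"] = 7.0
    result = screen_predictors(table)
    assert np.isnan(result.loc["vis_mean", "r_1h"])
    assert result.loc["vis_mean", "sig_1h"] == "undefined"


def test_screening_requires_complete_rows():
    table = build_lagged_table(_summaries(8))
    with pytest.raises(ValueError, match="complete rows"):
        screen_predictors(table)


# -- quadratic model ---------------------------------------------------------


def test_noise_free_coefficient_recovery(quad_coeffs):
    table = simulate_from_polynomial(
        PolySimConfig(coefficients=quad_coeffs, n_points=400, noise_sd=0.0, seed=3)
    )
    res = NextDayOzoneModel(table["x1"], table["x2"], table["y"]).fit()
    rel = np.abs((res.params.to_numpy() - np.array(quad_coeffs)) / np.array(quad_coeffs))
    assert rel.max() <= 1e-6
    assert res.r2 == pytest.approx(1.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_recovery_for_random_coefficient_draws(draw_seed):
    """Exact recovery holds for any full-rank design, whatever the surface."""
    rng = np.random.default_rng(draw_seed)
    coeffs = tuple(rng.uniform(-5, 5, 6))
    table = simulate_from_polynomial(
        PolySimConfig(coefficients=coeffs, n_points=60, noise_sd=0.0,
                      seed=draw_seed + 1)
    )
    res = NextDayOzoneModel(table["x1"], table["x2"], table["y"]).fit()
    np.testing.assert_allclose(res.params.to_numpy(), coeffs, rtol=1e-6, atol=1e-6)


def test_noisy_recovery_within_three_standard_errors(quad_coeffs):
    table = simulate_from_polynomial(
        PolySimConfig(coefficients=quad_coeffs, n_points=500, noise_sd=10.0, seed=5)
    )
    res = NextDayOzoneModel(table["x1"], table["x2"], table["y"]).fit()
    err = np.abs(res.params.to_numpy() - np.array(quad_coeffs))
    assert (err <= 3 * res.bse.to_numpy()).all()


def test_constant_response_degenerates_gracefully():
    rng = np.random.default_rng(1)
    res = NextDayOzoneModel(rng.uniform(30, 150, 50), rng.uniform(20, 36, 50),
                            np.full(50, 42.0)).fit()
    np.testing.assert_allclose(res.params.to_numpy()[:5], 0.0, atol=1e-8)
    assert res.params["b_0"] == pytest.approx(42.0, abs=1e-8)
    assert res.r2 == 0.0


def test_rank_deficient_design_names_collinear_terms():
    x1 = np.linspace(30, 150, 40)
    model = NextDayOzoneModel(x1, 2 * x1, x1)  # X2 proportional to X1
    with pytest.raises(ValueError, match="collinear"):
        model.fit()


def test_model_preconditions():
    with pytest.raises(ValueError, match="at least 6"):
        NextDayOzoneModel([1, 2, 3], [1, 2, 3], [1, 2, 3])
    with pytest.raises(ValueError, match="variance"):
        NextDayOzoneModel([1, 2, 3, 4, 5, 6], [2] * 6, [1, 2, 3, 4, 5, 6])


def test_predict_evaluates_polynomial(quad_coeffs):
    assert predict(quad_coeffs, 87, 29) == pytest.approx(170.80, abs=0.005)
    assert predict(quad_coeffs, 36, 24) == pytest.approx(114.79, abs=0.005)
    assert predict((0, 0, 0, 0, 0, 0), 87, 29) == 0.0
    table = simulate_from_polynomial(
        PolySimConfig(coefficients=quad_coeffs, n_points=100, noise_sd=0.0, seed=9)
    )
    res = NextDayOzoneModel(table["x1"], table["x2"], table["y"]).fit()
    assert res.predict(87, 29) == pytest.approx(170.80, abs=0.01)


# -- rate curves and thresholds ----------------------------------------------


def _lagged(values, targets):
    dates = pd.date_range("2010-06-01", periods=len(values), freq="D")
    frame = pd.DataFrame({"o3_mean": values, "next_o3_8h_max": targets}, index=dates)
    for p in PREDICTORS:
        if p not in frame:
            frame[p] = 1.0
    frame["next_o3_1h_max"] = targets
    return frame


def test_rate_curve_limits():
    values = np.linspace(30, 120, 40)
    always = _lagged(values, np.full(40, 300.0))
    curve = exceedance_rate_curve(always, "o3_mean")
    np.testing.assert_allclose(curve.rate, 1.0)
    never = _lagged(values, np.full(40, 100.0))
    curve0 = exceedance_rate_curve(never, "o3_mean")
    np.testing.assert_allclose(curve0.rate, 0.0)


def test_rate_curve_hand_counted_fractions():
    values = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 100.0])
    targets = np.array([100, 100, 200, 100, 200, 200, 100, 200, 200, 200.0])
    table = _lagged(values, targets)
    curve = exceedance_rate_curve(table, "o3_mean", min_rows=10)
    # at threshold 50: rows {50..100}, 5 of 6 exceed 160
    i = int(np.where(curve.thresholds == 50.0)[0][0])
    assert curve.support[i] == 6
    assert curve.rate[i] == pytest.approx(5 / 6)
    # at threshold 95: rows {100}, 1 of 1
    j = int(np.where(curve.thresholds == 95.0)[0][0])
    assert curve.support[j] == 1 and curve.rate[j] == 1.0
    assert curve.low_confidence[j]


def test_rate_curve_support_non_increasing_and_iso_monotone(default_daily):
    table = build_lagged_table(default_daily)
    curve = exceedance_rate_curve(table, "o3_mean")
    assert (np.diff(curve.support) <= 0).all()
    assert (np.diff(curve.iso_rate) >= -1e-12).all()
    assert curve.iso_rate.min() >= 0 and curve.iso_rate.max() <= 1


def test_rate_curve_preconditions():
    table = _lagged(np.linspace(0, 1, 10), np.full(10, 100.0))
    with pytest.raises(ValueError, match="at least 30"):
        exceedance_rate_curve(table, "o3_mean")


def _step_curve(variable, grid, breakpoints):
    """Monotone step curve: rate jumps at the given (threshold, rate) pairs."""
    rate = np.zeros_like(grid, dtype=float)
    for c, r in breakpoints:
        rate[grid >= c] = r
    support = np.arange(len(grid), 0, -1)
    return RateCurve(variable=variable, target_metric="8h", limit=160.0,
                     thresholds=grid, rate=rate, support=support,
                     iso_rate=rate, low_confidence=support < 5)


def test_threshold_inversion_on_constructed_step_curves():
    grid_o3 = np.arange(30.0, 140.0)
    curve_o3 = _step_curve("o3_mean", grid_o3,
                           [(40, 0.2), (87, 0.5), (113, 0.8), (127, 1.0)])
    grid_t = np.arange(20.0, 37.0)
    curve_t = _step_curve("t_max", grid_t, [(24.5, 0.2), (29, 0.5), (31, 0.8), (33, 1.0)])
    thr = warning_thresholds(curve_o3, curve_t)
    assert thr.levels["level1"] == (87.0, 29.0)
    assert thr.levels["level2"] == (113.0, 31.0)
    assert thr.levels["level3"] == (127.0, 33.0)
    assert thr.levels["zero"] == (39.0, 24.0)
    assert thr.fires("level1", 90.0, 30.0)
    assert not thr.fires("level1", 90.0, 25.0)  # conjunctive rule


def test_unattained_levels_reported_as_none():
    grid = np.arange(0.0, 50.0)
    partial = _step_curve("o3_mean", grid, [(10, 0.5)])  # never reaches 0.8/1.0
    thr = warning_thresholds(partial, partial)
    assert thr.levels["level2"] == (None, None)
    assert thr.levels["level3"] == (None, None)
    assert not thr.fires("level3", 1e9, 1e9)

    flat = _step_curve("o3_mean", grid, [])  # constant zero rate
    thr0 = warning_thresholds(flat, flat)
    assert thr0.levels["zero"] == (49.0, 49.0)
    assert thr0.levels["level1"] == (None, None)


def test_thresholds_monotone_across_levels_on_generator_output(default_daily):
    table = build_lagged_table(default_daily)
    curves = {
        v: exceedance_rate_curve(table, v) for v in ("o3_mean", "t_max")
    }
    thr = warning_thresholds(curves["o3_mean"], curves["t_max"])
    for pos in (0, 1):
        attained = [thr.levels[k][pos]
                    for k in ("zero", "level1", "level2", "level3")
                    if thr.levels[k][pos] is not None]
        assert attained == sorted(attained)


def test_fit_quadratic_model_from_generator_table(default_daily):
    table = build_lagged_table(default_daily)
    res = fit_quadratic_model(table, "8h")
    assert res.n >= 100
    assert 0 <= res.r2 <= 1
    assert res.target_metric == "8h"
    assert "R^2" in res.summary()
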