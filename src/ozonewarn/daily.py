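"""Daily aggregation: ozone metrics, candidate predictors and exceedance accounting.

Each calendar day of an :class:`~ozonewarn.timeseries.HourlySeries` is reduced
to one row holding the three ozone metrics (daily mean, daily 1-h maximum,
daily maximum 8-h running mean) and the candidate next-day predictors
(temperature, dew point, dew-point depression, humidity, wind, visibility,
24-h pressure/temperature tendencies, NO/NO2/NOx/OX levels and the NO/NO2
ratio).  Exceedance statistics compare the metrics against ambient
air-quality limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DAYLIGHT, is_daylight
from .timeseries import HourlySeries

#: minimum observed hours for a daily mean (75% completeness)
MIN_HOURS_DAILY_MEAN = 18
#: an 8-h window mean is valid with at least this many observed hours
MIN_HOURS_8H_WINDOW = 6
#: minimum observed hours in a 12-h day/night window average
MIN_HOURS_WINDOW_MEAN = 9


@dataclass(frozen=True)
class AirQualityStandard:
    """Level-II ambient ozone limits (ug/m3): 1-h mean and daily max 8-h mean."""

    limit_1h: float = 200.0
    limit_8h: float = 160.0

    def __post_init__(self) -> None:
        if not (self.limit_1h > 0 and self.limit_8h > 0):
            raise ValueError("standard limits must be > 0")


def rolling_8h_max(hourly_values) -> float:
    """Daily maximum 8-h running mean from exactly 24 hourly slots.

    Windows start at hours 00-16 (confined to the calendar day); a window
    contributes when it has at least :data:`MIN_HOURS_8H_WINDOW` observed
    hours, its value being the mean of the observed hours.  Returns NaN when
    no window is valid.
    """
    values = np.asarray(hourly_values, dtype=float)
    if values.shape != (24,):
        raise ValueError("rolling_8h_max expects exactly 24 hourly slots")
    windows = np.lib.stride_tricks.sliding_window_view(values, 8)  # (17, 8)
    counts = np.sum(~np.isnan(windows), axis=1)
    valid = counts >= MIN_HOURS_8H_WINDOW
    if not valid.any():
        return float("nan")
    means = np.nanmean(windows[valid], axis=1)
    return float(means.max())


def _mean_if(values: np.ndarray, min_hours: int = MIN_HOURS_DAILY_MEAN) -> float:
    n = int(np.sum(~np.isnan(values)))
    if n < min_hours:
        return float("nan")
    return float(np.nanmean(values))


def _day_frame(series: HourlySeries, date) -> pd.DataFrame:
    """The 24 hourly rows of one calendar day, padded with missing hours."""
    date = pd.Timestamp(date).normalize()
    idx = pd.date_range(date, periods=24, freq="h")
    return series.frame.reindex(idx)


def summarize_day(series: HourlySeries, date, prev_day: pd.Series | None = None,
                  daylight: tuple = DAYLIGHT) -> pd.Series:
    """One day's metrics and predictors.

    Daily means require at least 18 observed hours (75%), otherwise they are
    missing; ``o3_1h_max`` is the maximum over the observed hours.  The 24-h
    tendencies ``dp24``/``dt24`` are today's minus yesterday's daily mean and
    are missing without ``prev_day``.  Derived sums are formed from the
    component means, so ``nox_mean = no_mean + no2_mean`` and
    ``ox_mean = o3_mean + no2_mean`` hold by construction.
    """
    day = _day_frame(series, date)
    hours = day.index.hour.to_numpy()
    out = {"date": pd.Timestamp(date).normalize()}

    o3 = day["o3"].to_numpy()
    out["o3_mean"] = _mean_if(o3)
    out["o3_1h_max"] = float(np.nanmax(o3)) if np.any(~np.isnan(o3)) else float("nan")
    out["o3_8h_max"] = rolling_8h_max(o3)

    temp = day["temp_c"].to_numpy()
    out["t_mean"] = _mean_if(temp)
    out["t_max"] = (
        float(np.nanmax(temp))
        if np.sum(~np.isnan(temp)) >= MIN_HOURS_DAILY_MEAN
        else float("nan")
    )
    out["td_mean"] = _mean_if(day["td_c"].to_numpy())
    out["ttd_mean"] = out["t_mean"] - out["td_mean"]
    out["rh_mean"] = _mean_if(day["rh_pct"].to_numpy())
    out["ws_mean"] = _mean_if(day["ws_ms"].to_numpy())
    out["vis_mean"] = _mean_if(day["vis_km"].to_numpy())

    press_mean = _mean_if(day["press_hpa"].to_numpy())
    out["press_mean"] = press_mean
    if prev_day is not None:
        out["dp24"] = press_mean - prev_day.get("press_mean", float("nan"))
        out["dt24"] = out["t_mean"] - prev_day.get("t_mean", float("nan"))
    else:
        out["dp24"] = float("nan")
        out["dt24"] = float("nan")

    no = day["no"].to_numpy()
    no2 = day["no2"].to_numpy()
    out["no_mean"] = _mean_if(no)
    out["no2_mean"] = _mean_if(no2)
    out["nox_mean"] = out["no_mean"] + out["no2_mean"]
    out["ox_mean"] = out["o3_mean"] + out["no2_mean"]
    ratio_ok = ~np.isnan(no) & ~np.isnan(no2) & (no2 > 0)
    out["no_no2_ratio_mean"] = (
        float(np.mean(no[ratio_ok] / no2[ratio_ok]))
        if ratio_ok.sum() >= MIN_HOURS_DAILY_MEAN
        else float("nan")
    )

    # day/night window averages of OX and NOx (for the oxidant partition)
    both = ~np.isnan(o3) & ~np.isnan(no2) & ~np.isnan(no)
    ox_h = np.where(both, o3 + no2, np.nan)
    nox_h = np.where(both, no + no2, np.nan)
    day_mask = is_daylight(hours, daylight)
    for label, mask in (("day", day_mask), ("night", ~day_mask)):
        out[f"ox_{label}"] = _mean_if(ox_h[mask], MIN_HOURS_WINDOW_MEAN)
        out[f"nox_{label}"] = _mean_if(nox_h[mask], MIN_HOURS_WINDOW_MEAN)
        out[f"o3_{label}"] = _mean_if(o3[mask], MIN_HOURS_WINDOW_MEAN)
        out[f"no_{label}"] = _mean_if(no[mask], MIN_HOURS_WINDOW_MEAN)
        out[f"no2_{label}"] = _mean_if(no2[mask], MIN_HOURS_WINDOW_MEAN)

    out["n_o3"] = int(np.sum(~np.isnan(o3)))
    out["n_no"] = int(np.sum(~np.isnan(no)))
    out["n_no2"] = int(np.sum(~np.isnan(no2)))
    out["n_temp"] = int(np.sum(~np.isnan(temp)))
    return pd.Series(out)


def summarize(series: HourlySeries, daylight: tuple = DAYLIGHT) -> pd.DataFrame:
    """Daily summary table for every calendar day the series touches.

    The 24-h tendencies chain automatically from the previous day's row.
    """
    if len(series) == 0:
        raise ValueError("cannot summarize an empty series")
    dates = pd.date_range(
        series.frame.index[0].normalize(), series.frame.index[-1].normalize(), freq="D"
    )
    rows = []
    prev = None
    for date in dates:
        row = summarize_day(series, date, prev_day=prev, daylight=daylight)
        rows.append(row)
        prev = row
    table = pd.DataFrame(rows).set_index("date")
    return table


def mean_diurnal_profile(series: HourlySeries, variable: str) -> pd.Series:
    """Per-hour arithmetic mean over all days; hours with no data are NaN."""
    if variable not in series.frame.columns:
        if variable == "nox":
            values = series.frame["no"] + series.frame["no2"]
        elif variable == "ox":
            values = series.frame["o3"] + series.frame["no2"]
        else:
            raise ValueError(f"unknown variable: {variable!r}")
    else:
        values = series.frame[variable]
    profile = values.groupby(series.frame.index.hour).mean()
    return profile.reindex(range(24))


def exceedance_report(
    summaries: pd.DataFrame,
    std: AirQualityStandard = AirQualityStandard(),
    periods: list | None = None,
) -> pd.DataFrame:
    """Exceed-standard days and rates per period, with a pooled row.

    A day exceeds the 1-h criterion iff ``o3_1h_max > limit_1h`` and the 8-h
    criterion iff ``o3_8h_max > limit_8h`` (strict inequality, "not to
    exceed" semantics).  ``periods`` is a list of ``(label, start, end)``
    with inclusive date bounds; when omitted the whole table is one period.
    Rates are exceedance count over valid-day count (days with the metric
    present); empty periods report zero valid days and missing rates.
    """
    if periods is None:
        periods = [("all", summaries.index.min(), summaries.index.max())]
    rows = []
    for label, start, end in periods:
        sub = summaries.loc[
            (summaries.index >= pd.Timestamp(start))
            & (summaries.index <= pd.Timestamp(end))
        ]
        valid_1h = sub["o3_1h_max"].notna()
        valid_8h = sub["o3_8h_max"].notna()
        n1, n8 = int(valid_1h.sum()), int(valid_8h.sum())
        e1 = int((sub["o3_1h_max"] > std.limit_1h).sum())
        e8 = int((sub["o3_8h_max"] > std.limit_8h).sum())
        rows.append(
            {
                "period": label,
                "n_valid_days_1h": n1,
                "n_valid_days_8h": n8,
                "n_exceed_1h": e1,
                "n_exceed_8h": e8,
                "rate_1h": e1 / n1 if n1 else float("nan"),
                "rate_8h": e8 / n8 if n8 else float("nan"),
            }
        )
    pooled = {
        "period": "pooled",
        "n_valid_days_1h": sum(r["n_valid_days_1h"] for r in rows),
        "n_valid_days_8h": sum(r["n_valid_days_8h"] for r in rows),
        "n_exceed_1h": sum(r["n_exceed_1h"] for r in rows),
        "n_exceed_8h": sum(r["n_exceed_8h"] for r in rows),
    }
    pooled["rate_1h"] = (
        pooled["n_exceed_1h"] / pooled["n_valid_days_1h"]
        if pooled["n_valid_days_1h"]
        else float("nan")
    )
    pooled["rate_8h"] = (
        pooled["n_exceed_8h"] / pooled["n_valid_days_8h"]
        if pooled["n_valid_days_8h"]
        else float("nan")
    )
    rows.append(pooled)
    return pd.DataFrame(rows).set_index("period")
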