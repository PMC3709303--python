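"""Photostationary-state diagnostics for the O3-NO-NO2 system.

During daylight the null cycle NO + O3 -> NO2 and NO2 + hv -> NO + O3
equilibrates, so concentrations satisfy [O3][NO]/[NO2] = J2/K1, where J2 is
the NO2 photolysis rate and K1 the NO + O3 rate coefficient.  Only the ratio
is identifiable from concentrations; following common practice for station
data reported by mass it is expressed in concentration units (ug/m3).

This module estimates the diurnal J2/K1 profile, the NO2 share of total
oxidant as a function of NOx (split day/night), and the NOx levels at which
the fitted daylight O3 curve crosses the NO and NO2 curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .daily import summarize
from .simulate import DAYLIGHT, is_daylight
from .timeseries import HourlySeries


def j2k1(o3: float, no: float, no2: float) -> float:
    """Photostationary ratio J2/K1 = [O3][NO]/[NO2] (ug/m3).

    Undefined at NO2 = 0 (raises rather than returning zero).
    """
    if no2 <= 0:
        raise ValueError("j2k1 is undefined for no2 <= 0")
    if o3 < 0 or no < 0:
        raise ValueError("concentrations must be >= 0")
    return o3 * no / no2


def j2k1_profile(series: HourlySeries, daylight: tuple = DAYLIGHT) -> pd.DataFrame:
    """Per-hour mean of the photostationary ratio over all days.

    Hours contribute through records with a complete (O3, NO, NO2) triple and
    NO2 > 0; hours with no valid triple are missing.  Returns a frame indexed
    by hour 0-23 with columns ``j2k1`` (mean ratio), ``n`` (triples used) and
    ``daylight``.
    """
    f = series.frame
    ok = f["o3"].notna() & f["no"].notna() & f["no2"].notna() & (f["no2"] > 0)
    ratio = (f["o3"] * f["no"] / f["no2"])[ok]
    grouped = ratio.groupby(ratio.index.hour)
    out = pd.DataFrame(index=pd.RangeIndex(24, name="hour"))
    out["j2k1"] = grouped.mean().reindex(range(24))
    out["n"] = grouped.size().reindex(range(24)).fillna(0).astype(int)
    out["daylight"] = is_daylight(out.index.to_numpy(), daylight)
    return out


@dataclass
class FractionCurve:
    """[NO2]/[OX] versus NOx from daily day/night window averages."""

    points: pd.DataFrame  # columns: date, period, nox, fraction
    binned: pd.DataFrame  # columns: period, bin_left, fraction_mean, n
    n_dropped: int  # points dropped for OX = 0


def no2_ox_fraction(
    series: HourlySeries,
    daylight: tuple = DAYLIGHT,
    bin_width: float = 10.0,
    min_pairs: int = 10,
) -> FractionCurve:
    """NO2 share of total oxidant versus NOx, separately for day and night.

    Each point is one day's window-average concentrations; fractions lie in
    [0, 1] by construction.  Binned means use NOx bins of ``bin_width``
    ug/m3.  Requires at least ``min_pairs`` days with both a day and a night
    point.
    """
    daily = summarize(series, daylight=daylight)
    records, dropped = [], 0
    for period in ("day", "night"):
        o3 = daily[f"o3_{period}"]
        no2 = daily[f"no2_{period}"]
        nox = daily[f"nox_{period}"]
        ok = o3.notna() & no2.notna() & nox.notna()
        ox = o3[ok] + no2[ok]
        zero = ox <= 0
        dropped += int(zero.sum())
        keep = ok.index[ok][~zero.to_numpy()]
        records.append(
            pd.DataFrame(
                {
                    "date": keep,
                    "period": period,
                    "nox": nox[keep].to_numpy(),
                    "fraction": (no2[keep] / (o3[keep] + no2[keep])).to_numpy(),
                }
            )
        )
    points = pd.concat(records, ignore_index=True)
    pairs = points.groupby("date")["period"].nunique()
    if int((pairs == 2).sum()) < min_pairs:
        raise ValueError(f"need at least {min_pairs} day-night pairs")
    points["bin_left"] = np.floor(points["nox"] / bin_width) * bin_width
    binned = (
        points.groupby(["period", "bin_left"])["fraction"]
        .agg(fraction_mean="mean", n="size")
        .reset_index()
    )
    return FractionCurve(points=points.drop(columns="bin_left"), binned=binned,
                         n_dropped=dropped)


@dataclass
class CrossoverResult:
    """Quadratic daylight fits of O3/NO/NO2 against NOx and their crossings."""

    nox_at_o3_eq_no: float | None
    nox_at_o3_eq_no2: float | None
    coefficients: dict = field(default_factory=dict)  # species -> (a, b, c)
    r2: dict = field(default_factory=dict)
    nox_range: tuple = (float("nan"), float("nan"))


def _quadfit(x: np.ndarray, y: np.ndarray):
    coef = np.polyfit(x, y, 2)
    resid = y - np.polyval(coef, x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return coef, r2


def _crossing(coef_a, coef_b, lo: float, hi: float) -> float | None:
    """Smallest real root of the fitted-curve difference inside [lo, hi]."""
    diff = np.polysub(coef_a, coef_b)
    roots = np.roots(diff)
    real = sorted(
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-9 and lo - 1e-9 <= r.real <= hi + 1e-9
    )
    return real[0] if real else None


def crossover_analysis(daylight_daily: pd.DataFrame, min_days: int = 20) -> CrossoverResult:
    """Fit daylight daily averages of O3, NO and NO2 as quadratics in NOx and
    locate the O3=NO and O3=NO2 crossings inside the observed NOx range.

    ``daylight_daily`` needs columns ``nox, o3, no, no2`` (one row per day).
    Crossings outside the observed range are reported as not found, never
    extrapolated.
    """
    data = daylight_daily[["nox", "o3", "no", "no2"]].dropna()
    if len(data) < min_days:
        raise ValueError(f"need at least {min_days} days, got {len(data)}")
    x = data["nox"].to_numpy(dtype=float)
    if np.std(x) < 1e-9:
        raise ValueError("degenerate NOx spread (sd ~ 0)")
    coefficients, r2 = {}, {}
    for species in ("o3", "no", "no2"):
        coefficients[species], r2[species] = _quadfit(
            x, data[species].to_numpy(dtype=float)
        )
    lo, hi = float(x.min()), float(x.max())
    return CrossoverResult(
        nox_at_o3_eq_no=_crossing(coefficients["o3"], coefficients["no"], lo, hi),
        nox_at_o3_eq_no2=_crossing(coefficients["o3"], coefficients["no2"], lo, hi),
        coefficients={k: tuple(v) for k, v in coefficients.items()},
        r2=r2,
        nox_range=(lo, hi),
    )
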