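"""Synthetic hourly station data with photostationary O3-NO-NO2 coupling.

The generator emulates the statistical structure a summertime urban ozone
analysis assumes, so that every downstream stage can be exercised without
access to station data:

* a slowly varying regional oxidant background (AR(1) across days, mean
  ~100 ug/m3) plus a temperature-anomaly amplification of photochemistry;
* NOx with morning/evening rush-hour peaks, a day-to-day traffic/dispersion
  factor and positive hourly noise;
* a daylight photolysis-to-titration ratio J2/K1 (concentration units) that
  is zero at night and peaks late morning;
* O3 and NO2 obtained by partitioning total oxidant OX = O3 + NO2 jointly
  with NO + NO2 = NOx under the photostationary relation
  [O3] = (J2/K1) * [NO2] / [NO]; at night (J2/K1 = 0) NO titration runs to
  exhaustion of the limiting reagent, so min(O3, NO) = 0.

Daytime photochemical production is modelled as an efficiency-shaped gain on
NOx (plus a constant primary-NO2 fraction of NOx at all hours), so that the
oxidant maximum falls mid-afternoon while the NOx-independent part of OX --
the regional background -- stays an unbiased intercept in the OX~NOx
regression, for both the day and the night window.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .timeseries import POLLUTANT_COLUMNS, HourlySeries

#: half-open daylight window [start, stop): photolysis is zero outside it
DAYLIGHT = (6, 18)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults emulate a polluted summer in a northern
    Chinese industrial city (diurnal O3 peak mid-afternoon, regional oxidant
    background near 100 ug/m3, J2/K1 between 3 and 15 ug/m3 peaking at
    11:00, rush-hour NOx)."""

    seed: int = 0
    n_days: int = 120
    start: str = "2010-06-01"
    # regional oxidant background (ug/m3), AR(1) across days
    regional_ox_mean: float = 100.0
    regional_ox_ar1: float = 0.6
    regional_ox_sd: float = 24.0
    # temperature (deg C): daily-mean AR(1) plus diurnal sinusoid peaking 15:00
    temp_mean: float = 26.0
    temp_diurnal_amp: float = 5.0
    temp_daily_sd: float = 3.0
    temp_hourly_sd: float = 0.5
    temp_ar1: float = 0.75
    # NOx (ug/m3): base + rush-hour bumps (07-09 and 17-19), day factor, noise
    nox_base: float = 38.0
    nox_rush_amp: float = 30.0
    nox_day_sd: float = 0.25
    nox_noise_sd: float = 4.0
    # photolysis-to-titration ratio J2/K1 (ug/m3), daylight hump
    photolysis_peak_hour: int = 11
    j2k1_max: float = 15.0
    j2k1_min: float = 3.0
    j2k1_width_h: float = 2.0
    # oxidant production
    temp_o3_coupling: float = 8.0  # ug/m3 of OX per deg C of T_max anomaly
    primary_no2_fraction: float = 0.10
    photochem_gain_max: float = 2.2
    photochem_gain_peak_hour: int = 14
    photochem_gain_width_h: float = 2.6
    # observation model
    obs_noise_sd: float = 1.5
    missing_fraction: float = 0.0
    # auxiliary meteorology (artifact parameters for the predictor table)
    td_depression_mean: float = 8.0
    td_depression_sd: float = 3.0
    ws_mean: float = 2.5
    vis_mean_km: float = 15.0
    press_mean_hpa: float = 1005.0
    press_sd_hpa: float = 4.0

    def validate(self) -> None:
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        for name in (
            "regional_ox_sd", "temp_daily_sd", "temp_hourly_sd", "nox_noise_sd",
            "obs_noise_sd", "nox_day_sd", "td_depression_sd", "press_sd_hpa",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("regional_ox_ar1", "temp_ar1"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.j2k1_min > self.j2k1_max:
            raise ValueError("j2k1_min must be <= j2k1_max")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")

    @classmethod
    def from_dict(cls, mapping: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown SimConfig field(s): {', '.join(sorted(unknown))}")
        return cls(**mapping)


def is_daylight(hour, window: tuple = DAYLIGHT):
    """Boolean daylight mask for hour-of-day labels (start-of-hour)."""
    hour = np.asarray(hour)
    return (hour >= window[0]) & (hour < window[1])


def photolysis_ratio(hour, cfg: SimConfig = SimConfig()):
    """Deterministic diurnal J2/K1 shape (ug/m3): a daylight hump rising from
    ``j2k1_min`` at the window edges to ``j2k1_max`` at the photolysis peak,
    identically zero at night."""
    hour = np.asarray(hour, dtype=float)
    hump = cfg.j2k1_min + (cfg.j2k1_max - cfg.j2k1_min) * np.exp(
        -((hour - cfg.photolysis_peak_hour) ** 2) / (2 * cfg.j2k1_width_h**2)
    )
    return np.where(is_daylight(hour), hump, 0.0)


def _photochem_gain(hour, cfg: SimConfig):
    hour = np.asarray(hour, dtype=float)
    hump = cfg.photochem_gain_max * np.exp(
        -((hour - cfg.photochem_gain_peak_hour) ** 2)
        / (2 * cfg.photochem_gain_width_h**2)
    )
    return np.where(is_daylight(hour), hump, 0.0)


def _ar1(rng, n, mean, sd, phi):
    """Stationary AR(1) path with marginal standard deviation ``sd``."""
    x = np.empty(n)
    if sd == 0:
        x[:] = mean
        return x
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size=n)
    x[0] = mean + rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = mean + phi * (x[t - 1] - mean) + innov[t]
    return x


def partition_oxidant(ox, nox, ratio):
    """Split total oxidant between O3 and NO2 under the photostationary state.

    Solves ``(OX - NO2)(NOx - NO2) = r * NO2`` for the chemically admissible
    root ``NO2 in [0, min(OX, NOx)]`` (the other root exceeds both totals).
    At ``r = 0`` this reduces to titration to exhaustion:
    ``NO2 = min(OX, NOx)``, hence ``min(O3, NO) = 0``.

    Returns ``(o3, no, no2)`` arrays.
    """
    ox = np.asarray(ox, dtype=float)
    nox = np.asarray(nox, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    s = ox + nox + ratio
    prod = ox * nox
    disc = np.maximum(s * s - 4.0 * prod, 0.0)
    # numerically stable small root of x^2 - s x + prod = 0
    denom = s + np.sqrt(disc)
    no2 = np.where(denom > 0, 2.0 * prod / np.where(denom > 0, denom, 1.0), 0.0)
    no2 = np.minimum(no2, np.minimum(ox, nox))
    return ox - no2, nox - no2, no2


def simulate_hourly(cfg: SimConfig = SimConfig()) -> HourlySeries:
    """Generate an :class:`HourlySeries` of ``cfg.n_days`` days.

    Deterministic under a fixed ``cfg.seed``; independent named substreams
    drive each random component so changing one parameter does not reshuffle
    the others.
    """
    cfg.validate()
    n_days, n_hours = cfg.n_days, cfg.n_days * 24
    streams = np.random.SeedSequence(cfg.seed).spawn(7)
    rng_reg, rng_temp, rng_noxd, rng_noxh, rng_obs, rng_missing_entropy, rng_met = (
        np.random.default_rng(s) for s in streams
    )

    index = pd.date_range(cfg.start, periods=n_hours, freq="h", name="timestamp")
    hour = index.hour.to_numpy()
    day = np.arange(n_hours) // 24

    # daily drivers
    regional = _ar1(rng_reg, n_days, cfg.regional_ox_mean, cfg.regional_ox_sd,
                    cfg.regional_ox_ar1)
    tbar = _ar1(rng_temp, n_days, cfg.temp_mean, cfg.temp_daily_sd, cfg.temp_ar1)
    day_factor = np.maximum(0.2, 1.0 + rng_noxd.normal(0.0, cfg.nox_day_sd, n_days))

    # temperature: diurnal sinusoid peaking mid-afternoon (15:00)
    temp = tbar[day] + cfg.temp_diurnal_amp * np.cos(2 * np.pi * (hour - 15) / 24.0)
    if cfg.temp_hourly_sd > 0:
        temp = temp + rng_met.normal(0.0, cfg.temp_hourly_sd, n_hours)
    t_max_today = tbar + cfg.temp_diurnal_amp
    # amplification of photochemistry by the daily-maximum temperature anomaly
    boost = cfg.temp_o3_coupling * (
        t_max_today - (cfg.temp_mean + cfg.temp_diurnal_amp)
    )

    # NOx: rush-hour bumps at 08 and 18 local (sigma 1.5 h)
    bump = cfg.nox_rush_amp * (
        np.exp(-((hour - 8) ** 2) / (2 * 1.5**2))
        + np.exp(-((hour - 18) ** 2) / (2 * 1.5**2))
    )
    nox = day_factor[day] * (cfg.nox_base + bump)
    if cfg.nox_noise_sd > 0:
        nox = nox + np.abs(rng_noxh.normal(0.0, cfg.nox_noise_sd, n_hours))

    ratio = photolysis_ratio(hour, cfg)
    gain = _photochem_gain(hour, cfg)
    ox = np.maximum(
        regional[day] + boost[day] + (cfg.primary_no2_fraction + gain) * nox, 1.0
    )
    o3, no, no2 = partition_oxidant(ox, nox, ratio)

    if cfg.obs_noise_sd > 0:
        o3 = np.maximum(o3 + rng_obs.normal(0.0, cfg.obs_noise_sd, n_hours), 0.0)
        no = np.maximum(no + rng_obs.normal(0.0, cfg.obs_noise_sd, n_hours), 0.0)
        no2 = np.maximum(no2 + rng_obs.normal(0.0, cfg.obs_noise_sd, n_hours), 0.0)

    # auxiliary meteorology (simple, persistent daily structure)
    depress = np.maximum(
        0.5, _ar1(rng_met, n_days, cfg.td_depression_mean, cfg.td_depression_sd, 0.5)
    )
    td = temp - depress[day]
    rh = 100.0 * np.exp(
        17.625 * td / (243.04 + td) - 17.625 * temp / (243.04 + temp)
    )
    rh = np.clip(rh, 2.0, 100.0)
    ws = np.maximum(
        0.1,
        cfg.ws_mean
        + 0.8 * np.cos(2 * np.pi * (hour - 15) / 24.0)
        + rng_met.normal(0.0, 0.6, n_hours),
    )
    vis = np.clip(
        cfg.vis_mean_km * np.exp(rng_met.normal(0.0, 0.35, n_days))[day]
        + rng_met.normal(0.0, 1.0, n_hours),
        0.1,
        60.0,
    )
    press = (
        _ar1(rng_met, n_days, cfg.press_mean_hpa, cfg.press_sd_hpa, 0.7)[day]
        + 0.8 * np.cos(2 * np.pi * (hour - 10) / 12.0)
    )

    frame = pd.DataFrame(
        {
            "o3": o3,
            "no": no,
            "no2": no2,
            "temp_c": temp,
            "td_c": td,
            "rh_pct": rh,
            "ws_ms": ws,
            "vis_km": vis,
            "press_hpa": press,
        },
        index=index,
    )
    series = HourlySeries(frame, station_label=f"synthetic-seed{cfg.seed}")
    if cfg.missing_fraction > 0:
        series = inject_missing(
            series, cfg.missing_fraction,
            seed=int(rng_missing_entropy.integers(0, 2**31 - 1)),
        )
    return series


def inject_missing(series: HourlySeries, fraction: float, seed: int) -> HourlySeries:
    """Blank ``round(fraction * n_observed)`` observed pollutant cells,
    chosen uniformly and reproducibly under ``seed``."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    frame = series.frame.copy()
    block = frame[list(POLLUTANT_COLUMNS)].to_numpy()
    observed = np.argwhere(~np.isnan(block))
    k = int(round(fraction * len(observed)))
    if k:
        rng = np.random.default_rng(seed)
        pick = observed[rng.choice(len(observed), size=k, replace=False)]
        block[pick[:, 0], pick[:, 1]] = np.nan
        frame[list(POLLUTANT_COLUMNS)] = block
    return HourlySeries(frame, series.station_label)


# ---------------------------------------------------------------------------
# regression-ready tables from a bivariate quadratic response surface
# ---------------------------------------------------------------------------

#: coefficient order of the quadratic response surface
QUADRATIC_TERMS = ("b_x1sq", "b_x2sq", "b_x1x2", "b_x1", "b_x2", "b_0")


def evaluate_quadratic(coefficients, x1, x2):
    """Evaluate ``b1*X1^2 + b2*X2^2 + b3*X1*X2 + b4*X1 + b5*X2 + b6``."""
    b1, b2, b3, b4, b5, b6 = coefficients
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return b1 * x1**2 + b2 * x2**2 + b3 * x1 * x2 + b4 * x1 + b5 * x2 + b6


@dataclass(frozen=True)
class PolySimConfig:
    """Settings for sampling a noisy quadratic response surface Y(X1, X2)."""

    coefficients: tuple  # order: QUADRATIC_TERMS
    n_points: int = 200
    x1_range: tuple = (30.0, 150.0)
    x2_range: tuple = (20.0, 36.0)
    noise_sd: float = 0.0
    seed: int = 0
    grid: bool = False  # lay points on a sqrt(n) x sqrt(n) grid

    def validate(self) -> None:
        if len(tuple(self.coefficients)) != 6:
            raise ValueError("coefficients must have six entries")
        if self.n_points < 6:
            raise ValueError("n_points must be >= 6 (six coefficients)")
        for name in ("x1_range", "x2_range"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"{name} must be a non-degenerate interval")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.grid and int(np.sqrt(self.n_points)) ** 2 != self.n_points:
            raise ValueError("grid layout requires n_points to be a perfect square")


def simulate_from_polynomial(cfg: PolySimConfig) -> pd.DataFrame:
    """Sample ``(x1, x2, y)`` rows with ``y`` = quadratic form + N(0, noise_sd).

    Points are uniform over the ranges, or a regular grid when
    ``cfg.grid`` is set; deterministic under ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if cfg.grid:
        m = int(np.sqrt(cfg.n_points))
        g1 = np.linspace(*cfg.x1_range, m)
        g2 = np.linspace(*cfg.x2_range, m)
        x1, x2 = (a.ravel() for a in np.meshgrid(g1, g2))
    else:
        x1 = rng.uniform(*cfg.x1_range, cfg.n_points)
        x2 = rng.uniform(*cfg.x2_range, cfg.n_points)
    y = evaluate_quadratic(cfg.coefficients, x1, x2)
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, len(y))
    return pd.DataFrame({"x1": x1, "x2": x2, "y": y})
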