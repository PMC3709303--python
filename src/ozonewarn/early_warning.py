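"""Next-day ozone early warning: predictor screening, quadratic model and
graded thresholds.

The procedure forecasts whether tomorrow's ozone will exceed the ambient
standard from today's observations: (1) build a lagged table pairing fifteen
same-day factors with the next day's ozone metrics; (2) screen the factors by
two-tailed Pearson correlation; (3) fit the two strongest predictors -- the
daily mean ozone X1 and the daily maximum temperature X2 -- in a full
bivariate quadratic Y = b1 X1^2 + b2 X2^2 + b3 X1 X2 + b4 X1 + b5 X2 + b6;
(4) compute empirical conditional exceedance-rate curves (the fraction of
days with the predictor at or above a threshold whose next day exceeded the
standard) smoothed isotonically, and (5) invert them into graded warning
thresholds at 50/80/100% rates (levels 1-3) plus a no-risk level at 0%.
A warning fires only when both the ozone and the temperature condition hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .daily import AirQualityStandard
from .simulate import QUADRATIC_TERMS, evaluate_quadratic

#: the fifteen screened same-day factors, in reporting order
PREDICTORS = (
    "t_mean", "t_max", "td_mean", "ttd_mean", "rh_mean", "ws_mean", "vis_mean",
    "dp24", "dt24", "ox_mean", "o3_mean", "no_mean", "no2_mean", "nox_mean",
    "no_no2_ratio_mean",
)

TARGET_COLUMNS = {"1h": "next_o3_1h_max", "8h": "next_o3_8h_max"}

#: graded warning levels and the conditional exceedance rate defining each
WARNING_LEVELS = {"level1": 0.5, "level2": 0.8, "level3": 1.0}


def build_lagged_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pair day-d predictors with day-(d+1) ozone metrics.

    One row per day d whose successor day is present in the summary table;
    rows where both next-day metrics are missing are dropped.  Raises when no
    consecutive day pair exists.
    """
    idx = summaries.index
    nxt = idx + pd.Timedelta(days=1)
    has_next = nxt.isin(idx)
    if not has_next.any():
        raise ValueError("no consecutive day pairs in the summary table")
    base = summaries.loc[has_next, list(PREDICTORS)].copy()
    successors = summaries.loc[nxt[has_next]]
    base["next_o3_1h_max"] = successors["o3_1h_max"].to_numpy()
    base["next_o3_8h_max"] = successors["o3_8h_max"].to_numpy()
    keep = base[["next_o3_1h_max", "next_o3_8h_max"]].notna().any(axis=1)
    return base.loc[keep]


def screen_predictors(table: pd.DataFrame, min_rows: int = 10) -> pd.DataFrame:
    """Pairwise-complete Pearson screening of the fifteen factors against both
    next-day targets.

    Two-tailed p-values come from the t distribution with n-2 degrees of
    freedom; significance classes at 0.05 and 0.01.  A factor that is
    constant over its complete rows has undefined correlation, reported as
    NaN with class ``"undefined"``.
    """
    rows = []
    for factor in PREDICTORS:
        entry = {"factor": factor}
        for tag, target in TARGET_COLUMNS.items():
            pair = table[[factor, target]].dropna()
            n = len(pair)
            if n < min_rows:
                raise ValueError(
                    f"factor {factor!r} has only {n} complete rows against "
                    f"{target} (need {min_rows})"
                )
            x = pair[factor].to_numpy(dtype=float)
            y = pair[target].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r, p, sig = float("nan"), float("nan"), "undefined"
            else:
                r, p = stats.pearsonr(x, y)
                sig = "0.01" if p < 0.01 else ("0.05" if p < 0.05 else "none")
            entry[f"r_{tag}"] = float(r)
            entry[f"p_{tag}"] = float(p)
            entry[f"sig_{tag}"] = sig
            entry[f"n_{tag}"] = n
        rows.append(entry)
    return pd.DataFrame(rows).set_index("factor")


class NextDayOzoneModel:
    """Bivariate quadratic regression of tomorrow's ozone on today's levels.

    ``Y = b_x1sq X1^2 + b_x2sq X2^2 + b_x1x2 X1 X2 + b_x1 X1 + b_x2 X2 + b_0``
    with X1 = daily mean ozone (ug/m3), X2 = daily maximum temperature
    (deg C) and Y a next-day ozone metric (ug/m3), fitted by ordinary least
    squares.
    """

    def __init__(self, x1, x2, y, target_metric: str = "8h") -> None:
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = ~(np.isnan(x1) | np.isnan(x2) | np.isnan(y))
        self.x1, self.x2, self.y = x1[ok], x2[ok], y[ok]
        self.target_metric = target_metric
        if len(self.y) < 6:
            raise ValueError("need at least 6 complete rows for six coefficients")
        for name, v in (("X1", self.x1), ("X2", self.x2)):
            if np.std(v) == 0:
                raise ValueError(f"{name} has zero variance")

    @classmethod
    def from_lagged_table(
        cls, table: pd.DataFrame, target_metric: str = "8h"
    ) -> "NextDayOzoneModel":
        target = TARGET_COLUMNS[target_metric]
        return cls(table["o3_mean"], table["t_max"], table[target], target_metric)

    def design_matrix(self) -> np.ndarray:
        return np.column_stack(
            [
                self.x1**2,
                self.x2**2,
                self.x1 * self.x2,
                self.x1,
                self.x2,
                np.ones_like(self.x1),
            ]
        )

    def fit(self) -> "NextDayOzoneResults":
        design = self.design_matrix()
        # scale-invariant rank check; name the dependent columns on failure
        scaled = design / np.linalg.norm(design, axis=0)
        rank = np.linalg.matrix_rank(scaled, tol=1e-8)
        if rank < 6:
            from scipy.linalg import qr

            _, _, piv = qr(scaled, pivoting=True)
            bad = [QUADRATIC_TERMS[i] for i in sorted(piv[rank:])]
            raise ValueError(f"rank-deficient design; collinear term(s): {bad}")
        res = sm.OLS(self.y, design).fit()
        return NextDayOzoneResults(self, res)


class NextDayOzoneResults:
    """Fitted quadratic early-warning model."""

    def __init__(self, model: NextDayOzoneModel, sm_results) -> None:
        self.model = model
        self._res = sm_results
        self.params = pd.Series(sm_results.params, index=QUADRATIC_TERMS)
        self.bse = pd.Series(sm_results.bse, index=QUADRATIC_TERMS)
        # a constant response carries no explainable variance
        self.r2 = 0.0 if np.var(model.y) == 0 else float(sm_results.rsquared)
        self.n = int(sm_results.nobs)
        self.target_metric = model.target_metric

    def predict(self, x1, x2):
        """Evaluate the fitted quadratic at (X1, X2)."""
        return evaluate_quadratic(self.params.to_numpy(), x1, x2)

    def to_dict(self) -> dict:
        out = {k: float(v) for k, v in self.params.items()}
        out.update(
            {"r2": self.r2, "n": self.n, "target_metric": self.target_metric}
        )
        return out

    def summary(self) -> str:
        lines = [
            f"Next-day ozone quadratic model (target: {self.target_metric} metric), "
            f"n={self.n}, R^2={self.r2:.3f}",
            "  term        coef          se",
        ]
        for term in QUADRATIC_TERMS:
            lines.append(
                f"  {term:<8}{self.params[term]:>12.4f}{self.bse[term]:>12.4f}"
            )
        return "\n".join(lines)

    def plot_response(self, ax=None, x2_levels=(24, 29, 33)):  # pragma: no cover
        """Predicted next-day ozone versus X1 at fixed temperature levels."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(self.model.x1.min(), self.model.x1.max(), 100)
        for t in x2_levels:
            ax.plot(grid, self.predict(grid, t), label=f"T_max = {t} degC")
        ax.set_xlabel("today's O3 mean (ug/m3)")
        ax.set_ylabel("predicted next-day O3 (ug/m3)")
        ax.legend()
        return ax


def fit_quadratic_model(table: pd.DataFrame, target_metric: str = "8h"):
    """Convenience wrapper: build and fit :class:`NextDayOzoneModel`."""
    return NextDayOzoneModel.from_lagged_table(table, target_metric).fit()


def predict(results_or_params, x1, x2):
    """Evaluate a fitted model (or a six-coefficient sequence) at (X1, X2)."""
    if hasattr(results_or_params, "predict"):
        return results_or_params.predict(x1, x2)
    return evaluate_quadratic(results_or_params, x1, x2)


@dataclass
class RateCurve:
    """Conditional next-day exceedance rate as a function of a threshold.

    ``rate[i]`` is the fraction of table rows with ``variable >= thresholds[i]``
    whose next-day metric exceeded the standard; ``support`` counts the
    conditioning rows (non-increasing in the threshold).  ``iso_rate`` is the
    isotonic (pool-adjacent-violators) smoothing of ``rate`` weighted by
    support, which enforces the monotone structure graded warnings presume.
    """

    variable: str
    target_metric: str
    limit: float
    thresholds: np.ndarray
    rate: np.ndarray
    support: np.ndarray
    iso_rate: np.ndarray
    low_confidence: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "rate": self.rate,
                "iso_rate": self.iso_rate,
                "support": self.support,
                "low_confidence": self.low_confidence,
            }
        )


def exceedance_rate_curve(
    table: pd.DataFrame,
    variable: str,
    std: AirQualityStandard = AirQualityStandard(),
    target_metric: str = "8h",
    step: float = 1.0,
    min_rows: int = 30,
    min_support: int = 5,
) -> RateCurve:
    """Empirical tail-conditioned exceedance-rate curve.

    For each threshold c on a ``step``-unit grid spanning the observed range
    of ``variable``, the rate is
    ``#(variable >= c and next-day metric > limit) / #(variable >= c)``.
    Thresholds supported by fewer than ``min_support`` rows are flagged
    low-confidence.  Tail conditioning (not binning) matches the reading
    "the rate reached X% once the factor exceeded c" and is stable at
    one-unit steps.
    """
    target = TARGET_COLUMNS[target_metric]
    limit = std.limit_8h if target_metric == "8h" else std.limit_1h
    data = table[[variable, target]].dropna()
    if len(data) == 0:
        raise ValueError("empty lagged table")
    if len(data) < min_rows:
        raise ValueError(f"need at least {min_rows} rows, got {len(data)}")
    x = data[variable].to_numpy(dtype=float)
    exceed = data[target].to_numpy(dtype=float) > limit
    thresholds = np.arange(np.floor(x.min()), np.floor(x.max()) + step / 2, step)
    support = np.array([(x >= c).sum() for c in thresholds], dtype=int)
    rate = np.array(
        [exceed[x >= c].mean() if (x >= c).any() else np.nan for c in thresholds]
    )
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    iso_rate = iso.fit_transform(thresholds, rate, sample_weight=support)
    return RateCurve(
        variable=variable,
        target_metric=target_metric,
        limit=float(limit),
        thresholds=thresholds,
        rate=rate,
        support=support,
        iso_rate=iso_rate,
        low_confidence=support < min_support,
    )


@dataclass
class WarningThresholds:
    """(O3_mean, T_max) threshold pairs per warning level.

    ``levels`` maps ``zero`` (no-risk ceiling) and ``level1``/``level2``/
    ``level3`` (50/80/100% conditional exceedance rate) to pairs; a missing
    component is None when that level is not attained on the data.  A warning
    at a level fires only when BOTH conditions hold (conjunctive rule).
    """

    levels: dict
    target_metric: str = "8h"

    def fires(self, level: str, o3_mean: float, t_max: float) -> bool:
        o3_thr, t_thr = self.levels[level]
        if o3_thr is None or t_thr is None:
            return False
        return o3_mean > o3_thr and t_max > t_thr

    def to_dict(self) -> dict:
        return {
            "target_metric": self.target_metric,
            "levels": {
                k: {"o3_mean_threshold": v[0], "t_max_threshold": v[1]}
                for k, v in self.levels.items()
            },
        }


def _invert_curve(curve: RateCurve) -> dict:
    """Per-level threshold from an isotonic-smoothed rate curve."""
    out = {}
    iso = curve.iso_rate
    thr = curve.thresholds
    positive = iso > 0
    if positive.all():
        out["zero"] = None  # rate already positive at the lowest threshold
    else:
        # largest threshold with smoothed rate 0, scanning from below
        out["zero"] = float(thr[~positive][-1])
    for level, r_star in WARNING_LEVELS.items():
        reached = iso >= r_star - 1e-12
        out[level] = float(thr[reached][0]) if reached.any() else None
    return out


def warning_thresholds(
    curve_o3: RateCurve, curve_t: RateCurve
) -> WarningThresholds:
    """Invert the two rate curves into graded (O3_mean, T_max) thresholds.

    For each warning rate r* the threshold is the smallest grid value whose
    smoothed rate reaches r*; the zero level is the largest grid value still
    at rate 0.  Unattained levels are reported as None, never extrapolated.
    Monotonicity across levels is inherited from the isotonic curves.
    """
    inv_o3 = _invert_curve(curve_o3)
    inv_t = _invert_curve(curve_t)
    levels = {
        key: (inv_o3[key], inv_t[key]) for key in ("zero", "level1", "level2", "level3")
    }
    return WarningThresholds(levels=levels, target_metric=curve_o3.target_metric)
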