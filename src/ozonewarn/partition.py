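"""Regional/local decomposition of total oxidant by linear regression.

Daily window averages of total oxidant OX = O3 + NO2 increase linearly with
NOx.  The intercept of OX ~ NOx is the NOx-independent part -- interpreted
as the regional background oxidant advected into the site -- while the slope
is the local, primary-pollution-correlated contribution per unit NOx.  The
regression is fitted separately for daylight and night window averages;
comparable intercepts with a lower night slope indicate a common regional
background modulated by local daytime photochemistry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .daily import summarize
from .simulate import DAYLIGHT
from .timeseries import HourlySeries


class OxidantPartition:
    """OLS model ``OX = intercept + slope * NOx`` over daily averages.

    Parameters
    ----------
    ox, nox : array-like
        Daily window averages (ug/m3), same length; rows with a missing
        value in either are dropped.
    period_label : str
        ``"day"``, ``"night"`` or ``"all"`` -- carried into the results.
    """

    def __init__(self, ox, nox, period_label: str = "all") -> None:
        ox = np.asarray(ox, dtype=float)
        nox = np.asarray(nox, dtype=float)
        ok = ~np.isnan(ox) & ~np.isnan(nox)
        self.ox = ox[ok]
        self.nox = nox[ok]
        self.period_label = period_label
        if len(self.ox) < 3:
            raise ValueError("need at least 3 complete (OX, NOx) points")
        if np.std(self.nox) < 1e-12:
            raise ValueError("zero NOx variance: slope is not identifiable")

    @classmethod
    def from_daily(cls, daily: pd.DataFrame, period: str = "day") -> "OxidantPartition":
        """Build from a daily summary table (columns ``ox_day``/``nox_day``
        etc. as written by :func:`ozonewarn.daily.summarize`)."""
        if period == "all":
            return cls(daily["ox_mean"], daily["nox_mean"], period_label="all")
        return cls(daily[f"ox_{period}"], daily[f"nox_{period}"], period_label=period)

    @classmethod
    def from_hourly(
        cls, series: HourlySeries, period: str = "day", daylight: tuple = DAYLIGHT
    ) -> "OxidantPartition":
        return cls.from_daily(summarize(series, daylight=daylight), period=period)

    def fit(self) -> "OxidantPartitionResults":
        design = sm.add_constant(self.nox)
        res = sm.OLS(self.ox, design).fit()
        return OxidantPartitionResults(self, res)


class OxidantPartitionResults:
    """Fitted oxidant partition: regional intercept and local slope."""

    def __init__(self, model: OxidantPartition, sm_results) -> None:
        self.model = model
        self._res = sm_results
        self.period_label = model.period_label
        self.intercept = float(sm_results.params[0])
        self.slope = float(sm_results.params[1])
        self.intercept_se = float(sm_results.bse[0])
        self.slope_se = float(sm_results.bse[1])
        # a constant response carries no explainable variance
        self.r2 = 0.0 if np.var(model.ox) == 0 else float(sm_results.rsquared)
        self.n = int(sm_results.nobs)

    def predict(self, nox) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(nox, dtype=float)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._res.conf_int(alpha)
        return pd.DataFrame(ci, index=["intercept", "slope"], columns=["lo", "hi"])

    def to_dict(self) -> dict:
        return {
            "period_label": self.period_label,
            "intercept": self.intercept,
            "slope": self.slope,
            "intercept_se": self.intercept_se,
            "slope_se": self.slope_se,
            "r2": self.r2,
            "n": self.n,
        }

    def summary(self) -> str:
        return (
            f"Oxidant partition ({self.period_label}), n={self.n}\n"
            f"  regional (intercept): {self.intercept:8.2f} ug/m3  "
            f"(se {self.intercept_se:.2f})\n"
            f"  local (slope):        {self.slope:8.3f} per unit NOx  "
            f"(se {self.slope_se:.3f})\n"
            f"  R^2: {self.r2:.3f}"
        )

    def plot(self, ax=None):  # pragma: no cover - optional plotting
        """Scatter of the daily points with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.nox, self.model.ox, s=12, alpha=0.6)
        grid = np.linspace(self.model.nox.min(), self.model.nox.max(), 50)
        ax.plot(grid, self.predict(grid), color="k")
        ax.set_xlabel("NOx (ug/m3)")
        ax.set_ylabel("OX (ug/m3)")
        ax.set_title(f"OX ~ NOx ({self.period_label})")
        return ax


def compare_day_night(
    day_fit: OxidantPartitionResults, night_fit: OxidantPartitionResults
) -> dict:
    """Relative slope difference (%) and intercept difference (ug/m3).

    The relative slope difference ``(day - night) / day * 100`` quantifies how
    much weaker the local contribution is at night; the intercept difference
    checks that the regional background is shared between day and night.
    """
    if abs(day_fit.slope) < 1e-12:
        raise ZeroDivisionError("day slope is zero: relative difference undefined")
    return {
        "slope_diff_pct": (day_fit.slope - night_fit.slope) / day_fit.slope * 100.0,
        "intercept_diff": day_fit.intercept - night_fit.intercept,
    }
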