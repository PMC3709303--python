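"""Hourly station time series: container, CSV round-trip and plausibility screening.

The raw input of every analysis stage is an hourly record of the three
photochemically coupled species (O3, NO, NO2, mass concentrations in
``ug/m3``) together with surface meteorology.  The container is a thin
wrapper around a :class:`pandas.DataFrame` with a strictly continuous hourly
:class:`~pandas.DatetimeIndex`; gaps in the record are represented by rows of
missing values, never by absent rows, so that positional day/hour arithmetic
downstream is always safe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: species screened by :func:`qa_screen`
POLLUTANT_COLUMNS = ("o3", "no", "no2")
#: surface meteorology carried alongside the pollutants
MET_COLUMNS = ("temp_c", "td_c", "rh_pct", "ws_ms", "vis_km", "press_hpa")
VALUE_COLUMNS = POLLUTANT_COLUMNS + MET_COLUMNS
MANDATORY_CSV_COLUMNS = ("timestamp",) + POLLUTANT_COLUMNS

#: canonical on-disk timestamp format (local civil time, start of the hour)
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"


class HourlySeries:
    """Continuous hourly record for one station.

    Parameters
    ----------
    frame : pandas.DataFrame
        Indexed by hourly timestamps (strictly increasing, one-hour spacing,
        no gaps).  Any of :data:`VALUE_COLUMNS` that are absent are added as
        all-missing columns; extra columns are dropped.
    station_label : str
        Free-text identifier carried through reports.
    """

    def __init__(self, frame: pd.DataFrame, station_label: str = "") -> None:
        if not isinstance(frame.index, pd.DatetimeIndex):
            raise TypeError("HourlySeries requires a DatetimeIndex")
        index = frame.index
        if index.has_duplicates:
            dup = index[index.duplicated()][0]
            raise ValueError(f"duplicate timestamp: {dup}")
        if len(index) > 1:
            deltas = np.diff(index.asi8)
            bad = np.nonzero(deltas != 3_600_000_000_000)[0]
            if bad.size:
                raise ValueError(
                    "timestamps must be strictly increasing at one-hour "
                    f"spacing; offending timestamp: {index[bad[0] + 1]}"
                )
        data = pd.DataFrame(index=index.rename("timestamp"))
        for col in VALUE_COLUMNS:
            if col in frame.columns:
                data[col] = pd.to_numeric(frame[col], errors="coerce").astype(float)
            else:
                data[col] = np.nan
        self.frame = data
        self.station_label = station_label

    # -- basic protocol -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        span = ""
        if len(self.frame):
            span = f" {self.frame.index[0]} .. {self.frame.index[-1]}"
        return f"<HourlySeries n={len(self.frame)}{span} station={self.station_label!r}>"

    def equals(self, other: "HourlySeries") -> bool:
        """Value equality: identical index, values and missingness."""
        return self.station_label == other.station_label and self.frame.equals(
            other.frame
        )

    def copy(self) -> "HourlySeries":
        return HourlySeries(self.frame.copy(), self.station_label)

    def n_observed(self, columns=POLLUTANT_COLUMNS) -> int:
        """Count of non-missing cells over the given columns."""
        return int(self.frame[list(columns)].notna().to_numpy().sum())


def _parse_floats(values: pd.Series) -> np.ndarray:
    """Correctly-rounded float parsing; unparseable tokens become NaN."""
    out = np.empty(len(values), dtype=float)
    for i, token in enumerate(values.to_numpy()):
        try:
            out[i] = float(token)
        except (TypeError, ValueError):
            out[i] = np.nan
    return out


def read_hourly_csv(path, station_label: str = "") -> HourlySeries:
    """Read an hourly station CSV into an :class:`HourlySeries`.

    The file must carry a header naming at least ``timestamp,o3,no,no2``;
    met columns are optional and filled as missing when absent.  Empty cells,
    ``NA`` and any other unparseable numeric token become missing values.
    Hours absent between the first and last timestamp are filled in as
    all-missing rows.  Duplicate or non-monotone timestamps are rejected.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in MANDATORY_CSV_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing_cols)}")
    if len(raw) == 0:
        return HourlySeries(
            pd.DataFrame(index=pd.DatetimeIndex([], name="timestamp")), station_label
        )
    ts = pd.to_datetime(raw["timestamp"], format="ISO8601")
    if ts.duplicated().any():
        raise ValueError(f"duplicate timestamp: {ts[ts.duplicated()].iloc[0]}")
    decreasing = ts.diff().dt.total_seconds() <= 0
    if decreasing.fillna(False).any():
        raise ValueError(f"non-monotone timestamp: {ts[decreasing.fillna(False)].iloc[0]}")
    frame = pd.DataFrame(index=pd.DatetimeIndex(ts, name="timestamp"))
    for col in VALUE_COLUMNS:
        if col in raw.columns:
            frame[col] = _parse_floats(raw[col])
    full_index = pd.date_range(ts.iloc[0], ts.iloc[-1], freq="h", name="timestamp")
    frame = frame.reindex(full_index)
    return HourlySeries(frame, station_label)


def write_hourly_csv(series: HourlySeries, path):
    """Write a series as CSV; inverse of :func:`read_hourly_csv`.

    Missing values are written as empty cells; floats use shortest
    round-trip representation, so read(write(s)) reproduces s exactly.
    """
    out = series.frame.copy()
    out.index = out.index.strftime(TIMESTAMP_FORMAT)
    out.index.name = "timestamp"
    out.to_csv(path, na_rep="")
    return path


@dataclass(frozen=True)
class QAConfig:
    """Physical plausibility ceilings for the screened species (ug/m3)."""

    max_o3: float = 600.0
    max_no: float = 1000.0
    max_no2: float = 500.0
    allow_negative: bool = False

    def __post_init__(self) -> None:
        for name in ("max_o3", "max_no", "max_no2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def ceilings(self) -> dict:
        return {"o3": self.max_o3, "no": self.max_no, "no2": self.max_no2}


def qa_screen(series: HourlySeries, cfg: QAConfig = QAConfig()):
    """Replace physically implausible pollutant values by missing.

    A value is implausible when it exceeds its ceiling, or when it is
    negative and ``cfg.allow_negative`` is false (the ceiling is inclusive:
    a value exactly at the ceiling is retained).  Returns the screened
    series and a per-variable count of replacements; screening never fails
    and is idempotent.
    """
    frame = series.frame.copy()
    report = {}
    for col, ceiling in cfg.ceilings.items():
        values = frame[col]
        bad = values > ceiling
        if not cfg.allow_negative:
            bad = bad | (values < 0)
        bad = bad.fillna(False)
        report[col] = int(bad.sum())
        frame.loc[bad, col] = np.nan
    return HourlySeries(frame, series.station_label), report
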