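"""End-to-end orchestration: one reproducible run from hourly data to warning
thresholds, with a content-digest manifest for byte-level reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import daily as daily_mod
from . import early_warning as warn_mod
from . import photochem, timeseries
from .daily import AirQualityStandard
from .partition import OxidantPartition, compare_day_night
from .simulate import DAYLIGHT, SimConfig, simulate_hourly

log = logging.getLogger("ozonewarn")


@dataclass
class RunConfig:
    """Settings for a full pipeline run.

    Exactly one of ``input_csv`` (an hourly station CSV) or ``sim``
    (settings for the synthetic generator) must be given.
    """

    outdir: str
    input_csv: str | None = None
    sim: SimConfig | None = None
    standard: AirQualityStandard = field(default_factory=AirQualityStandard)
    daylight: tuple = DAYLIGHT
    periods: list | None = None  # [(label, start, end)]; default: calendar years
    target_metric: str = "8h"
    seed: int = 0
    qa: timeseries.QAConfig = field(default_factory=timeseries.QAConfig)

    def validate(self) -> None:
        if (self.input_csv is None) == (self.sim is None):
            raise ValueError("exactly one of input_csv / sim must be set")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(cfg: RunConfig) -> dict:
    out = {
        "input_csv": cfg.input_csv,
        "sim": dataclasses.asdict(cfg.sim) if cfg.sim else None,
        "standard": dataclasses.asdict(cfg.standard),
        "daylight": list(cfg.daylight),
        "periods": [[p[0], str(p[1]), str(p[2])] for p in cfg.periods]
        if cfg.periods
        else None,
        "target_metric": cfg.target_metric,
        "seed": cfg.seed,
        "qa": dataclasses.asdict(cfg.qa),
    }
    return out


def run_all(cfg: RunConfig) -> dict:
    """Execute every analysis stage and write the report bundle.

    Stages: simulate-or-read -> QA screen -> daily summary -> exceedance
    report -> photostationary diagnostics -> oxidant partition -> predictor
    screening -> quadratic model -> rate curves -> warning thresholds.
    Every artifact is CSV or JSON; a manifest records the config, seed,
    per-stage status and content digests.  A stage whose preconditions the
    data cannot meet (e.g. too few rows for the warning stage) is recorded
    as skipped with its reason; the bundle still completes.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    files: list[Path] = []

    def emit_csv(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        path = outdir / name
        frame.to_csv(path, index=index, na_rep="")
        files.append(path)

    def emit_json(name: str, obj) -> None:
        path = outdir / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
        files.append(path)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
                stages[name] = "ok"
            except ValueError as exc:
                stages[name] = f"skipped: {exc}"
                log.warning("stage %s skipped: %s", name, exc)
            log.info("stage %s: %.2fs", name, time.perf_counter() - t0)

        return wrap

    # -- input ---------------------------------------------------------------
    if cfg.sim is not None:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        series = simulate_hourly(sim_cfg)
        timeseries.write_hourly_csv(series, outdir / "hourly.csv")
        files.append(outdir / "hourly.csv")
    else:
        series = timeseries.read_hourly_csv(cfg.input_csv)
    stages["input"] = "ok"

    series, qa_report = timeseries.qa_screen(series, cfg.qa)
    stages["qa_screen"] = "ok"

    daily = daily_mod.summarize(series, daylight=cfg.daylight)
    emit_csv("daily.csv", daily)
    stages["summarize"] = "ok"

    periods = cfg.periods
    if periods is None:
        years = sorted(set(daily.index.year))
        periods = [
            (str(y), pd.Timestamp(year=y, month=1, day=1),
             pd.Timestamp(year=y, month=12, day=31))
            for y in years
        ]

    @stage("exceedance")
    def _exceedance():
        report = daily_mod.exceedance_report(daily, cfg.standard, periods)
        emit_csv("exceedance.csv", report)

    @stage("photostat")
    def _photostat():
        profile = photochem.j2k1_profile(series, cfg.daylight)
        emit_csv("j2k1_profile.csv", profile)
        frac = photochem.no2_ox_fraction(series, cfg.daylight)
        emit_csv("no2_ox_fraction_binned.csv", frac.binned, index=False)
        day_cols = daily[["nox_day", "o3_day", "no_day", "no2_day"]].rename(
            columns=lambda c: c.replace("_day", "")
        )
        cross = photochem.crossover_analysis(day_cols)
        emit_json(
            "crossover.json",
            {
                "nox_at_o3_eq_no": cross.nox_at_o3_eq_no,
                "nox_at_o3_eq_no2": cross.nox_at_o3_eq_no2,
                "r2": cross.r2,
                "coefficients": {
                    k: list(map(float, v)) for k, v in cross.coefficients.items()
                },
                "nox_range": list(cross.nox_range),
            },
        )

    @stage("oxpartition")
    def _oxpartition():
        fits = {}
        for period in ("day", "night", "all"):
            fits[period] = OxidantPartition.from_daily(daily, period).fit()
        payload = {k: v.to_dict() for k, v in fits.items()}
        payload["day_vs_night"] = compare_day_night(fits["day"], fits["night"])
        emit_json("oxpartition.json", payload)

    # -- early warning -------------------------------------------------------
    warn_state: dict = {}

    @stage("lagged_table")
    def _lagged():
        warn_state["table"] = warn_mod.build_lagged_table(daily)

    if "table" in warn_state:
        table = warn_state["table"]

        @stage("screening")
        def _screening():
            emit_csv("screening.csv", warn_mod.screen_predictors(table))

        @stage("quadratic_model")
        def _model():
            res = warn_mod.fit_quadratic_model(table, cfg.target_metric)
            emit_json("warning_model.json", res.to_dict())

        @stage("warning_thresholds")
        def _thresholds():
            curves = {}
            for variable in ("o3_mean", "t_max"):
                curve = warn_mod.exceedance_rate_curve(
                    table, variable, cfg.standard, cfg.target_metric
                )
                curves[variable] = curve
                emit_csv(f"rate_curve_{variable}.csv", curve.to_frame(), index=False)
            thresholds = warn_mod.warning_thresholds(
                curves["o3_mean"], curves["t_max"]
            )
            emit_json("thresholds.json", thresholds.to_dict())

    manifest = {
        "config": _config_dict(cfg),
        "seed": cfg.seed,
        "station_label": series.station_label,
        "qa_replacements": qa_report,
        "stages": stages,
        "files": {p.name: _sha256(p) for p in sorted(files)},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
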