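"""CSV/JSON/TOML handling and the end-to-end analysis pipeline.

The pipeline reproduces the study's three analysis products on any daily
series (observed or synthetic): the fitted model report (with the PACF df
selection table and AIC), the lag-specific and cumulative RR curves per
exposure percentile, and the descriptive tables (summary statistics and the
starred Spearman matrix).  Every artifact embeds the normalized
configuration and the seed, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DailySeries
from .descriptives import spearman_matrix, summarize
from .effects import summarize_curve
from .model import ModelSpec, PoissonDLNM
from .simulate import SimulationConfig, generate

__all__ = ["RunConfig", "read_daily_csv", "read_holidays", "run_pipeline"]

log = logging.getLogger("pollenlag")


def read_holidays(path) -> set[dt.date]:
    """One ISO date per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(dt.date.fromisoformat(line))
    return out


def read_daily_csv(path, holidays: set[dt.date] | None = None) -> DailySeries:
    """Load and validate a daily series table.

    Requires a header with at least date (ISO-8601), count and pollen
    columns; the calendar must be gap-free.  Day-of-week is derived from the
    date, the holiday flag from ``holidays`` when the file has no holiday
    column.
    """
    frame = pd.read_csv(path)
    return DailySeries.from_frame(frame, holidays=holidays)


@dataclasses.dataclass
class RunConfig:
    """Normalized pipeline configuration (TOML [simulation]/[model]/[output])."""

    input_csv: str | None = None
    holiday_file: str | None = None
    simulation: SimulationConfig | None = None
    spec: ModelSpec = dataclasses.field(default_factory=ModelSpec)
    out_dir: str = "pollenlag_out"
    probs: tuple[int, ...] = (5, 25, 50, 75, 95)
    grid_size: int = 50
    reference: float = 0.0
    zcrit: float = 1.96
    seed: int | None = None
    make_plots: bool = True

    @staticmethod
    def from_toml(path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = RunConfig()
        run = raw.get("run", {})
        for key in ("input_csv", "holiday_file", "out_dir", "grid_size", "reference", "zcrit", "seed", "make_plots"):
            if key in run:
                setattr(cfg, key, run[key])
        if "probs" in run:
            cfg.probs = tuple(int(p) for p in run["probs"])
        if "model" in raw:
            cfg.spec = ModelSpec(**{k: _tuplify(v) for k, v in raw["model"].items()})
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            if "start_date" in sim and isinstance(sim["start_date"], str):
                sim["start_date"] = dt.date.fromisoformat(sim["start_date"])
            if cfg.seed is not None:
                sim.setdefault("seed", cfg.seed)
            cfg.simulation = SimulationConfig(**{k: _tuplify(v) for k, v in sim.items()})
        return cfg

    def normalized(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # implicit in where the report lives; keeps reruns byte-identical
        if self.simulation is not None:
            d["simulation"] = _jsonable(dataclasses.asdict(self.simulation))
        d["spec"] = dataclasses.asdict(self.spec)
        return _jsonable(d)


def _tuplify(v):
    return tuple(_tuplify(x) for x in v) if isinstance(v, list) else v


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_curve_matrices(out: Path, tag: str, curves: dict, lags: np.ndarray) -> None:
    """Three CSVs (rr, ci_low, ci_high): rows = lags, one column per percentile."""
    for field in ("rr", "ci_low", "ci_high"):
        cols = {}
        for p, entry in curves.items():
            curve = entry[tag]
            cols[f"P{p} ({entry['exposure']:.1f})"] = getattr(curve, field)
        pd.DataFrame(cols, index=pd.Index(lags, name="lag")).to_csv(out / f"{tag}_{field}.csv")


def run_pipeline(config: RunConfig) -> dict:
    """simulate (optional) -> df selection -> fit -> effects -> tables -> disk.

    Returns a bundle dict with the series, results object, surfaces, curve
    summaries and the paths written.  Deterministic for a fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # -- stage: data
    if config.simulation is not None:
        sim_cfg = config.simulation
        if config.seed is not None and config.seed != sim_cfg.seed:
            sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
        series, truth = generate(sim_cfg)
        truth.to_json(out / "truth.json")
        bundle["truth"] = truth
        log.info("stage=simulate n=%d seed=%d", len(series), sim_cfg.seed)
    elif config.input_csv:
        holidays = read_holidays(config.holiday_file) if config.holiday_file else None
        series = read_daily_csv(config.input_csv, holidays=holidays)
        log.info("stage=read n=%d path=%s", len(series), config.input_csv)
    else:
        raise ValueError("config must provide input_csv or a [simulation] table")
    series.to_csv(out / "series.csv")
    bundle["series"] = series

    # -- stage: descriptives (Table 1/2 shapes)
    summary = summarize(series)
    summary.to_csv(out / "table1_summary.csv", index=False)
    corr = spearman_matrix(series)
    corr.stars().to_csv(out / "table2_spearman.csv")
    corr.rho_frame().to_csv(out / "table2_rho.csv")
    corr.p_frame().to_csv(out / "table2_p.csv")
    bundle["summary"] = summary
    bundle["spearman"] = corr
    log.info("stage=descriptives variables=%d", len(summary))

    # -- stage: fit (includes PACF df selection when time_df='auto')
    results = PoissonDLNM(series, config.spec).fit()
    bundle["results"] = results
    (out / "fit_summary.txt").write_text(results.summary() + "\n")
    with open(out / "fit.json", "w") as fh:
        json.dump(results.to_json_dict(), fh, indent=1)
    if results.df_score_table is not None:
        results.df_score_table.to_csv(out / "time_df_selection.csv", index=False)
    log.info("stage=fit time_df=%d aic=%.2f converged=%s", results.time_df, results.aic, results.converged)

    # -- stage: effect surfaces and percentile curves
    surface = results.predict_surface(grid_size=config.grid_size, reference=config.reference, zcrit=config.zcrit)
    bundle["surface"] = surface
    pd.DataFrame(surface.rr, index=pd.Index(surface.exposures, name="exposure"), columns=surface.lags).to_csv(
        out / "surface_rr.csv"
    )
    curves = results.percentile_effects(config.probs, reference=config.reference, zcrit=config.zcrit)
    bundle["curves"] = curves
    _write_curve_matrices(out, "specific", curves, surface.lags)
    _write_curve_matrices(out, "cumulative", curves, surface.lags)

    summaries = {}
    for p, entry in curves.items():
        summaries[f"P{p}"] = {
            "exposure": entry["exposure"],
            "specific": dataclasses.asdict(summarize_curve(entry["specific"])),
            "cumulative": dataclasses.asdict(summarize_curve(entry["cumulative"])),
        }
    bundle["curve_summaries"] = summaries
    log.info("stage=effects percentiles=%s", list(curves))

    # -- stage: plots
    plots = []
    if config.make_plots:
        from . import plots as _plots

        plots = _plots.save_standard_plots(out, series, surface, curves)
    log.info("stage=plots files=%d", len(plots))

    report = {
        "config": config.normalized(),
        "fit": results.to_json_dict(),
        "time_df_table": None
        if results.df_score_table is None
        else results.df_score_table.to_dict(orient="records"),
        "percentile_exposures": {f"P{p}": entry["exposure"] for p, entry in curves.items()},
        "curve_summaries": summaries,
        "artifacts": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    bundle["report"] = report
    bundle["out_dir"] = out
    return bundle
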