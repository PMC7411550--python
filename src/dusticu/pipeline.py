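"""End-to-end orchestration: main analysis and sensitivity grids.

``run_main_analysis`` executes ingest -> linkage -> strata -> conditional
model for each endpoint; ``run_sensitivity`` repeats the fit over a grid of
confounder subsets, lag truncations and buffer distances, reporting sample
sizes per cell since buffer choices change row attrition.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ccmodel, ingest, linkage, strata, synthdata
from .exceptions import ConvergenceError, DegenerateDataError
from .ingest import RowLog

logger = logging.getLogger(__name__)

ENDPOINTS = ("all", "respiratory", "cardiovascular")

#: named confounder subsets for the sensitivity grid (the exact alternatives
#: are configurable; these defaults enumerate the natural lattice)
CONFOUNDER_SETS: dict[str, ccmodel.DesignSpec] = {
    "none": ccmodel.DesignSpec.dust_only(),
    "time": ccmodel.DesignSpec(
        temperature_lag0_df=0, temperature_lag1_df=0, dewpoint_df=0, pm25=False, ozone=False
    ),
    "time+temp+dew": ccmodel.DesignSpec(pm25=False, ozone=False),
    "time+pm25": ccmodel.DesignSpec(
        temperature_lag0_df=0, temperature_lag1_df=0, dewpoint_df=0, ozone=False
    ),
    "time+ozone": ccmodel.DesignSpec(
        temperature_lag0_df=0, temperature_lag1_df=0, dewpoint_df=0, pm25=False
    ),
    "time+temp+dew+pm25": ccmodel.DesignSpec(ozone=False),
    "time+temp+dew+ozone": ccmodel.DesignSpec(pm25=False),
    "time+pm25+ozone": ccmodel.DesignSpec(
        temperature_lag0_df=0, temperature_lag1_df=0, dewpoint_df=0
    ),
    "full": ccmodel.DesignSpec.main(),
}


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    synth: synthdata.SynthConfig | None = None
    input_dir: str | Path | None = None
    storm_buffer_km: float = 20.0
    monitor_buffer_km: float = 20.0
    max_lag: int = 5
    design: ccmodel.DesignSpec = field(default_factory=ccmodel.DesignSpec.main)
    endpoints: tuple[str, ...] = ENDPOINTS
    outdir: str | Path | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.storm_buffer_km <= 0 or self.monitor_buffer_km <= 0:
            raise ValueError("buffer distances must be positive")
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if self.synth is None and self.input_dir is None:
            raise ValueError("either a synth config or an input directory is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = synthdata.SynthConfig(**raw["synth"])
        if "design" in raw and raw["design"] is not None:
            d = raw["design"]
            raw["design"] = CONFOUNDER_SETS[d] if isinstance(d, str) else ccmodel.DesignSpec(**d)
        if "endpoints" in raw:
            raw["endpoints"] = tuple(raw["endpoints"])
        return cls(**raw)


@dataclass
class ResultsBundle:
    estimates: pd.DataFrame
    fits: dict[str, ccmodel.FitResult]
    associations: pd.DataFrame | None
    sample_sizes: dict[str, int]
    row_log: RowLog
    stratum_days: pd.DataFrame


def _load_inputs(config: RunConfig, log: RowLog):
    if config.synth is not None:
        synth = config.synth
        if config.seed is not None:
            synth = dataclasses.replace(synth, seed=config.seed)
        bundle = synthdata.generate_bundle(synth)
        return (
            bundle.storms,
            bundle.monitors,
            bundle.icu,
            bundle.zip_footprints,
            bundle.zone_footprints,
        )
    d = Path(config.input_dir)
    storms = ingest.read_storm_events(d / "storms.csv", log=log)
    monitors = ingest.read_monitor_daily(d / "monitors.csv", log=log)
    icu = ingest.read_icu_counts(d / "icu.csv", log=log)
    fps = linkage.read_footprints(d / "footprints.csv")
    return storms, monitors, icu, fps["zip"], fps["zone"]


def run_main_analysis(config: RunConfig) -> ResultsBundle:
    """Execute the full pipeline and return per-lag and window estimates."""
    log = RowLog()
    storms, monitors, icu, zip_fps, zone_fps = _load_inputs(config, log)

    dust = linkage.assign_storms_to_zips(
        storms, zone_fps, zip_fps, buffer_km=config.storm_buffer_km, log=log
    )
    exposures = linkage.aggregate_monitors_to_zip(
        monitors, zip_fps, buffer_km=config.monitor_buffer_km
    )
    strata_list = strata.build_strata(dust, max_lag=config.max_lag)
    days = strata.expand_stratum_days(
        strata_list, exposures=exposures, icu=icu, dust_table=dust, max_lag=config.max_lag
    )

    sample_sizes = {
        "n_storms": int(len(storms)),
        "n_dust_zip_days": int(len(dust)),
        "n_strata": int(len(strata_list)),
        "n_stratum_days": int(len(days)),
    }

    fits: dict[str, ccmodel.FitResult] = {}
    tables = []
    for endpoint in config.endpoints:
        ycol = f"count_{endpoint}"
        if ycol not in days.columns or days[ycol].fillna(0).sum() == 0:
            logger.warning("endpoint %s skipped: all counts zero or absent", endpoint)
            log.add(f"endpoint_{endpoint}_skipped_all_zero")
            continue
        try:
            fit, dm = ccmodel.fit_stratum_table(days, endpoint, config.design)
        except (DegenerateDataError, ConvergenceError) as exc:
            logger.error("endpoint %s failed in ccmodel: %s", endpoint, exc)
            log.add(f"endpoint_{endpoint}_fit_failed")
            continue
        log.add(f"endpoint_{endpoint}_rows_dropped_incomplete", len(days) - len(dm.rows))
        fits[endpoint] = fit
        tbl = ccmodel.lag_estimates_table(fit, max_lag=config.max_lag)
        tbl.insert(0, "endpoint", endpoint)
        tables.append(tbl)
        sample_sizes[f"n_days_{endpoint}"] = fit.n_days
        sample_sizes[f"n_strata_{endpoint}"] = fit.n_strata
        sample_sizes[f"n_admissions_{endpoint}"] = int(
            days[ycol].iloc[dm.rows].fillna(0).sum()
        )

    estimates = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=[
                "endpoint", "term", "estimate", "se", "percent",
                "ci_low", "ci_high", "p", "dispersion",
            ]
        )
    )
    result = ResultsBundle(
        estimates=estimates,
        fits=fits,
        associations=None,
        sample_sizes=sample_sizes,
        row_log=log,
        stratum_days=days,
    )
    if config.outdir is not None:
        _write_results(result, config.outdir)
    return result


def run_meta_associations(config: RunConfig, days: pd.DataFrame | None = None) -> pd.DataFrame:
    """Dust-day meteorology/pollution contrasts on the stratum-day table."""
    from . import metassoc

    if days is None:
        days = run_main_analysis(
            dataclasses.replace(config, outdir=None, endpoints=())
        ).stratum_days
    table = days.rename(columns={"dust_lag0": "dust"})
    return metassoc.association_table(table)


def _write_results(result: ResultsBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.estimates.to_csv(outdir / "estimates.csv", index=False)
    result.stratum_days.assign(
        date=pd.to_datetime(result.stratum_days["date"]).dt.strftime("%Y-%m-%d")
    ).to_csv(outdir / "strata.csv", index=False)
    (outdir / "run_log.json").write_text(
        json.dumps(
            {"sample_sizes": result.sample_sizes, "row_drops": result.row_log.as_dict()},
            indent=2,
        )
    )


@dataclass
class SensitivityGrid:
    confounders: tuple[str, ...] = tuple(CONFOUNDER_SETS)
    max_lags: tuple[int, ...] = (3, 4, 5)
    buffers: tuple[tuple[float, float], ...] = (
        (20.0, 20.0),
        (20.0, 10.0),
        (20.0, 50.0),
        (10.0, 20.0),
    )  # (storm_buffer_km, monitor_buffer_km)


def run_sensitivity(config: RunConfig, grid: SensitivityGrid | None = None) -> pd.DataFrame:
    """One fit per grid cell; per-cell failures are recorded, not fatal.

    Returns a long table keyed by (confounder set, max_lag, storm buffer,
    monitor buffer, endpoint, term) with estimates and per-cell sample
    sizes.
    """
    if grid is None:
        grid = SensitivityGrid()
    rows = []
    for (storm_b, monitor_b), max_lag, conf in itertools.product(
        grid.buffers, grid.max_lags, grid.confounders
    ):
        try:
            cell_cfg = dataclasses.replace(
                config,
                storm_buffer_km=storm_b,
                monitor_buffer_km=monitor_b,
                max_lag=max_lag,
                design=dataclasses.replace(CONFOUNDER_SETS[conf], lag_terms=max_lag + 1),
                outdir=None,
            )
            res = run_main_analysis(cell_cfg)
        except Exception as exc:  # per-cell robustness by contract
            logger.error(
                "sensitivity cell (%s, lag %d, buffers %s/%s) failed: %s",
                conf, max_lag, storm_b, monitor_b, exc,
            )
            rows.append(
                pd.DataFrame(
                    [{
                        "confounders": conf, "max_lag": max_lag,
                        "storm_buffer_km": storm_b, "monitor_buffer_km": monitor_b,
                        "error": str(exc),
                    }]
                )
            )
            continue
        tbl = res.estimates.copy()
        tbl.insert(0, "confounders", conf)
        tbl.insert(1, "max_lag", max_lag)
        tbl.insert(2, "storm_buffer_km", storm_b)
        tbl.insert(3, "monitor_buffer_km", monitor_b)
        for ep in config.endpoints:
            for key in ("n_days", "n_strata", "n_admissions"):
                col = f"{key}_{ep}"
                tbl.loc[tbl["endpoint"] == ep, key] = res.sample_sizes.get(col)
        rows.append(tbl)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
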