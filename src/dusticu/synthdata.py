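"""Synthetic storm calendars, environment series, and ICU counts.

The generator produces a drop-in replacement for the three proprietary /
bulk inputs of the analysis (storm events, daily monitor records, per-ZIP
daily ICU counts) together with simple rectangular ZIP and forecast-zone
footprints, with the statistical structure the analysis assumes:

* storms follow an inhomogeneous annual cycle (bimodal month weights,
  peaks in July-August with a secondary April bump) and afternoon-peaked
  begin hours;
* each environment variable is a seasonal sinusoid plus a ZIP-level
  intercept and daily noise, with configurable additive shifts on
  dust-exposed ZIP-days (defaults: PM10 +47.8 ug/m3, PM2.5 +3.7,
  temperature +2.38 F, dew point +2.34 F, ozone -0.52 ppb,
  precipitation 0);
* ICU counts are overdispersed Poisson (gamma-mixture, variance =
  overdispersion x mean) with mean
  baseline x day-of-week x ZIP effect x prod_k lag_rr[k]^dust(d-k).

Counts are drawn for three disjoint components (respiratory,
cardiovascular, other); the reported ``all`` endpoint is their sum, so the
per-day count invariants (respiratory <= all, cardiovascular <= all) hold
exactly.

ZIP footprints are axis-aligned rectangles on a lon/lat grid; forecast
zones are bounding boxes of 2x2 blocks of ZIPs.  With the default 40 km
grid spacing and 10 km rectangles, the 20 km linkage buffer recovers
exactly the zone-membership exposure truth recorded in the bundle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .linkage import ENV_VARIABLES, KM_PER_DEG, Footprint, write_footprints

COMPONENTS = ("respiratory", "cardiovascular", "other")

#: month weights: bimodal, July-August peak with a secondary April bump
DEFAULT_MONTH_WEIGHTS = (2, 2, 3, 6, 4, 3, 10, 10, 4, 2, 2, 2)

DEFAULT_ENV_OFFSETS = {
    "temperature": 2.38,
    "dewpoint": 2.34,
    "precipitation": 0.0,
    "pm25": 3.7,
    "pm10": 47.8,
    "ozone": -0.52,
}

#: (annual mean, seasonal amplitude, daily noise sd, between-ZIP sd)
_ENV_PROFILES = {
    "temperature": (72.0, 18.0, 5.0, 3.0),
    "dewpoint": (45.0, 10.0, 4.0, 3.0),
    "pm25": (9.0, 2.0, 3.0, 1.5),
    "pm10": (33.0, 8.0, 8.0, 5.0),
    "ozone": (50.0, 10.0, 6.0, 4.0),
}

_GRID_ORIGIN = (-112.0, 33.0)  # lon, lat of the ZIP grid origin


@dataclass
class SynthConfig:
    """Parameters of the synthetic world.

    ``storm_rate`` is the expected number of storms per ZIP and year;
    ``env_offsets`` are the dust-day additive shifts per environment
    variable; ``baseline_mean`` and ``lag_rr`` are keyed by count
    component; ``monitor_missing_rate`` deletes monitor-days per variable
    (the PM2.5 default emulates 1-in-3 sampling).
    """

    n_zips: int = 24
    zip_spacing_km: float = 40.0
    zip_size_km: float = 10.0
    years: tuple[int, int] = (2000, 2015)
    storm_rate: float = 1.0
    month_weights: tuple[float, ...] = DEFAULT_MONTH_WEIGHTS
    env_offsets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ENV_OFFSETS))
    baseline_mean: dict[str, float] = field(
        default_factory=lambda: {"respiratory": 0.7, "cardiovascular": 1.6, "other": 0.4}
    )
    dow_effects: tuple[float, ...] = (1.08, 1.10, 1.10, 1.08, 1.05, 0.82, 0.77)
    lag_rr: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "respiratory": (1.092, 1.0, 1.0, 1.0, 1.0, 1.075),
            "cardiovascular": (1.0,) * 6,
            "other": (1.0,) * 6,
        }
    )
    zip_effect_sd: float = 0.25
    overdispersion: float = 1.5
    monitor_missing_rate: dict[str, float] = field(default_factory=lambda: {"pm25": 2.0 / 3.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.month_weights) != 12 or any(w < 0 for w in self.month_weights):
            raise ValueError("month_weights must be 12 nonnegative values")
        total = float(sum(self.month_weights))
        if total <= 0:
            raise ValueError("month_weights must not all be zero")
        self.month_weights = tuple(w / total for w in self.month_weights)
        for comp, rr in self.lag_rr.items():
            if len(rr) != 6:
                raise ValueError(f"lag_rr[{comp!r}] must have exactly 6 entries (lags 0-5)")
            if any(r <= 0 for r in rr):
                raise ValueError(f"lag_rr[{comp!r}] entries must be positive")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("years", "month_weights", "dow_effects"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "lag_rr" in raw:
            raw["lag_rr"] = {k: tuple(v) for k, v in raw["lag_rr"].items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticBundle:
    storms: pd.DataFrame
    monitors: pd.DataFrame
    icu: pd.DataFrame
    zip_footprints: dict[str, Footprint]
    zone_footprints: dict[str, Footprint]
    zone_members: dict[str, list[str]]
    dust_days: pd.DataFrame  # exposure truth: (zip, date, dust=1)
    config: SynthConfig


# ---------------------------------------------------------------------------
# geometry


def generate_footprints(
    config: SynthConfig,
) -> tuple[dict[str, Footprint], dict[str, Footprint], dict[str, list[str]]]:
    """Rectangular ZIP footprints on a grid and 2x2-block zone footprints."""
    lon0, lat0 = _GRID_ORIGIN
    ncols = max(1, math.ceil(math.sqrt(config.n_zips)))
    dlat = config.zip_spacing_km / KM_PER_DEG
    dlon = config.zip_spacing_km / (KM_PER_DEG * math.cos(math.radians(lat0)))
    half_lat = (config.zip_size_km / 2.0) / KM_PER_DEG
    half_lon = (config.zip_size_km / 2.0) / (KM_PER_DEG * math.cos(math.radians(lat0)))

    zips: dict[str, Footprint] = {}
    zone_members: dict[str, list[str]] = {}
    for i in range(config.n_zips):
        r, c = divmod(i, ncols)
        clon = lon0 + c * dlon
        clat = lat0 + r * dlat
        key = f"{84001 + i}"
        zips[key] = Footprint(
            key=key,
            kind="zip",
            points=[
                (clon - half_lon, clat - half_lat),
                (clon + half_lon, clat - half_lat),
                (clon + half_lon, clat + half_lat),
                (clon - half_lon, clat + half_lat),
            ],
        )
        zone_key = f"Z{(r // 2) * ((ncols + 1) // 2) + (c // 2):03d}"
        zone_members.setdefault(zone_key, []).append(key)

    zones: dict[str, Footprint] = {}
    for zone_key, members in zone_members.items():
        lons = [p[0] for m in members for p in zips[m].points]
        lats = [p[1] for m in members for p in zips[m].points]
        zones[zone_key] = Footprint(
            key=zone_key,
            kind="zone",
            points=[
                (min(lons), min(lats)),
                (max(lons), min(lats)),
                (max(lons), max(lats)),
                (min(lons), max(lats)),
            ],
        )
    return zips, zones, zone_members


# ---------------------------------------------------------------------------
# storms


def generate_storm_calendar(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a storm calendar from the configured inhomogeneous annual cycle.

    The number of storms is Poisson with mean storm_rate x n_zips x n_years;
    months follow ``month_weights``, the day is uniform within the month,
    the begin hour is afternoon-peaked, and each storm lands in one
    uniformly chosen forecast zone.
    """
    if config.storm_rate <= 0:
        raise ValueError("storm_rate must be positive")
    _, _, zone_members = generate_footprints(config)
    zone_keys = sorted(zone_members)
    y0, y1 = config.years
    n_years = y1 - y0 + 1
    n_storms = int(rng.poisson(config.storm_rate * config.n_zips * n_years))

    years = rng.integers(y0, y1 + 1, size=n_storms)
    months = rng.choice(np.arange(1, 13), size=n_storms, p=np.asarray(config.month_weights))
    days_in_month = pd.to_datetime(
        {"year": years, "month": months, "day": np.ones(n_storms, dtype=int)}
    ).dt.days_in_month.to_numpy()
    days = 1 + (rng.random(n_storms) * days_in_month).astype(int)
    hours = np.clip(np.round(rng.normal(14.5, 2.5, size=n_storms)), 0, 23).astype(int)
    zones = rng.choice(zone_keys, size=n_storms)

    out = pd.DataFrame(
        {
            "event_id": [f"S{i:06d}" for i in range(n_storms)],
            "zone_id": zones,
            "state": "SYNTHETIC",
            "begin_date": pd.to_datetime({"year": years, "month": months, "day": days}),
            "begin_hour": hours,
            "event_type": "Dust Storm",
        }
    )
    return out.sort_values(["begin_date", "zone_id", "event_id"]).reset_index(drop=True)


def dust_days_from_storms(
    storms: pd.DataFrame, zone_members: dict[str, list[str]]
) -> pd.DataFrame:
    """Exposure truth: every member ZIP of a storm's zone on its begin date."""
    rows = [
        (z, pd.Timestamp(s.begin_date).normalize())
        for s in storms.itertuples(index=False)
        for z in zone_members.get(str(s.zone_id), [])
    ]
    out = pd.DataFrame(rows, columns=["zip", "date"]).drop_duplicates()
    out["dust"] = 1
    return out.sort_values(["zip", "date"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# environment


def generate_environment(
    config: SynthConfig,
    storms: pd.DataFrame,
    rng: np.random.Generator,
    footprints=None,
) -> pd.DataFrame:
    """Daily monitor records: sinusoidal seasonality + ZIP intercept + noise.

    One monitor sits at each ZIP centroid.  The configured ``env_offsets``
    are added on dust-exposed ZIP-days; monitor-days are then deleted per
    variable at ``monitor_missing_rate``.
    """
    if footprints is None:
        zips, _, zone_members = generate_footprints(config)
    else:
        zips, _, zone_members = footprints
    dust = dust_days_from_storms(storms, zone_members)
    dust_by_zip = {z: set(g["date"]) for z, g in dust.groupby("zip")}

    y0, y1 = config.years
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    phase = 2.0 * np.pi * (doy - 200) / 365.25  # warm-season peak

    frames = []
    for zip_key in sorted(zips):
        lon, lat = zips[zip_key].centroid
        dust_mask = np.array([d in dust_by_zip.get(zip_key, ()) for d in dates])
        values = {}
        for var, (mean, amp, noise_sd, zip_sd) in _ENV_PROFILES.items():
            zip_eff = rng.normal(0.0, zip_sd)
            v = mean + amp * np.cos(phase) + zip_eff + rng.normal(0.0, noise_sd, size=len(dates))
            v = v + config.env_offsets.get(var, 0.0) * dust_mask
            if var in ("pm25", "pm10", "ozone"):
                v = np.maximum(v, 0.0)
            values[var] = v
        wet = rng.random(len(dates)) < 0.15
        precip = np.where(wet, rng.exponential(3.0, size=len(dates)), 0.0)
        precip = precip + config.env_offsets.get("precipitation", 0.0) * dust_mask
        values["precipitation"] = np.maximum(precip, 0.0)

        frame = pd.DataFrame(
            {
                "monitor_id": f"M{zip_key}",
                "lon": lon,
                "lat": lat,
                "date": np.tile(dates, len(ENV_VARIABLES)),
                "variable": np.repeat(list(ENV_VARIABLES), len(dates)),
                "value": np.concatenate([values[v] for v in ENV_VARIABLES]),
            }
        )
        for var, rate in config.monitor_missing_rate.items():
            if rate <= 0:
                continue
            var_mask = frame["variable"] == var
            drop = rng.random(len(frame)) < rate
            frame = frame[~(var_mask & drop)]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# ICU counts


def _overdispersed_poisson(
    rng: np.random.Generator, mean: np.ndarray, phi: float
) -> np.ndarray:
    """Gamma-mixture (negative binomial) counts with variance = phi * mean."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 1.0:
        return rng.poisson(mean)
    shape = mean / (phi - 1.0)
    lam = np.where(mean > 0, rng.gamma(np.maximum(shape, 1e-12)) * (phi - 1.0), 0.0)
    return rng.poisson(lam)


def generate_icu_counts(
    config: SynthConfig, exposures: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw daily ICU counts for every ZIP-day in ``exposures``.

    ``exposures`` must carry (zip, date, dust) rows covering the ZIP-days
    to simulate.  Counts for each component follow the distributed-lag
    relative risks in ``config.lag_rr``; endpoints reported are
    respiratory, cardiovascular and all = respiratory + cardiovascular +
    other.
    """
    for comp in COMPONENTS:
        if len(config.lag_rr.get(comp, ())) != 6:
            raise ValueError(f"lag_rr[{comp!r}] must have exactly 6 entries")

    expo = exposures[["zip", "date", "dust"]].copy()
    expo["date"] = pd.to_datetime(expo["date"]).dt.normalize()
    expo = expo.drop_duplicates(["zip", "date"]).sort_values(["zip", "date"])

    zip_keys = sorted(expo["zip"].unique())
    zip_effects = {z: math.exp(rng.normal(0.0, config.zip_effect_sd)) for z in zip_keys}
    dow = np.asarray(config.dow_effects)

    pieces = []
    for zip_key, grp in expo.groupby("zip", sort=True):
        grp = grp.set_index("date").sort_index()
        full = pd.date_range(grp.index.min(), grp.index.max(), freq="D")
        dust_series = grp["dust"].reindex(full, fill_value=0).to_numpy(dtype=float)
        weekday = full.weekday.to_numpy()
        present = np.isin(full, grp.index)

        counts = {}
        for comp in COMPONENTS:
            log_rr = np.zeros(len(full))
            for k, rr in enumerate(config.lag_rr[comp]):
                if rr == 1.0:
                    continue
                shifted = np.zeros(len(full))
                shifted[k:] = dust_series[: len(full) - k] if k else dust_series
                log_rr += math.log(rr) * shifted
            mean = (
                config.baseline_mean.get(comp, 0.0)
                * dow[weekday]
                * zip_effects[zip_key]
                * np.exp(log_rr)
            )
            counts[comp] = _overdispersed_poisson(rng, mean, config.overdispersion)

        frame = pd.DataFrame(
            {
                "date": full,
                "respiratory": counts["respiratory"],
                "cardiovascular": counts["cardiovascular"],
                "all": counts["respiratory"] + counts["cardiovascular"] + counts["other"],
            }
        )[present]
        frame.insert(0, "zip", zip_key)
        pieces.append(frame)

    wide = pd.concat(pieces, ignore_index=True)
    out = wide.melt(id_vars=["zip", "date"], var_name="endpoint", value_name="count")
    out["count"] = out["count"].astype(int)
    return out.sort_values(["zip", "date", "endpoint"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# bundle


def generate_bundle(config: SynthConfig) -> SyntheticBundle:
    """Generate the full synthetic world from one seed, deterministically."""
    rng = np.random.default_rng(config.seed)
    rng_storm, rng_env, rng_icu = rng.spawn(3)

    zips, zones, zone_members = generate_footprints(config)
    storms = generate_storm_calendar(config, rng_storm)
    monitors = generate_environment(config, storms, rng_env, footprints=(zips, zones, zone_members))
    dust = dust_days_from_storms(storms, zone_members)

    y0, y1 = config.years
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    grid = pd.MultiIndex.from_product([sorted(zips), dates], names=["zip", "date"]).to_frame(
        index=False
    )
    dust_key = set(zip(dust["zip"], dust["date"]))
    grid["dust"] = [1 if (z, d) in dust_key else 0 for z, d in zip(grid["zip"], grid["date"])]
    icu = generate_icu_counts(config, grid, rng_icu)

    return SyntheticBundle(
        storms=storms,
        monitors=monitors,
        icu=icu,
        zip_footprints=zips,
        zone_footprints=zones,
        zone_members=zone_members,
        dust_days=dust,
        config=config,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write the bundle in the canonical CSV formats the ingest module reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "storms": outdir / "storms.csv",
        "monitors": outdir / "monitors.csv",
        "icu": outdir / "icu.csv",
        "footprints": outdir / "footprints.csv",
        "truth": outdir / "truth.json",
    }
    storms = bundle.storms.copy()
    storms["begin_date"] = pd.to_datetime(storms["begin_date"]).dt.strftime("%Y-%m-%d")
    storms.to_csv(paths["storms"], index=False)
    monitors = bundle.monitors.copy()
    monitors["date"] = pd.to_datetime(monitors["date"]).dt.strftime("%Y-%m-%d")
    monitors.to_csv(paths["monitors"], index=False)
    icu = bundle.icu.copy()
    icu["date"] = pd.to_datetime(icu["date"]).dt.strftime("%Y-%m-%d")
    icu.to_csv(paths["icu"], index=False)
    write_footprints(
        {"zip": bundle.zip_footprints, "zone": bundle.zone_footprints}, paths["footprints"]
    )
    truth = {
        "config": bundle.config.to_dict(),
        "zone_members": bundle.zone_members,
        "n_dust_zip_days": int(len(bundle.dust_days)),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, default=str))
    return paths
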