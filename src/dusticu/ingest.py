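"""Reading and validating the tabular inputs.

Canonical UTF-8 CSV schemas (header row):

* ``storms.csv``   — event_id, zone_id, state, begin_date (ISO-8601),
  begin_hour, event_type
* ``monitors.csv`` — monitor_id, lon, lat, date, variable, value
* ``icu.csv``      — zip, date, endpoint, count

Real NWS Storm Events and EPA AQS daily-summary exports vary by vintage, so
they are mapped onto the canonical schemas through small adapter
configurations rather than dedicated code paths.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger(__name__)

ENDPOINTS = ("all", "respiratory", "cardiovascular")

#: states excluded from the storm record: Saharan incursions in the
#: Caribbean territories and the two isolated reports east of the Mississippi
DEFAULT_EXCLUDED_STATES = (
    "PUERTO RICO",
    "VIRGIN ISLANDS",
    "U.S. VIRGIN ISLANDS",
    "INDIANA",
    "DELAWARE",
)

#: EPA AQS parameter codes for the pollutant variables
AQS_VARIABLE_MAP = {"88101": "pm25", "81102": "pm10", "44201": "ozone"}

_CANONICAL_VARIABLES = ("temperature", "dewpoint", "precipitation", "pm25", "pm10", "ozone")


class RowLog:
    """Machine-readable accounting of row-level filtering decisions."""

    def __init__(self) -> None:
        self.counts: Counter[str] = Counter()

    def add(self, reason: str, n: int = 1) -> None:
        if n:
            self.counts[reason] += int(n)

    def total(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RowLog({dict(self.counts)})"


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    for col in cols:
        if col not in df.columns:
            raise FormatError(f"{what}: missing required column: {col!r}")


def nws_storm_adapter(df: pd.DataFrame, log: RowLog | None = None) -> pd.DataFrame:
    """Map an NWS Storm Events export onto the canonical storm schema.

    Keeps zone-referenced rows (CZ_TYPE == "Z"); the zone key is
    ``STATE_FIPS-CZ_FIPS`` when STATE_FIPS is present, else CZ_FIPS.
    """
    _require_columns(
        df, ["BEGIN_YEARMONTH", "BEGIN_DAY", "EVENT_TYPE", "STATE", "CZ_FIPS"], "NWS storms"
    )
    out = df.copy()
    if "CZ_TYPE" in out.columns:
        n0 = len(out)
        out = out[out["CZ_TYPE"].astype(str).str.upper() == "Z"]
        if log is not None:
            log.add("storm_not_zone_referenced", n0 - len(out))
    ym = out["BEGIN_YEARMONTH"].astype(str)
    day = out["BEGIN_DAY"].astype(str).str.zfill(2)
    begin_date = ym.str.slice(0, 4) + "-" + ym.str.slice(4, 6) + "-" + day
    if "STATE_FIPS" in out.columns:
        zone = out["STATE_FIPS"].astype(str) + "-" + out["CZ_FIPS"].astype(str)
    else:
        zone = out["CZ_FIPS"].astype(str)
    begin_hour = (
        pd.to_numeric(out["BEGIN_TIME"], errors="coerce") // 100
        if "BEGIN_TIME" in out.columns
        else np.nan
    )
    event_id = out["EVENT_ID"] if "EVENT_ID" in out.columns else np.arange(len(out))
    return pd.DataFrame(
        {
            "event_id": event_id.astype(str),
            "zone_id": zone,
            "state": out["STATE"].astype(str),
            "begin_date": begin_date,
            "begin_hour": begin_hour,
            "event_type": out["EVENT_TYPE"].astype(str),
        }
    )


def read_storm_events(
    path,
    event_type_filter: str = "Dust Storm",
    excluded_states=DEFAULT_EXCLUDED_STATES,
    excluded_zones=(),
    adapter=None,
    log: RowLog | None = None,
) -> pd.DataFrame:
    """Read and filter the storm-event table.

    Only rows whose event type equals ``event_type_filter`` exactly and whose
    state / zone is not excluded are retained.  Rows with unparseable begin
    dates are rejected with a logged reason.

    ``adapter`` may be ``None`` (canonical schema), ``"nws"`` (raw NWS Storm
    Events columns), a column-rename mapping, or a callable
    ``DataFrame -> DataFrame``.
    """
    df = pd.read_csv(path, dtype=str)
    if adapter == "nws":
        df = nws_storm_adapter(df, log)
    elif callable(adapter):
        df = adapter(df)
    elif isinstance(adapter, Mapping):
        df = df.rename(columns=dict(adapter))
    _require_columns(df, ["event_id", "zone_id", "state", "begin_date", "event_type"], "storms")
    if "begin_hour" not in df.columns:
        df["begin_hour"] = np.nan

    n0 = len(df)
    df = df[df["event_type"] == event_type_filter]
    if log is not None:
        log.add("storm_event_type_filtered", n0 - len(df))

    excluded_upper = {s.upper() for s in excluded_states}
    n0 = len(df)
    df = df[~df["state"].astype(str).str.upper().str.strip().isin(excluded_upper)]
    if log is not None:
        log.add("storm_state_excluded", n0 - len(df))

    n0 = len(df)
    df = df[~df["zone_id"].astype(str).isin({str(z) for z in excluded_zones})]
    if log is not None:
        log.add("storm_zone_excluded", n0 - len(df))

    dates = pd.to_datetime(df["begin_date"], errors="coerce")
    n_bad = int(dates.isna().sum())
    if n_bad:
        logger.warning("rejected %d storm rows with unparseable begin dates", n_bad)
        if log is not None:
            log.add("storm_bad_date", n_bad)
    df = df[dates.notna()].copy()
    df["begin_date"] = dates[dates.notna()]
    df["begin_hour"] = pd.to_numeric(df["begin_hour"], errors="coerce")
    return df[["event_id", "zone_id", "state", "begin_date", "begin_hour", "event_type"]].reset_index(
        drop=True
    )


def read_monitor_daily(
    path, variable_map: Mapping[str, str] | None = None, log: RowLog | None = None
) -> pd.DataFrame:
    """Read daily monitor records (24-h averages, local time).

    ``variable_map`` maps source variable/parameter codes to the canonical
    set; unknown codes are skipped with a warning and counted.  Negative PM
    values are rejected.  Duplicated monitor-variable-days are collapsed to
    their mean with a logged warning.
    """
    df = pd.read_csv(path, dtype={"monitor_id": str, "variable": str})
    _require_columns(df, ["monitor_id", "lon", "lat", "date", "variable", "value"], "monitors")
    if variable_map is not None:
        mapped = df["variable"].map(dict(variable_map))
    else:
        mapped = df["variable"].where(df["variable"].isin(_CANONICAL_VARIABLES))
    n_unknown = int(mapped.isna().sum())
    if n_unknown:
        logger.warning("skipped %d monitor rows with unknown variable codes", n_unknown)
        if log is not None:
            log.add("monitor_unknown_variable", n_unknown)
    df = df[mapped.notna()].copy()
    df["variable"] = mapped[mapped.notna()]

    df["date"] = pd.to_datetime(df["date"], errors="coerce")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    n_bad = int(df["date"].isna().sum() + df["value"].isna().sum())
    if log is not None:
        log.add("monitor_unparseable", n_bad)
    df = df.dropna(subset=["date", "value"])

    neg_pm = df["variable"].isin(["pm25", "pm10"]) & (df["value"] < 0)
    if neg_pm.any():
        logger.warning("rejected %d negative PM monitor values", int(neg_pm.sum()))
        if log is not None:
            log.add("monitor_negative_pm", int(neg_pm.sum()))
    df = df[~neg_pm]

    key = ["monitor_id", "date", "variable"]
    n_dup = int(df.duplicated(key).sum())
    if n_dup:
        logger.warning("collapsed %d duplicated monitor-variable-days by mean", n_dup)
        if log is not None:
            log.add("monitor_duplicates_collapsed", n_dup)
    out = (
        df.groupby(key, sort=True, as_index=False)
        .agg(lon=("lon", "first"), lat=("lat", "first"), value=("value", "mean"))
    )
    return out[["monitor_id", "lon", "lat", "date", "variable", "value"]]


def read_icu_counts(path, log: RowLog | None = None) -> pd.DataFrame:
    """Read per-ZIP daily ICU counts (endpoints: all, respiratory, cardiovascular)."""
    df = pd.read_csv(path, dtype={"zip": str, "endpoint": str})
    _require_columns(df, ["zip", "date", "endpoint", "count"], "icu")
    df["date"] = pd.to_datetime(df["date"], errors="coerce")
    df["count"] = pd.to_numeric(df["count"], errors="coerce")
    bad = (
        df["date"].isna()
        | df["count"].isna()
        | (df["count"] < 0)
        | (df["count"] % 1 != 0)
        | ~df["endpoint"].isin(ENDPOINTS)
    )
    if bad.any():
        logger.warning("rejected %d invalid ICU rows", int(bad.sum()))
        if log is not None:
            log.add("icu_invalid_rows", int(bad.sum()))
    df = df[~bad].copy()
    df["count"] = df["count"].astype(int)

    wide = df.pivot_table(index=["zip", "date"], columns="endpoint", values="count", aggfunc="sum")
    for ep in ("respiratory", "cardiovascular"):
        if ep in wide.columns and "all" in wide.columns:
            n_violate = int((wide[ep] > wide["all"]).sum())
            if n_violate:
                logger.warning("%d ZIP-days with %s count exceeding all-cause count", n_violate, ep)
                if log is not None:
                    log.add(f"icu_{ep}_exceeds_all", n_violate)
    return df.sort_values(["zip", "date", "endpoint"]).reset_index(drop=True)


def summarize_admissions(counts, total=None) -> pd.DataFrame:
    """Per-category share of total admissions, rounded to integer percent.

    ``counts`` maps category name to admission count; ``total`` defaults to
    the sum of the counts (pass it explicitly for overlapping categories).
    """
    s = pd.Series(dict(counts), dtype=float)
    if (s < 0).any():
        raise ValueError("category counts must be nonnegative")
    grand = float(s.sum()) if total is None else float(total)
    if grand == 0:
        raise ZeroDivisionError("undefined proportions: zero grand total")
    out = pd.DataFrame({"count": s})
    out["percent"] = (100.0 * s / grand).round().astype(int)
    return out
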