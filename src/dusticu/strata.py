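"""Time-stratified case-crossover stratum construction.

A stratum is a ZIP x year x calendar-quarter cell containing at least one
dust-storm day.  Its index days are the dust days plus control days at
28-day intervals inside the same quarter (bidirectional, so the dust day's
weekday is conserved and each unmerged stratum holds two to three controls).
Days up to ``max_lag`` days after every index day are appended so lagged
exposure effects can be estimated; lag days crossing the quarter boundary
are retained and carry covariates from their true dates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL_INTERVAL_DAYS = 28


def season_of(date) -> tuple[int, int]:
    """(year, quarter) with quarters Jan-Mar=1 ... Oct-Dec=4."""
    ts = pd.Timestamp(date)
    return ts.year, (ts.month - 1) // 3 + 1


def candidate_control_days(dust_date, interval: int = CONTROL_INTERVAL_DAYS) -> list[pd.Timestamp]:
    """All dates at +/- 28k days from the dust date within its year-quarter.

    Excludes the dust date itself.  Because 28 is a multiple of 7, every
    control shares the dust day's weekday.
    """
    d0 = pd.Timestamp(dust_date).normalize()
    cell = season_of(d0)
    out = []
    for sign in (-1, 1):
        k = 1
        while True:
            d = d0 + pd.Timedelta(days=sign * interval * k)
            if season_of(d) != cell:
                break
            out.append(d)
            k += 1
    return sorted(out)


@dataclass
class Stratum:
    stratum_id: str
    zip: str
    year: int
    quarter: int
    dust_days: frozenset
    index_days: frozenset
    all_days: frozenset

    @property
    def n_index_days(self) -> int:
        return len(self.index_days)


def build_strata(dust_days: pd.DataFrame, max_lag: int = 5) -> list[Stratum]:
    """One stratum per (zip, year, quarter) cell containing a dust day.

    Multiple dust storms in a cell are merged into a single stratum whose
    index days are the union of all dust days and their control days;
    ``all_days`` adds the +1..+max_lag follow-up of every index day,
    deduplicated.  Output order and content are independent of the input row
    order.
    """
    df = dust_days.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    df = df.drop_duplicates(subset=["zip", "date"]).sort_values(["zip", "date"])
    yq = df["date"].map(season_of)
    df["year"] = [t[0] for t in yq]
    df["quarter"] = [t[1] for t in yq]

    strata = []
    for (zip_key, year, quarter), grp in df.groupby(["zip", "year", "quarter"], sort=True):
        dust = set(grp["date"])
        index_days = set(dust)
        for d in dust:
            index_days.update(candidate_control_days(d))
        all_days = set(index_days)
        for d in index_days:
            for k in range(1, max_lag + 1):
                all_days.add(d + pd.Timedelta(days=k))
        strata.append(
            Stratum(
                stratum_id=f"{zip_key}:{year}Q{quarter}",
                zip=str(zip_key),
                year=int(year),
                quarter=int(quarter),
                dust_days=frozenset(dust),
                index_days=frozenset(index_days),
                all_days=frozenset(all_days),
            )
        )
    return strata


def expand_stratum_days(
    strata: list[Stratum],
    exposures: pd.DataFrame | None = None,
    icu: pd.DataFrame | None = None,
    dust_table: pd.DataFrame | None = None,
    max_lag: int = 5,
) -> pd.DataFrame:
    """One row per stratum-day with lagged dust indicators and joined data.

    ``dust_lag[k]`` is 1 iff a dust storm exposed the row's ZIP on
    ``date - k`` for k = 0..max_lag, computed against the full dust-day
    table (``dust_table``; defaults to the union of in-stratum dust days),
    so a day may carry several nonzero lags when storms occur close
    together.  ``exposures`` (wide ZIP-day covariates) contributes the
    environment variables plus ``temperature_lag1``; ``icu`` (long counts)
    contributes ``count_<endpoint>`` columns.  Strata with fewer than two
    index days are flagged non-informative.
    """
    if dust_table is not None:
        dd = dust_table.copy()
        dd["date"] = pd.to_datetime(dd["date"]).dt.normalize()
        dust_set = set(zip(dd["zip"].astype(str), dd["date"]))
    else:
        dust_set = {(s.zip, d) for s in strata for d in s.dust_days}

    rows = []
    for s in sorted(strata, key=lambda s: s.stratum_id):
        informative = s.n_index_days >= 2
        if not informative:
            logger.info("stratum %s has <2 index days; flagged non-informative", s.stratum_id)
        for day_number, date in enumerate(sorted(s.all_days), start=1):
            if date in s.dust_days:
                role = "dust"
            elif date in s.index_days:
                role = "control"
            else:
                role = "lag"
            lags = [
                1 if (s.zip, date - pd.Timedelta(days=k)) in dust_set else 0
                for k in range(max_lag + 1)
            ]
            rows.append(
                (
                    s.stratum_id,
                    s.zip,
                    s.year,
                    s.quarter,
                    date,
                    day_number,
                    role,
                    informative,
                    *lags,
                )
            )
    lag_cols = [f"dust_lag{k}" for k in range(max_lag + 1)]
    out = pd.DataFrame(
        rows,
        columns=[
            "stratum_id",
            "zip",
            "year",
            "quarter",
            "date",
            "day_number",
            "role",
            "informative",
            *lag_cols,
        ],
    )

    if exposures is not None:
        expo = exposures.copy()
        expo["date"] = pd.to_datetime(expo["date"])
        expo = expo.drop(columns=[c for c in ("dust",) if c in expo.columns])
        out = out.merge(expo, on=["zip", "date"], how="left")
        lag1 = expo[["zip", "date", "temperature"]].copy()
        lag1["date"] = lag1["date"] + pd.Timedelta(days=1)
        lag1 = lag1.rename(columns={"temperature": "temperature_lag1"})
        out = out.merge(lag1, on=["zip", "date"], how="left")

    if icu is not None:
        wide = (
            icu.assign(date=pd.to_datetime(icu["date"]))
            .pivot_table(index=["zip", "date"], columns="endpoint", values="count", aggfunc="sum")
            .rename(columns=lambda ep: f"count_{ep}")
            .reset_index()
        )
        out = out.merge(wide, on=["zip", "date"], how="left")

    return out.sort_values(["stratum_id", "date"]).reset_index(drop=True)
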