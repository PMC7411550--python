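"""Spatial linkage of storms and monitors to ZIP codes.

Dust storms are reported by weather forecast zone (WFZ).  A ZIP code is
considered exposed on a storm's begin date when its footprint intersects the
zone footprint or lies within a distance buffer (default 20 km) of it.
Monitor observations are aggregated to a ZIP-day value as the median over
all monitors located inside the ZIP footprint or within the buffer of its
centroid.

Footprints arrive as ordered lon/lat vertex lists.  Distances between
footprints are computed on a local equirectangular projection (kilometres),
which at buffer scales of tens of km is accurate to well below the buffer
tolerance; point-to-point distance uses the haversine formula on a sphere of
radius 6371 km.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .exceptions import DomainError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0

#: canonical environment variable names, in canonical column order
ENV_VARIABLES = ("temperature", "dewpoint", "precipitation", "pm25", "pm10", "ozone")

#: numerical slack on inclusive buffer comparisons (km)
_DIST_EPS = 1e-9


def _check_lonlat(lon: float, lat: float) -> None:
    if not (-180.0 <= lon <= 180.0) or not (-90.0 <= lat <= 90.0):
        raise DomainError(f"coordinates out of range: lon={lon}, lat={lat}")


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lon, lat) points.

    Symmetric, and zero iff the points coincide.  Raises :class:`DomainError`
    for coordinates outside [-180, 180] x [-90, 90].
    """
    lon1, lat1 = a
    lon2, lat2 = b
    _check_lonlat(lon1, lat1)
    _check_lonlat(lon2, lat2)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class Footprint:
    """A ZIP or forecast-zone footprint given as an ordered lon/lat vertex list."""

    key: str
    kind: str  # "zip" | "zone"
    points: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise DomainError(f"footprint {self.key!r} has no points")
        for lon, lat in self.points:
            _check_lonlat(lon, lat)

    @property
    def centroid(self) -> tuple[float, float]:
        lons = [p[0] for p in self.points]
        lats = [p[1] for p in self.points]
        return (sum(lons) / len(lons), sum(lats) / len(lats))

    def local_geometry(self, lon0: float, lat0: float):
        """Shapely geometry in km coordinates of a local equirectangular frame."""
        c = math.cos(math.radians(lat0))
        xy = [((lon - lon0) * KM_PER_DEG * c, (lat - lat0) * KM_PER_DEG) for lon, lat in self.points]
        if len(xy) == 1:
            return Point(xy[0])
        if len(xy) == 2:
            return LineString(xy)
        poly = Polygon(xy)
        if not poly.is_valid or poly.area == 0.0:
            return LineString(xy)
        return poly


def footprint_min_distance_km(a: Footprint, b: Footprint) -> float:
    """Minimum distance in km between two footprints (0 when they intersect)."""
    lon_a, lat_a = a.centroid
    lon_b, lat_b = b.centroid
    lon0, lat0 = (lon_a + lon_b) / 2.0, (lat_a + lat_b) / 2.0
    return a.local_geometry(lon0, lat0).distance(b.local_geometry(lon0, lat0))


def footprints_intersect(a: Footprint, b: Footprint) -> bool:
    lon0, lat0 = a.centroid
    return a.local_geometry(lon0, lat0).intersects(b.local_geometry(lon0, lat0))


def read_footprints(path) -> dict[str, dict[str, Footprint]]:
    """Read footprints.csv (kind, key, vertex_index, lon, lat).

    Returns ``{"zip": {key: Footprint}, "zone": {key: Footprint}}``.
    """
    df = pd.read_csv(path, dtype={"kind": str, "key": str})
    out: dict[str, dict[str, Footprint]] = {"zip": {}, "zone": {}}
    for (kind, key), grp in df.groupby(["kind", "key"], sort=True):
        grp = grp.sort_values("vertex_index")
        pts = list(zip(grp["lon"].astype(float), grp["lat"].astype(float)))
        out.setdefault(kind, {})[key] = Footprint(key=key, kind=kind, points=pts)
    return out


def write_footprints(footprints: dict[str, dict[str, Footprint]], path) -> None:
    rows = []
    for kind in sorted(footprints):
        for key in sorted(footprints[kind]):
            for i, (lon, lat) in enumerate(footprints[kind][key].points):
                rows.append((kind, key, i, lon, lat))
    pd.DataFrame(rows, columns=["kind", "key", "vertex_index", "lon", "lat"]).to_csv(
        path, index=False
    )


def assign_storms_to_zips(
    storms: pd.DataFrame,
    zone_footprints: dict[str, Footprint],
    zip_footprints: dict[str, Footprint],
    buffer_km: float = 20.0,
    log=None,
) -> pd.DataFrame:
    """Mark ZIP codes exposed on each storm's begin date.

    A ZIP is exposed iff its footprint intersects the storm's zone footprint
    or their minimum distance is <= ``buffer_km`` (inclusive).  Storms whose
    zone has no footprint are skipped with a logged count.  Returns a
    deduplicated table with columns (zip, date, dust=1), sorted by zip, date.
    """
    exposed_cache: dict[str, list[str]] = {}
    rows = []
    n_unknown = 0
    zip_keys = sorted(zip_footprints)
    for storm in storms.itertuples(index=False):
        zone_id = str(storm.zone_id)
        if zone_id not in zone_footprints:
            n_unknown += 1
            continue
        if zone_id not in exposed_cache:
            zone_fp = zone_footprints[zone_id]
            exposed_cache[zone_id] = [
                z
                for z in zip_keys
                if footprint_min_distance_km(zone_fp, zip_footprints[z])
                <= buffer_km + _DIST_EPS
            ]
        date = pd.Timestamp(storm.begin_date).normalize()
        for z in exposed_cache[zone_id]:
            rows.append((z, date))
    if n_unknown:
        logger.warning("skipped %d storms referencing unknown zones", n_unknown)
        if log is not None:
            log.add("storm_unknown_zone", n_unknown)
    out = pd.DataFrame(rows, columns=["zip", "date"]).drop_duplicates()
    out["dust"] = 1
    return out.sort_values(["zip", "date"]).reset_index(drop=True)


def _qualifying_monitors(
    monitors: pd.DataFrame, fp: Footprint, buffer_km: float
) -> list[str]:
    """Monitor ids inside the ZIP footprint or within buffer_km of its centroid."""
    lon0, lat0 = fp.centroid
    geom = fp.local_geometry(lon0, lat0)
    c = math.cos(math.radians(lat0))
    out = []
    coords = monitors.drop_duplicates("monitor_id")
    for m in coords.itertuples(index=False):
        pt = Point((m.lon - lon0) * KM_PER_DEG * c, (m.lat - lat0) * KM_PER_DEG)
        if geom.distance(pt) <= _DIST_EPS:
            out.append(m.monitor_id)
        elif haversine_km((m.lon, m.lat), (lon0, lat0)) <= buffer_km + _DIST_EPS:
            out.append(m.monitor_id)
    return out


def aggregate_monitors_to_zip(
    monitors: pd.DataFrame,
    zip_footprints: dict[str, Footprint],
    buffer_km: float = 20.0,
) -> pd.DataFrame:
    """Median-aggregate monitor records to a wide ZIP-day exposure table.

    For each ZIP-day-variable the value is the median over qualifying
    monitors (inside the footprint, or within ``buffer_km`` of the centroid);
    the cell is missing when no qualifying monitor reported.  Even-count
    medians are midpoints of the two central values.  Output columns:
    zip, date, then :data:`ENV_VARIABLES`.  Result is independent of input
    row order.
    """
    frames = []
    for zip_key in sorted(zip_footprints):
        ids = _qualifying_monitors(monitors, zip_footprints[zip_key], buffer_km)
        if not ids:
            continue
        sub = monitors[monitors["monitor_id"].isin(ids)]
        if sub.empty:
            continue
        wide = (
            sub.groupby(["date", "variable"], sort=True)["value"]
            .median()
            .unstack("variable")
            .reindex(columns=list(ENV_VARIABLES))
        )
        wide = wide.reset_index()
        wide.insert(0, "zip", zip_key)
        frames.append(wide)
    if not frames:
        return pd.DataFrame(columns=["zip", "date", *ENV_VARIABLES])
    out = pd.concat(frames, ignore_index=True)
    out["date"] = pd.to_datetime(out["date"])
    return out.sort_values(["zip", "date"]).reset_index(drop=True)


def attach_dust_indicator(exposures: pd.DataFrame, dust_days: pd.DataFrame) -> pd.DataFrame:
    """Add a 0/1 ``dust`` column to a wide exposure table."""
    key = set(zip(dust_days["zip"], pd.to_datetime(dust_days["date"])))
    out = exposures.copy()
    out["dust"] = [
        1 if (z, d) in key else 0 for z, d in zip(out["zip"], pd.to_datetime(out["date"]))
    ]
    return out
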