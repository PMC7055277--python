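"""Spatial gridding: project endpoints, bin into square cells, select
high-demand zones and compute inter-zone distances.

The city is covered by a grid of half-open square cells of side ``cell_side``
metres (default 100 m). A cell qualifies as a high-demand zone when at least
``M`` trips arrive AND at least ``M`` trips depart from it within the
analysis window; the retained zones and the trips between them define the
origin-destination network downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyResultError, InvalidConfigError

__all__ = [
    "GridSpec",
    "ZoneSet",
    "haversine_km",
    "project_point",
    "assign_zone",
    "count_endpoints",
    "select_high_demand",
    "restrict_trips",
    "zone_distances",
    "trip_distances_km",
]

#: metres per degree of latitude in the equirectangular projection
M_PER_DEG = 111_320.0
#: mean Earth radius (km) used by every great-circle computation
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GridSpec:
    """Half-open square grid anchored at its south-west corner.

    ``origin_lon``/``origin_lat`` give the lon/lat of the corner;
    ``reference_latitude`` fixes the metres-per-degree-of-longitude scale.
    Cells are [x, x+L) x [y, y+L) in the projected frame, indexed
    (row, col) from the south-west.
    """

    cell_side: float = 100.0
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    n_cols: int = 500
    n_rows: int = 500
    reference_latitude: float | None = None

    def __post_init__(self):
        if self.cell_side <= 0:
            raise InvalidConfigError("cell_side must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise InvalidConfigError("grid must have at least one cell")

    @property
    def ref_lat(self) -> float:
        return self.origin_lat if self.reference_latitude is None else self.reference_latitude


def project_point(lon, lat, grid: GridSpec):
    """Equirectangular projection of lon/lat (degrees) to grid metres.

    x = 111320 * cos(ref_lat) * (lon - origin_lon),
    y = 111320 * (lat - origin_lat).

    Non-finite coordinates project to NaN; callers treat those records as
    invalid and count them as exclusions.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = M_PER_DEG * np.cos(np.radians(grid.ref_lat)) * (lon - grid.origin_lon)
    y = M_PER_DEG * (lat - grid.origin_lat)
    return x, y


def assign_zone(x, y, grid: GridSpec):
    """Map projected points (metres) to (row, col) cell indices.

    Uses floor division with half-open cells. Returns (rows, cols, in_bounds)
    where out-of-bounds or non-finite points are flagged False and get index
    -1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    L = grid.cell_side
    finite = np.isfinite(x) & np.isfinite(y)
    cols = np.full(x.shape, -1, dtype=np.int64)
    rows = np.full(y.shape, -1, dtype=np.int64)
    cols[finite] = np.floor(x[finite] / L).astype(np.int64)
    rows[finite] = np.floor(y[finite] / L).astype(np.int64)
    in_bounds = (
        finite
        & (cols >= 0) & (cols < grid.n_cols)
        & (rows >= 0) & (rows < grid.n_rows)
    )
    cols[~in_bounds] = -1
    rows[~in_bounds] = -1
    return rows, cols, in_bounds


def count_endpoints(trips: pd.DataFrame, grid: GridSpec):
    """Per-cell departure and arrival count surfaces.

    ``trips`` must carry pickup/dropoff longitude/latitude columns (TLC-like
    schema). A trip contributes only if BOTH endpoints are in bounds; the
    number of excluded records is reported.

    Returns
    -------
    dict with 'origins' and 'destinations' (n_rows x n_cols int arrays),
    'n_in_bounds', 'n_excluded'.
    """
    px, py = project_point(trips["pickup_longitude"].to_numpy(),
                           trips["pickup_latitude"].to_numpy(), grid)
    dx, dy = project_point(trips["dropoff_longitude"].to_numpy(),
                           trips["dropoff_latitude"].to_numpy(), grid)
    pr, pc, p_ok = assign_zone(px, py, grid)
    dr, dc, d_ok = assign_zone(dx, dy, grid)
    ok = p_ok & d_ok
    shape = (grid.n_rows, grid.n_cols)
    origins = np.zeros(shape, dtype=np.int64)
    dests = np.zeros(shape, dtype=np.int64)
    np.add.at(origins, (pr[ok], pc[ok]), 1)
    np.add.at(dests, (dr[ok], dc[ok]), 1)
    return {
        "origins": origins,
        "destinations": dests,
        "n_in_bounds": int(ok.sum()),
        "n_excluded": int((~ok).sum()),
    }


@dataclass
class ZoneSet:
    """High-demand zones selected from the count surfaces.

    ``zone_id`` is a dense 0..N-1 index ordered by (row, col); centroids are
    cell centres, held both in grid metres and (if a grid is attached) in
    lon/lat. ``mode`` records which coordinate frame distances should use.
    """

    zone_id: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    centroids_xy_m: np.ndarray  # (N, 2) grid-frame metres
    arrivals: np.ndarray
    departures: np.ndarray
    threshold: int
    mode: str = "lonlat"  # 'lonlat' or 'planar'
    centroids_lonlat: np.ndarray | None = field(default=None)

    def __len__(self):
        return len(self.zone_id)


def select_high_demand(counts: dict, M: int, grid: GridSpec | None = None) -> ZoneSet:
    """Zones where arrivals >= M AND departures >= M.

    Raises EmptyResultError (with diagnostic maxima) when nothing survives.
    """
    if M < 1:
        raise InvalidConfigError("M must be >= 1")
    origins = counts["origins"]
    dests = counts["destinations"]
    keep = (origins >= M) & (dests >= M)
    rows, cols = np.nonzero(keep)
    if rows.size == 0:
        raise EmptyResultError(
            f"no zone has arrivals and departures >= {M} "
            f"(max departures={int(origins.max())}, max arrivals={int(dests.max())})"
        )
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    L = grid.cell_side if grid is not None else 100.0
    xy = np.column_stack(((cols + 0.5) * L, (rows + 0.5) * L))
    lonlat = None
    mode = "planar"
    if grid is not None:
        lon = grid.origin_lon + xy[:, 0] / (M_PER_DEG * np.cos(np.radians(grid.ref_lat)))
        lat = grid.origin_lat + xy[:, 1] / M_PER_DEG
        lonlat = np.column_stack((lon, lat))
        mode = "lonlat"
    return ZoneSet(
        zone_id=np.arange(rows.size, dtype=np.int64),
        rows=rows.astype(np.int64),
        cols=cols.astype(np.int64),
        centroids_xy_m=xy,
        arrivals=dests[rows, cols].astype(np.int64),
        departures=origins[rows, cols].astype(np.int64),
        threshold=int(M),
        mode=mode,
        centroids_lonlat=lonlat,
    )


def restrict_trips(trips: pd.DataFrame, zoneset: ZoneSet, grid: GridSpec):
    """Keep trips with both endpoints in selected zones; annotate zone ids.

    Returns (restricted DataFrame with 'origin_zone'/'dest_zone' columns,
    retained fraction relative to the in-bounds trip count).
    """
    if len(zoneset) == 0:
        raise InvalidConfigError("zoneset is empty")
    px, py = project_point(trips["pickup_longitude"].to_numpy(),
                           trips["pickup_latitude"].to_numpy(), grid)
    dx, dy = project_point(trips["dropoff_longitude"].to_numpy(),
                           trips["dropoff_latitude"].to_numpy(), grid)
    pr, pc, p_ok = assign_zone(px, py, grid)
    dr, dc, d_ok = assign_zone(dx, dy, grid)
    ok = p_ok & d_ok
    lut = np.full((int(zoneset.rows.max()) + 1, int(zoneset.cols.max()) + 1), -1,
                  dtype=np.int64)
    lut[zoneset.rows, zoneset.cols] = zoneset.zone_id
    o_zone = np.full(len(trips), -1, dtype=np.int64)
    d_zone = np.full(len(trips), -1, dtype=np.int64)
    sel = ok & (pr <= zoneset.rows.max()) & (pc <= zoneset.cols.max())
    o_zone[sel] = lut[pr[sel], pc[sel]]
    sel = ok & (dr <= zoneset.rows.max()) & (dc <= zoneset.cols.max())
    d_zone[sel] = lut[dr[sel], dc[sel]]
    keep = (o_zone >= 0) & (d_zone >= 0)
    out = trips.loc[keep].copy()
    out["origin_zone"] = o_zone[keep]
    out["dest_zone"] = d_zone[keep]
    n_in = int(ok.sum())
    fraction = float(keep.sum() / n_in) if n_in else 0.0
    return out, fraction


def haversine_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between lon/lat points (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(h))


def zone_distances(zoneset: ZoneSet) -> np.ndarray:
    """Symmetric N x N inter-centroid distance matrix in km.

    Great-circle (haversine) distances in lon/lat mode, Euclidean in planar
    mode; zero diagonal by construction.
    """
    if zoneset.mode == "lonlat" and zoneset.centroids_lonlat is not None:
        lon = zoneset.centroids_lonlat[:, 0]
        lat = zoneset.centroids_lonlat[:, 1]
        D = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    else:
        xy = zoneset.centroids_xy_m / 1000.0
        diff = xy[:, None, :] - xy[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(D, 0.0)
    return D


def trip_distances_km(trips: pd.DataFrame, mode: str = "lonlat") -> np.ndarray:
    """Per-trip endpoint-to-endpoint geographic distance in km."""
    if mode == "lonlat":
        return haversine_km(trips["pickup_longitude"], trips["pickup_latitude"],
                            trips["dropoff_longitude"], trips["dropoff_latitude"])
    dx = (trips["dropoff_x_m"] - trips["pickup_x_m"]).to_numpy()
    dy = (trips["dropoff_y_m"] - trips["pickup_y_m"]).to_numpy()
    return np.hypot(dx, dy) / 1000.0
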