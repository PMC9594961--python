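"""Behaviour- and energy-annotated home range on a 30 m occupancy grid.

Every 2-s behaviour record and every 10-min ODBA value is geolocated by the
GPS fix nearest in time, projected into a local metric plane, and binned into
30 × 30 m cells.  Each occupied cell carries:

* occupancy seconds (2 s per assigned behaviour record — behaviour records
  are the continuous time base; ODBA contributes only to energy),
* the proportional allocation over the 8 behaviours,
* the cell's share of total ODBA ("energy percentage", summing to 1 over the
  grid),
* a 24-bin local hour-of-day usage profile and a per-day occupancy vector.

Core cells (total occupancy ≥ 24 h) are grouped into geographic sites by
connected components under queen adjacency with a configurable gap
tolerance, and clustered hierarchically (complete linkage, euclidean) on
behaviour proportions or diel profiles to reveal functional structure the
map alone cannot show.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.sparse
import scipy.sparse.csgraph

from .io_formats import (
    EPOCH_S,
    ETHOGRAM,
    N_BEHAVIOURS,
    DEFAULT_TIMEZONE,
    BehaviourSequence,
    GpsTrack,
    LocalTangentProjection,
    OdbaSeries,
)

DEFAULT_CELL_SIZE_M = 30.0
#: Core-cell occupancy threshold: 24 h, in seconds (boundary inclusive).
DEFAULT_MIN_OCCUPANCY_S = 86_400.0


# --------------------------------------------------------------------------
# Nearest-fix geolocation
# --------------------------------------------------------------------------


def assign_to_nearest_fix(times: np.ndarray, track: GpsTrack) -> pd.DataFrame:
    """Attach to each timestamp the coordinates of the fix nearest in time.

    Ties (a record exactly midway between fixes) resolve to the earlier fix;
    records outside the track's span attach to the first/last fix.  Returns a
    DataFrame with columns lat, lon and fix_index.
    """
    if track.n_fixes == 0:
        raise ValueError("empty GPS track")
    fixes = track.fixes.sort_values("timestamp").reset_index(drop=True)
    ft = fixes["timestamp"].dt.tz_convert(None).to_numpy().astype("datetime64[s]").astype("int64")
    t = np.asarray(times, dtype="datetime64[s]").astype("int64")
    right = np.searchsorted(ft, t, side="left")
    right = np.clip(right, 0, ft.size - 1)
    left = np.clip(right - 1, 0, ft.size - 1)
    d_left = np.abs(t - ft[left])
    d_right = np.abs(ft[right] - t)
    idx = np.where(d_left <= d_right, left, right)  # tie -> earlier fix
    return pd.DataFrame(
        {
            "lat": fixes["lat"].to_numpy()[idx],
            "lon": fixes["lon"].to_numpy()[idx],
            "fix_index": idx,
        }
    )


# --------------------------------------------------------------------------
# Grid
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class LocalGrid:
    """Axis-aligned square grid in a local metric plane.

    The origin is snapped *down* to a multiple of the cell size of the
    minimum easting/northing, so cell membership is reproducible and
    translation by exact multiples of the cell size relabels but never
    re-partitions records.
    """

    projection: LocalTangentProjection
    cell_size_m: float
    origin_x: float
    origin_y: float

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size_m).astype(int)
        row = np.floor((np.asarray(y) - self.origin_y) / self.cell_size_m).astype(int)
        return row, col

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        x0 = self.origin_x + col * self.cell_size_m
        y0 = self.origin_y + row * self.cell_size_m
        return x0, y0, x0 + self.cell_size_m, y0 + self.cell_size_m

    def cell_corners_wgs84(self, row: int, col: int) -> list[tuple[float, float]]:
        """Closed counter-clockwise ring of (lat, lon) cell corners."""
        x0, y0, x1, y1 = self.cell_bounds(row, col)
        xs = [x0, x1, x1, x0, x0]
        ys = [y0, y0, y1, y1, y0]
        lat, lon = self.projection.inverse(np.array(xs), np.array(ys))
        return list(zip(lat.tolist(), lon.tolist()))


@dataclasses.dataclass
class OccupancyGrid:
    """Occupied-cell summaries plus the grid geometry.

    ``cells`` is indexed by a ``"row,col"`` cell id with columns row, col,
    occupancy_s, count per behaviour, prop_<behaviour>, odba_sum,
    energy_percentage; ``hour_profiles`` (cells × 24) and ``day_occupancy``
    (days × cells, seconds) carry the temporal structure.
    """

    grid: LocalGrid
    cells: pd.DataFrame
    hour_profiles: pd.DataFrame
    day_occupancy: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _cell_ids(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return np.char.add(np.char.add(rows.astype(str), ","), cols.astype(str))


def build_grid(
    sequences: Sequence[BehaviourSequence],
    track: GpsTrack,
    odba: OdbaSeries | None = None,
    cell_size_m: float = DEFAULT_CELL_SIZE_M,
    timezone: str = DEFAULT_TIMEZONE,
    projection: LocalTangentProjection | None = None,
) -> OccupancyGrid:
    """Geolocate all behaviour (and ODBA) records by nearest fix and bin
    them into ``cell_size_m`` square cells.

    Occupancy is 2 s per behaviour record; energy percentage is each cell's
    ODBA sum over the total (all zeros when no ODBA series is given).
    """
    if not sequences:
        raise ValueError("no behaviour sequences given")
    frames = []
    for seq in sequences:
        frames.append(
            pd.DataFrame({"time": seq.times, "code": seq.codes, "day": seq.day})
        )
    beh = pd.concat(frames, ignore_index=True)
    assigned = assign_to_nearest_fix(beh["time"].to_numpy(), track)
    beh = pd.concat([beh, assigned], axis=1)

    if projection is None:
        projection = LocalTangentProjection(
            float(beh["lat"].mean()), float(beh["lon"].mean())
        )
    x, y = projection.forward(beh["lat"].to_numpy(), beh["lon"].to_numpy())
    origin_x = cell_size_m * np.floor(x.min() / cell_size_m)
    origin_y = cell_size_m * np.floor(y.min() / cell_size_m)
    grid = LocalGrid(projection, cell_size_m, float(origin_x), float(origin_y))
    row, col = grid.cell_of(x, y)
    beh["cell"] = _cell_ids(row, col)
    beh["row"] = row
    beh["col"] = col

    # per-cell occupancy and behaviour counts
    occ = beh.groupby("cell", sort=True)
    cells = occ.agg(row=("row", "first"), col=("col", "first"), n_records=("code", "size"))
    cells["occupancy_s"] = cells["n_records"] * EPOCH_S
    counts = (
        beh.groupby(["cell", "code"]).size().unstack(fill_value=0)
        .reindex(columns=range(N_BEHAVIOURS), fill_value=0)
    )
    counts.columns = [f"count_{b}" for b in ETHOGRAM]
    cells = cells.join(counts)
    for b in ETHOGRAM:
        cells[f"prop_{b}"] = cells[f"count_{b}"] / cells["n_records"]

    # energy percentage from ODBA records assigned the same way
    cells["odba_sum"] = 0.0
    if odba is not None and len(odba.records):
        ot = odba.records["timestamp"].dt.tz_convert(None).to_numpy().astype("datetime64[s]")
        oa = assign_to_nearest_fix(ot, track)
        ox, oy = projection.forward(oa["lat"].to_numpy(), oa["lon"].to_numpy())
        orow, ocol = grid.cell_of(ox, oy)
        ocell = _cell_ids(orow, ocol)
        sums = pd.Series(odba.records["odba"].to_numpy()).groupby(ocell).sum()
        # ODBA landing in cells with no behaviour record still counts toward
        # the total but cannot annotate an unoccupied cell
        cells.loc[sums.index.intersection(cells.index), "odba_sum"] = sums
        total = float(sums.sum())
    else:
        total = 0.0
    cells["energy_percentage"] = (
        cells["odba_sum"] / total if total > 0 else 0.0
    )

    # temporal structure
    local_hour = (
        pd.DatetimeIndex(beh["time"]).tz_localize("UTC").tz_convert(timezone).hour
    )
    beh["hour"] = local_hour
    hour_counts = (
        beh.groupby(["cell", "hour"]).size().unstack(fill_value=0)
        .reindex(columns=range(24), fill_value=0)
    )
    hour_profiles = hour_counts.div(hour_counts.sum(axis=1), axis=0)
    day_occupancy = (
        beh.groupby(["day", "cell"]).size().unstack(fill_value=0) * EPOCH_S
    )
    return OccupancyGrid(grid, cells, hour_profiles, day_occupancy)


def total_area_m2(grid: OccupancyGrid) -> float:
    """Occupied-cell count × cell area."""
    return grid.n_cells * grid.grid.cell_size_m**2


def select_core_cells(
    grid: OccupancyGrid, min_occupancy_s: float = DEFAULT_MIN_OCCUPANCY_S
) -> pd.DataFrame:
    """Cells with total occupancy ≥ the threshold (24 h default, boundary
    inclusive), ordered by decreasing occupancy."""
    core = grid.cells[grid.cells["occupancy_s"] >= min_occupancy_s]
    return core.sort_values("occupancy_s", ascending=False)


def geographic_sites(cells: pd.DataFrame, max_gap_cells: int = 1) -> pd.Series:
    """Connected-component site labels for core cells.

    Queen adjacency (8-neighbour) with a gap tolerance: cells within
    Chebyshev distance 1 + ``max_gap_cells`` connect.  Labels are 0-based in
    order of first occurrence.
    """
    if cells.empty:
        raise ValueError("no core cells")
    rc = cells[["row", "col"]].to_numpy()
    n = len(rc)
    reach = 1 + max_gap_cells
    cheb = np.maximum(
        np.abs(rc[:, 0][:, None] - rc[:, 0][None, :]),
        np.abs(rc[:, 1][:, None] - rc[:, 1][None, :]),
    )
    adj = scipy.sparse.csr_matrix(cheb <= reach)
    _, labels = scipy.sparse.csgraph.connected_components(adj, directed=False)
    # relabel in order of first occurrence for stable output
    order = {}
    out = []
    for lab in labels:
        order.setdefault(lab, len(order))
        out.append(order[lab])
    return pd.Series(out, index=cells.index, name="site")


def cluster_cells(
    cells: pd.DataFrame,
    feature: str = "behaviour",
    k: int = 4,
    linkage: str = "complete",
    metric: str = "euclidean",
    hour_profiles: pd.DataFrame | None = None,
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of cells on behaviour proportions or diel
    profiles.

    Returns (labels from a k-cut, full merge tree in scipy linkage form) so
    any other cut can be audited.  ``feature`` is ``"behaviour"`` (the 8
    prop_<behaviour> columns) or ``"hour"`` (24-bin profiles, which must be
    passed alongside).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to cluster")
    if k > len(cells):
        raise ValueError("k exceeds the number of cells")
    if feature == "behaviour":
        X = cells[[f"prop_{b}" for b in ETHOGRAM]].to_numpy()
    elif feature == "hour":
        if hour_profiles is None:
            raise ValueError("hour_profiles required for feature='hour'")
        X = hour_profiles.loc[cells.index].to_numpy()
    else:
        raise ValueError("feature must be 'behaviour' or 'hour'")
    Z = scipy.cluster.hierarchy.linkage(X, method=linkage, metric=metric)
    labels = scipy.cluster.hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=cells.index, name=f"{feature}_cluster"), Z


def temporal_profiles(
    grid: OccupancyGrid, cells: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hour-of-day profile matrix (cells × 24, rows summing to 1) and the
    day × cell occupancy table in seconds, optionally restricted to a cell
    subset (e.g. core cells)."""
    hours = grid.hour_profiles
    days = grid.day_occupancy
    if cells is not None:
        hours = hours.loc[cells.index]
        days = days[[c for c in days.columns if c in set(cells.index)]]
    return hours, days
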