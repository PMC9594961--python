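"""Readers and writers for continuous-ethogram tag data.

The data model mirrors what a GPS-accelerometer tag with on-board behaviour
classification produces:

* a behaviour record every 2 s, drawn from a closed 8-class ethogram
  (dabbling, feeding, floating, flying, preening, resting, running, walking);
* a GPS fix every hour (WGS84 decimal degrees);
* one mean ODBA (overall dynamic body acceleration) value per 10-min window,
  a standard proxy for energy expenditure.

All tables are plain comma-separated text with a header row and ISO-8601
timestamps (UTC unless an offset is given).  Behaviour codes are stored as
labels, never integers; :func:`ethogram_index_map` gives the canonical
label↔index mapping used internally.

Days are delimited at local civil midnight in a configurable study timezone
(default ``Australia/Melbourne`` — the tags in the motivating study were
deployed in south-eastern Australia).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Constants / configuration defaults
# --------------------------------------------------------------------------

#: Fixed, alphabetically ordered 8-class ethogram.
ETHOGRAM: tuple[str, ...] = (
    "dabbling",
    "feeding",
    "floating",
    "flying",
    "preening",
    "resting",
    "running",
    "walking",
)
N_BEHAVIOURS = len(ETHOGRAM)
LABEL_TO_INDEX: dict[str, int] = {b: i for i, b in enumerate(ETHOGRAM)}
FLYING: int = LABEL_TO_INDEX["flying"]

#: Duration of one behaviour epoch, seconds.
EPOCH_S = 2
#: Epochs in a complete civil day.
EPOCHS_PER_DAY = 86400 // EPOCH_S  # 43,200

#: Study-local timezone used for day partitioning unless overridden.
DEFAULT_TIMEZONE = "Australia/Melbourne"

#: Mean Earth radius, m (shared by the haversine and the local projection).
EARTH_RADIUS_M = 6_371_000.0

#: Length of one ODBA averaging window, seconds.
ODBA_WINDOW_S = 600


def ethogram_index_map() -> dict[str, int]:
    """Return a copy of the canonical behaviour-label → index mapping."""
    return dict(LABEL_TO_INDEX)


class ValidationError(ValueError):
    """An input table violates a data-model invariant."""


class ParseError(ValueError):
    """An input table could not be parsed (malformed field)."""


class EmptyGridError(ValueError):
    """Raised when asked to export an occupancy grid with no occupied cell."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclasses.dataclass
class BehaviourSequence:
    """One animal-day of ordered 2-s behaviour epochs.

    ``times`` are UTC epoch-start timestamps (``datetime64[s]``); ``codes``
    are ethogram indices (int8).  The sequence belongs to the local calendar
    day ``day`` in the study timezone.
    """

    animal_id: str
    day: dt.date
    times: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.times.shape != self.codes.shape:
            raise ValidationError("times and codes must have equal length")
        if self.codes.size == 0:
            raise ValidationError("empty behaviour sequence")
        if self.codes.min() < 0 or self.codes.max() >= N_BEHAVIOURS:
            raise ValidationError("behaviour code outside the 8-class ethogram")
        if self.times.size > 1 and not (np.diff(self.times).astype(int) > 0).all():
            raise ValidationError(
                f"epoch times not strictly increasing for {self.animal_id} {self.day}"
            )
        if self.times.size > EPOCHS_PER_DAY:
            raise ValidationError(
                f"{self.times.size} epochs exceed one day for {self.animal_id} {self.day}"
            )

    @property
    def n_epochs(self) -> int:
        return int(self.codes.size)

    @property
    def labels(self) -> np.ndarray:
        return np.array(ETHOGRAM, dtype=object)[self.codes]


@dataclasses.dataclass
class GpsTrack:
    """Timestamped WGS84 fixes for one animal, sorted by time."""

    animal_id: str
    fixes: pd.DataFrame  # columns: timestamp (UTC), lat, lon

    def __post_init__(self) -> None:
        f = self.fixes
        for col in ("timestamp", "lat", "lon"):
            if col not in f.columns:
                raise ValidationError(f"GPS table missing column {col!r}")
        if (f["lat"].abs() > 90).any():
            bad = f.loc[f["lat"].abs() > 90, "lat"].iloc[0]
            raise ValidationError(f"latitude {bad} out of range for {self.animal_id}")
        if (f["lon"].abs() > 180).any():
            bad = f.loc[f["lon"].abs() > 180, "lon"].iloc[0]
            raise ValidationError(f"longitude {bad} out of range for {self.animal_id}")
        diffs = f["timestamp"].diff().dropna()
        if (diffs <= pd.Timedelta(0)).any():
            t = f["timestamp"][f["timestamp"].duplicated()].head(1)
            if not t.empty:
                raise ValidationError(
                    f"duplicate GPS timestamp {t.iloc[0]} for {self.animal_id}"
                )
            raise ValidationError(
                f"GPS timestamps not strictly increasing for {self.animal_id}"
            )

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)


@dataclasses.dataclass
class OdbaSeries:
    """Timestamped 10-min mean ODBA values for one animal."""

    animal_id: str
    records: pd.DataFrame  # columns: timestamp (window start, UTC), odba
    window_s: int = ODBA_WINDOW_S

    def __post_init__(self) -> None:
        r = self.records
        for col in ("timestamp", "odba"):
            if col not in r.columns:
                raise ValidationError(f"ODBA table missing column {col!r}")
        if (r["odba"] < 0).any():
            raise ValidationError(f"negative ODBA value for {self.animal_id}")
        diffs = r["timestamp"].diff().dropna()
        if (diffs < pd.Timedelta(seconds=self.window_s)).any():
            raise ValidationError(
                f"overlapping ODBA windows for {self.animal_id}"
            )


# --------------------------------------------------------------------------
# Local tangent projection (metric plane <-> WGS84)
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class LocalTangentProjection:
    """Equirectangular tangent-plane projection centred on (lat0, lon0).

    x = R cos(lat0) Δlon, y = R Δlat (radians).  The inverse is exact; scale
    distortion is negligible over the few-kilometre extents of a 30 m
    occupancy grid, which is all this package projects.
    """

    lat0: float
    lon0: float
    radius_m: float = EARTH_RADIUS_M

    def forward(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        x = self.radius_m * np.cos(math.radians(self.lat0)) * np.radians(lon - self.lon0)
        y = self.radius_m * np.radians(lat - self.lat0)
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lat = self.lat0 + np.degrees(y / self.radius_m)
        lon = self.lon0 + np.degrees(
            x / (self.radius_m * math.cos(math.radians(self.lat0)))
        )
        return lat, lon


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

_STANDARD_COLUMNS = {
    "behaviour": ("animal_id", "timestamp", "behaviour"),
    "gps": ("animal_id", "timestamp", "lat", "lon"),
    "odba": ("animal_id", "timestamp", "odba"),
}


def _load_table(path, kind: str, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    expected = _STANDARD_COLUMNS[kind]
    df = pd.read_csv(path)
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing} (have {list(df.columns)})")
    return df


def _parse_timestamps(df: pd.DataFrame, path) -> pd.DataFrame:
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    if ts.isna().any():
        i = int(ts.index[ts.isna()][0])
        raise ParseError(
            f"{path}: malformed timestamp {df['timestamp'].iloc[i]!r} "
            f"at data line {i + 2}"
        )
    out = df.copy()
    out["timestamp"] = ts
    return out


def read_behaviour_table(
    path,
    timezone: str = DEFAULT_TIMEZONE,
    column_map: Mapping[str, str] | None = None,
) -> list[BehaviourSequence]:
    """Read a behaviour CSV into per-animal, per-local-day sequences.

    The file needs columns ``animal_id,timestamp,behaviour`` (or a
    ``column_map`` from those standard names to the file's headers).  Rows are
    partitioned at local civil midnight in ``timezone``; the output is sorted
    by animal then day, and the sum of per-day epoch counts equals the input
    row count.
    """
    df = _parse_timestamps(_load_table(path, "behaviour", column_map), path)
    unknown = ~df["behaviour"].isin(ETHOGRAM)
    if unknown.any():
        bad = df.loc[unknown, "behaviour"].iloc[0]
        raise ValidationError(
            f"{path}: behaviour label {bad!r} outside the ethogram {ETHOGRAM}"
        )
    local = df["timestamp"].dt.tz_convert(timezone)
    df = df.assign(_day=local.dt.date)
    sequences: list[BehaviourSequence] = []
    for (animal, day), grp in df.groupby(["animal_id", "_day"], sort=True):
        grp = grp.sort_values("timestamp")
        times = grp["timestamp"].dt.tz_convert(None).to_numpy().astype("datetime64[s]")
        codes = grp["behaviour"].map(LABEL_TO_INDEX).to_numpy(dtype=np.int8)
        sequences.append(BehaviourSequence(str(animal), day, times, codes))
    return sequences


def read_gps_table(
    path, column_map: Mapping[str, str] | None = None
) -> list[GpsTrack]:
    """Read a GPS CSV into one validated, time-sorted track per animal."""
    df = _parse_timestamps(_load_table(path, "gps", column_map), path)
    tracks = []
    for animal, grp in df.groupby("animal_id", sort=True):
        fixes = grp[["timestamp", "lat", "lon"]].reset_index(drop=True)
        tracks.append(GpsTrack(str(animal), fixes))
    return tracks


def read_odba_table(
    path,
    column_map: Mapping[str, str] | None = None,
    window_s: int = ODBA_WINDOW_S,
) -> list[OdbaSeries]:
    """Read an ODBA CSV into one validated series per animal."""
    df = _parse_timestamps(_load_table(path, "odba", column_map), path)
    out = []
    for animal, grp in df.groupby("animal_id", sort=True):
        records = grp[["timestamp", "odba"]].reset_index(drop=True)
        out.append(OdbaSeries(str(animal), records, window_s=window_s))
    return out


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------

_ISO = "%Y-%m-%dT%H:%M:%SZ"


def write_behaviour_table(sequences: Iterable[BehaviourSequence], path) -> None:
    frames = []
    for seq in sequences:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": seq.animal_id,
                    "timestamp": pd.DatetimeIndex(seq.times).strftime(_ISO),
                    "behaviour": seq.labels,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_gps_table(tracks: Iterable[GpsTrack], path) -> None:
    frames = []
    for tr in tracks:
        f = tr.fixes.copy()
        f.insert(0, "animal_id", tr.animal_id)
        f["timestamp"] = f["timestamp"].dt.strftime(_ISO)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_odba_table(series: Iterable[OdbaSeries], path) -> None:
    frames = []
    for s in series:
        r = s.records.copy()
        r.insert(0, "animal_id", s.animal_id)
        r["timestamp"] = r["timestamp"].dt.strftime(_ISO)
        frames.append(r)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# --------------------------------------------------------------------------
# GeoJSON export of occupancy grids
# --------------------------------------------------------------------------


def export_cells_geojson(grid, path) -> None:
    """Write one WGS84 polygon feature per occupied grid cell (RFC 7946).

    ``grid`` is an :class:`ethobudget.home_range.OccupancyGrid`.  Feature
    properties carry occupancy seconds, energy percentage, per-behaviour
    proportions and any cluster/site labels present in the cell table.
    """
    cells = grid.cells
    if cells.empty:
        raise EmptyGridError("occupancy grid has no occupied cells")
    features = []
    for cell_id, row in cells.iterrows():
        corners = grid.grid.cell_corners_wgs84(int(row["row"]), int(row["col"]))
        props = {
            "cell_id": str(cell_id),
            "occupancy_s": float(row["occupancy_s"]),
            "energy_percentage": float(row["energy_percentage"]),
        }
        for b in ETHOGRAM:
            props[f"prop_{b}"] = float(row[f"prop_{b}"])
        for extra in ("site", "behaviour_cluster", "hour_cluster"):
            if extra in row.index and not pd.isna(row[extra]):
                props[extra] = int(row[extra])
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    # closed ring, counter-clockwise
                    "coordinates": [[[float(lon), float(lat)] for lat, lon in corners]],
                },
                "properties": props,
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection, indent=1))
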