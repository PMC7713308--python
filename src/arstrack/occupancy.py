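"""Occupancy surfaces, region residence and per-whale track metrics.

Occupancy is the number of days a whale spends in each 0.5° x 0.5° cell,
weighted by that whale's deployment duration divided by the longest
deployment duration, then summed across whales.  At a 3-h state
interval each estimated location contributes dt/24 of a day to its cell.
Cells are half-open ``[lon0, lon0 + c) x [lat0, lat0 + c)`` anchored at
integer degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd
import xarray as xr

from arstrack.argos_io import Deployment
from arstrack.movement import StateSeries

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class RegionMask:
    """A pure predicate on (lon, lat) defining a named region."""

    name: str
    predicate: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def __call__(self, lon, lat) -> np.ndarray:
        return np.asarray(self.predicate(np.asarray(lon), np.asarray(lat)), dtype=bool)

    def union(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(
            name=f"{self.name}|{other.name}",
            predicate=lambda lon, lat: self(lon, lat) | other(lon, lat),
        )


#: Great Southern Australian Coastal Upwelling System:
#: south of 30°S and east of 125°E.
GSACUS = RegionMask("GSACUS", lambda lon, lat: (lat <= -30.0) & (lon >= 125.0))


def great_circle_km(p1, p2) -> np.ndarray | float:
    """Great-circle (haversine) distance in km, R = 6371 km.

    ``p1``/``p2`` are (lon, lat) pairs in degrees, broadcastable arrays
    accepted.
    """
    lon1, lat1 = np.radians(np.asarray(p1, dtype=float)).T if np.ndim(p1) > 1 else np.radians(np.asarray(p1, dtype=float))
    lon2, lat2 = np.radians(np.asarray(p2, dtype=float)).T if np.ndim(p2) > 1 else np.radians(np.asarray(p2, dtype=float))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


@dataclass
class TrackMetrics:
    """Per-whale derived track statistics.

    ``track_duration_days`` spans first to last transmission *including
    gaps*; ``distance_km`` sums great-circle steps between consecutive
    regular state locations within segments only (never across segment
    boundaries); ``mean_speed_kmh`` divides distance by the elapsed
    within-segment hours (dt x step count).
    """

    tag_id: str
    track_duration_days: float
    n_state_locations: int
    distance_km: float
    mean_speed_kmh: float
    days_in_region: int | None = None
    speed_defined: bool = True


def _series_frames(series: StateSeries | Iterable[StateSeries]) -> list[pd.DataFrame]:
    if isinstance(series, StateSeries):
        return [series.data]
    return [s.data for s in series]


def track_metrics(
    series: StateSeries | Iterable[StateSeries],
    deployment: Deployment | None = None,
    dt_hours: float = 3.0,
    region: RegionMask | None = None,
) -> TrackMetrics:
    """Compute the derived track statistics for one whale.

    ``series`` holds one or more state-series segments for the same
    whale.  Duration comes from the deployment transmission span when
    given, else from the span of the state series (which excludes
    between-segment extrapolation but includes within-segment time).
    A single-location series yields zero distance with the speed flagged
    undefined.
    """
    frames = _series_frames(series)
    if not frames or all(len(f) == 0 for f in frames):
        raise ValueError("empty state series")
    tag = frames[0]["tag_id"].iloc[0]
    dist = 0.0
    steps = 0
    for f in frames:
        lon = f["lon"].to_numpy()
        lat = f["lat"].to_numpy()
        if len(f) > 1:
            dist += great_circle_km(
                np.column_stack([lon[:-1], lat[:-1]]),
                np.column_stack([lon[1:], lat[1:]]),
            ).sum()
            steps += len(f) - 1
    n_loc = sum(len(f) for f in frames)
    if deployment is not None:
        duration = deployment.duration_days
    else:
        t_all = pd.concat([f["timestamp"] for f in frames])
        duration = (t_all.max() - t_all.min()) / pd.Timedelta(days=1)
    speed_defined = steps > 0
    speed = dist / (dt_hours * steps) if speed_defined else float("nan")
    days = region_days(series, region) if region is not None else None
    return TrackMetrics(
        tag_id=tag,
        track_duration_days=float(duration),
        n_state_locations=int(n_loc),
        distance_km=float(dist),
        mean_speed_kmh=float(speed),
        days_in_region=days,
        speed_defined=speed_defined,
    )


@dataclass
class OccupancyGrid:
    """Weighted-day occupancy surface on half-open square cells."""

    cell_deg: float
    cells: pd.DataFrame  # cell_lon, cell_lat (lower-left corners), weighted_days
    weights: dict[str, float] = field(default_factory=dict)

    @property
    def total_weighted_days(self) -> float:
        return float(self.cells["weighted_days"].sum())

    def to_xarray(self) -> xr.DataArray:
        pivot = self.cells.pivot_table(
            index="cell_lat", columns="cell_lon", values="weighted_days", fill_value=0.0
        )
        return xr.DataArray(
            pivot.values,
            coords={"lat": pivot.index.values, "lon": pivot.columns.values},
            dims=("lat", "lon"),
            name="weighted_days",
            attrs={"cell_deg": self.cell_deg},
        )

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def occupancy(
    series_by_whale: dict[str, StateSeries | list[StateSeries]],
    durations_days: dict[str, float] | None = None,
    cell_deg: float = 0.5,
    dt_hours: float = 3.0,
) -> OccupancyGrid:
    """Weighted-day occupancy across whales.

    Each state location contributes ``dt_hours/24`` days to its cell;
    per-whale totals are multiplied by ``duration_w / max duration``
    (durations default to each whale's state-series span).  The grid
    total therefore equals ``sum_w weight_w * days_w`` exactly, where
    ``days_w`` is whale w's total located days.
    """
    if not series_by_whale:
        raise ValueError("need at least one whale")
    if durations_days is None:
        durations_days = {}
        for tag, s in series_by_whale.items():
            frames = _series_frames(s)
            t_all = pd.concat([f["timestamp"] for f in frames])
            durations_days[tag] = float((t_all.max() - t_all.min()) / pd.Timedelta(days=1))
    max_dur = max(durations_days.values())
    if max_dur <= 0:
        raise ValueError("longest deployment duration must be positive")
    weights = {tag: durations_days[tag] / max_dur for tag in series_by_whale}
    day_per_loc = dt_hours / 24.0
    pieces = []
    for tag, s in series_by_whale.items():
        for f in _series_frames(s):
            cl = np.floor(f["lon"].to_numpy() / cell_deg) * cell_deg
            cb = np.floor(f["lat"].to_numpy() / cell_deg) * cell_deg
            pieces.append(
                pd.DataFrame(
                    {
                        "cell_lon": cl,
                        "cell_lat": cb,
                        "weighted_days": day_per_loc * weights[tag],
                    }
                )
            )
    cells = (
        pd.concat(pieces, ignore_index=True)
        .groupby(["cell_lon", "cell_lat"], as_index=False)["weighted_days"]
        .sum()
    )
    return OccupancyGrid(cell_deg=cell_deg, cells=cells, weights=weights)


def region_days(
    series: StateSeries | Iterable[StateSeries], mask: RegionMask
) -> int:
    """Distinct UTC calendar days with >= 1 state location in the region."""
    days: set = set()
    for f in _series_frames(series):
        if f.empty:
            continue
        inside = mask(f["lon"].to_numpy(), f["lat"].to_numpy())
        t = pd.to_datetime(f["timestamp"], utc=True)
        days.update(t[inside].dt.date)
    return len(days)
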