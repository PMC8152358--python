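"""GPS stream filtering, trip segmentation and track regularization.

Raw fixes are speed-filtered (implied ground speed > 95 km/h by default),
split into central-place foraging trips (excursions beyond a 500 m colony
radius lasting at least 30 min), and resampled to a constant 30 s step with
shape-preserving piecewise-cubic Hermite interpolation on the projected
plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .projection import AzimuthalEquidistant

DEFAULT_VMAX_KMH = 95.0
DEFAULT_COLONY_RADIUS_M = 500.0
DEFAULT_MIN_TRIP_MIN = 30.0
DEFAULT_DT_S = 30.0


class DuplicateTimestampError(ValueError):
    """Raised when a track contains duplicated timestamps."""


@dataclass
class Trip:
    """One central-place foraging trip.

    ``fixes`` holds ordered rows with at least timestamp, x, y (projected
    km) and lon/lat.  ``complete`` is False when the bird had not returned
    within the colony radius before the data ended.
    """

    trip_id: str
    bird_id: str
    fixes: pd.DataFrame
    departure_time: pd.Timestamp
    arrival_time: pd.Timestamp | None
    complete: bool

    @property
    def duration_h(self) -> float:
        t = self.fixes["timestamp"]
        return (t.iloc[-1] - t.iloc[0]).total_seconds() / 3600.0


@dataclass
class SpeedFilterReport:
    removed_indices: list = field(default_factory=list)
    n_input: int = 0

    @property
    def n_removed(self) -> int:
        return len(self.removed_indices)


def project_fixes(fixes: pd.DataFrame, colony_lon: float, colony_lat: float) -> pd.DataFrame:
    """Add projected x/y (km, azimuthal equidistant at the colony)."""
    proj = AzimuthalEquidistant(colony_lon, colony_lat)
    out = fixes.copy()
    x, y = proj.forward(out["lon"].to_numpy(), out["lat"].to_numpy())
    out["x"] = x
    out["y"] = y
    return out


def _implied_speeds_kmh(x, y, t_s):
    d = np.hypot(np.diff(x), np.diff(y))
    dt = np.diff(t_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dt > 0, d / (dt / 3600.0), np.inf)


def speed_filter(
    fixes: pd.DataFrame, vmax: float = DEFAULT_VMAX_KMH
) -> tuple[pd.DataFrame, SpeedFilterReport]:
    """Iteratively drop fixes whose inbound implied speed exceeds ``vmax``.

    A forward scan removes the *later* fix of each offending pair and
    recomputes the speed from the surviving predecessor, repeating until no
    implied speed exceeds the threshold.  Removal indices refer to the input
    frame's positional order.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    report = SpeedFilterReport(n_input=len(fixes))
    if len(fixes) < 2:
        return fixes.copy(), report

    x = fixes["x"].to_numpy()
    y = fixes["y"].to_numpy()
    t = fixes["timestamp"].astype("int64").to_numpy() / 1e9
    keep = np.ones(len(fixes), dtype=bool)
    last = 0
    for i in range(1, len(fixes)):
        d = np.hypot(x[i] - x[last], y[i] - y[last])
        dt_h = (t[i] - t[last]) / 3600.0
        if dt_h <= 0 or d / dt_h > vmax:
            keep[i] = False
            report.removed_indices.append(i)
        else:
            last = i
    return fixes.loc[keep].reset_index(drop=True), report


def segment_trips(
    fixes: pd.DataFrame,
    radius_m: float = DEFAULT_COLONY_RADIUS_M,
    min_duration_min: float = DEFAULT_MIN_TRIP_MIN,
    bird_id: str | None = None,
) -> list[Trip]:
    """Split one bird's projected fixes into trips.

    Contiguous runs of fixes farther than ``radius_m`` from the colony form
    candidate trips; candidates whose boundary-to-boundary duration is below
    ``min_duration_min`` are discarded; a run that never re-enters the radius
    before the data end is kept but flagged partial.  A track that never
    leaves the radius yields an empty list.
    """
    if len(fixes) == 0:
        return []
    fixes = fixes.reset_index(drop=True)
    if bird_id is None:
        bird_id = str(fixes["bird_id"].iloc[0]) if "bird_id" in fixes else "unknown"
    r_km = radius_m / 1000.0
    outside = np.hypot(fixes["x"].to_numpy(), fixes["y"].to_numpy()) > r_km

    trips: list[Trip] = []
    i = 0
    n = len(fixes)
    trip_no = 0
    while i < n:
        if not outside[i]:
            i += 1
            continue
        j = i
        while j < n and outside[j]:
            j += 1
        complete = j < n  # re-entered the radius before data end
        departure = fixes["timestamp"].iloc[i]
        arrival = fixes["timestamp"].iloc[j] if complete else None
        end_time = arrival if complete else fixes["timestamp"].iloc[j - 1]
        duration_min = (end_time - departure).total_seconds() / 60.0
        if duration_min >= min_duration_min:
            trip_no += 1
            # include the boundary fixes on both sides when present
            lo = max(i - 1, 0)
            hi = min(j + 1, n)
            seg = fixes.iloc[lo:hi].reset_index(drop=True)
            trips.append(
                Trip(
                    trip_id=f"{bird_id}_t{trip_no:02d}",
                    bird_id=bird_id,
                    fixes=seg,
                    departure_time=departure,
                    arrival_time=arrival,
                    complete=complete,
                )
            )
        i = j
    return trips


def interpolate_track(trip: Trip, dt_s: float = DEFAULT_DT_S) -> Trip:
    """Regularize a trip to a constant ``dt_s`` grid.

    x(t) and y(t) are interpolated independently with a shape-preserving
    piecewise-cubic Hermite scheme (PCHIP); the output grid starts at the
    trip's first fix and never extrapolates beyond its last.  Original knots
    that land on the grid are reproduced exactly.
    """
    fixes = trip.fixes
    if len(fixes) < 2:
        raise ValueError("interpolation needs at least 2 fixes")
    t = fixes["timestamp"].astype("int64").to_numpy() / 1e9
    dup = np.flatnonzero(np.diff(t) == 0)
    if dup.size:
        raise DuplicateTimestampError(
            f"duplicate timestamps at input rows {list(dup)} / {list(dup + 1)}"
        )
    fx = PchipInterpolator(t, fixes["x"].to_numpy())
    fy = PchipInterpolator(t, fixes["y"].to_numpy())
    n_steps = int(np.floor((t[-1] - t[0]) / dt_s + 1e-9))
    grid = t[0] + np.arange(n_steps + 1) * dt_s
    new = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(grid * 1e9, utc=True),
            "x": fx(grid),
            "y": fy(grid),
        }
    )
    new["bird_id"] = trip.bird_id
    return Trip(
        trip_id=trip.trip_id,
        bird_id=trip.bird_id,
        fixes=new,
        departure_time=trip.departure_time,
        arrival_time=trip.arrival_time,
        complete=trip.complete,
    )


def departure_arrival_times(trips: list[Trip], colony_lon: float) -> pd.DataFrame:
    """Local-solar-time-of-day of departure and arrival per trip.

    Local solar time = UTC + lon/15 hours.  Partial trips get a missing
    arrival and are flagged.
    """
    offset = pd.Timedelta(hours=colony_lon / 15.0)
    rows = []
    for trip in trips:
        dep_local = trip.departure_time + offset
        arr_local = trip.arrival_time + offset if trip.arrival_time is not None else None
        rows.append(
            {
                "trip_id": trip.trip_id,
                "bird_id": trip.bird_id,
                "departure_local_h": dep_local.hour + dep_local.minute / 60 + dep_local.second / 3600,
                "arrival_local_h": (
                    arr_local.hour + arr_local.minute / 60 + arr_local.second / 3600
                    if arr_local is not None
                    else np.nan
                ),
                "complete": trip.complete,
            }
        )
    return pd.DataFrame(rows)


def preprocess_bird(
    fixes: pd.DataFrame,
    colony_lon: float,
    colony_lat: float,
    vmax: float = DEFAULT_VMAX_KMH,
    radius_m: float = DEFAULT_COLONY_RADIUS_M,
    min_duration_min: float = DEFAULT_MIN_TRIP_MIN,
    dt_s: float = DEFAULT_DT_S,
    interpolate: bool = True,
) -> tuple[list[Trip], SpeedFilterReport]:
    """Project, speed-filter, segment and (optionally) regularize one bird."""
    projected = project_fixes(fixes.sort_values("timestamp"), colony_lon, colony_lat)
    filtered, report = speed_filter(projected, vmax=vmax)
    trips = segment_trips(filtered, radius_m=radius_m, min_duration_min=min_duration_min)
    if interpolate:
        trips = [interpolate_track(t, dt_s=dt_s) for t in trips if len(t.fixes) >= 2]
    return trips, report
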