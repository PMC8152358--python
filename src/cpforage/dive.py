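"""Depth-trace zero-offset correction, dive detection, and track matching.

A 'moving quantile' zero-offset correction subtracts a rolling low-quantile
baseline from the raw 1 Hz depth so the surface reads 0 m, after which dives
are maximal contiguous runs above a > 0.25 m threshold.  Dive and immersion
records are matched to the 30 s regularized track segment centred on each
fix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_ZOC_WINDOW_S = 600
DEFAULT_ZOC_QUANTILE = 0.05
DEFAULT_DIVE_THRESHOLD_M = 0.25


@dataclass
class DiveEvent:
    start: pd.Timestamp
    end: pd.Timestamp
    max_depth_m: float
    duration_s: float
    matched_fix: int | None = None


def zero_offset_correct(
    trace: pd.DataFrame,
    window_s: int = DEFAULT_ZOC_WINDOW_S,
    quantile: float = DEFAULT_ZOC_QUANTILE,
) -> pd.DataFrame:
    """Subtract a centred rolling low-quantile baseline; floor at 0 m.

    ``trace`` needs columns timestamp and depth_m at 1 Hz.  The window must
    be much longer than any dive so the quantile tracks the drifting surface
    line, not dive signal.
    """
    if window_s < 60:
        raise ValueError("window_s must be >= 60 s")
    if not (0 < quantile <= 0.5):
        raise ValueError("quantile must be in (0, 0.5]")
    if len(trace) < window_s:
        raise ValueError(f"trace shorter ({len(trace)} s) than ZOC window ({window_s} s)")
    corrected = trace["depth_m"].to_numpy(dtype=float).copy()
    # a single quantile subtraction leaves a constant offset under drift
    # (the quantile sits below the surface line), so iterate until the
    # remaining baseline is within the 1 mm dead band (well below pressure
    # sensor resolution); edge samples reuse the nearest complete window.
    # the dead band makes the correction an exact no-op on already-corrected
    # traces.
    dead_band_m = 1e-3
    for _ in range(8):
        baseline = (
            pd.Series(corrected)
            .rolling(window=window_s, center=True, min_periods=window_s)
            .quantile(quantile)
            .bfill()
            .ffill()
            .to_numpy()
        )
        if np.max(np.abs(baseline)) <= dead_band_m:
            break
        corrected = np.clip(corrected - baseline, 0.0, None)
    out = trace.copy()
    out["depth_m"] = corrected
    return out


def detect_dives(
    trace: pd.DataFrame, threshold_m: float = DEFAULT_DIVE_THRESHOLD_M
) -> pd.DataFrame:
    """Maximal contiguous runs with corrected depth > threshold become dives.

    Returns a DataFrame with start, end, max_depth_m, duration_s; duration is
    the span of above-threshold samples (1 Hz, inclusive endpoints).
    """
    depth = trace["depth_m"].to_numpy()
    ts = trace["timestamp"].to_numpy()
    above = depth > threshold_m
    if not above.any():
        return pd.DataFrame(columns=["start", "end", "max_depth_m", "duration_s"])
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size - 1]])
    rows = []
    for s, e in zip(starts, ends):
        rows.append(
            {
                "start": ts[s],
                "end": ts[e],
                "max_depth_m": float(depth[s : e + 1].max()),
                "duration_s": float(e - s + 1),
            }
        )
    return pd.DataFrame(rows)


def match_to_track(
    events: pd.DataFrame,
    trip,
    dt_s: float = 30.0,
    time_col: str = "start",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign events to the fix whose centred ``dt_s`` window contains them.

    An event at exactly the midpoint between two fixes goes to the earlier
    fix.  Returns (events with a ``fix_index`` column, -1 when the event
    falls outside the track span; per-fix event counts).
    """
    fixes = trip.fixes if hasattr(trip, "fixes") else trip
    ft = fixes["timestamp"].astype("int64").to_numpy() / 1e9
    out = events.copy()
    n = len(fixes)
    counts = np.zeros(n, dtype=int)
    idx = np.full(len(events), -1, dtype=int)
    if len(events):
        et = pd.to_datetime(events[time_col]).astype("int64").to_numpy() / 1e9
        half = dt_s / 2.0
        for i, t in enumerate(et):
            if t < ft[0] - half or t > ft[-1] + half:
                continue
            j = int(np.searchsorted(ft, t))
            # candidate fixes j-1 and j; tie (equal distance) -> earlier fix
            if j == 0:
                k = 0
            elif j >= n:
                k = n - 1
            else:
                k = j - 1 if (t - ft[j - 1]) <= (ft[j] - t) else j
            if abs(t - ft[k]) <= half + 1e-9:
                idx[i] = k
                counts[k] += 1
    out["fix_index"] = idx
    per_fix = pd.DataFrame(
        {"fix_index": np.arange(n), "timestamp": fixes["timestamp"].to_numpy(), "n_events": counts}
    )
    return out, per_fix


def dive_rate_per_trip(dives: pd.DataFrame, trip) -> float:
    """Dives per hour over the trip duration."""
    hours = trip.duration_h if hasattr(trip, "duration_h") else np.nan
    return len(dives) / hours if hours and hours > 0 else np.nan


def parse_immersion(log: pd.DataFrame, resolution_s: float = 6.0) -> pd.DataFrame:
    """Collapse a 6 s wet/dry sample log into a piecewise-constant interval series.

    Consecutive identical states are merged; total wet time is conserved
    (each record covers ``resolution_s`` seconds).  Returns start, end, state,
    duration_s per interval.
    """
    if len(log) == 0:
        return pd.DataFrame(columns=["start", "end", "state", "duration_s"])
    log = log.sort_values("timestamp").reset_index(drop=True)
    states = log["state"].to_numpy()
    ts = log["timestamp"].to_numpy()
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(log)]])
    rows = []
    for s, e in zip(starts, ends):
        rows.append(
            {
                "start": ts[s],
                "end": ts[e - 1] + pd.Timedelta(seconds=resolution_s),
                "state": states[s],
                "duration_s": (e - s) * resolution_s,
            }
        )
    return pd.DataFrame(rows)


def wet_fraction_per_fix(immersion_log: pd.DataFrame, trip, dt_s: float = 30.0) -> np.ndarray:
    """Fraction of each fix's centred window logged wet (NaN where no data)."""
    fixes = trip.fixes if hasattr(trip, "fixes") else trip
    ft = fixes["timestamp"].astype("int64").to_numpy() / 1e9
    n = len(fixes)
    wet = np.zeros(n)
    tot = np.zeros(n)
    if len(immersion_log):
        it = pd.to_datetime(immersion_log["timestamp"]).astype("int64").to_numpy() / 1e9
        is_wet = (immersion_log["state"].to_numpy() == "wet").astype(float)
        half = dt_s / 2.0
        for t, w in zip(it, is_wet):
            j = int(np.searchsorted(ft, t))
            if j == 0:
                k = 0
            elif j >= n:
                k = n - 1
            else:
                k = j - 1 if (t - ft[j - 1]) <= (ft[j] - t) else j
            if abs(t - ft[k]) <= half + 1e-9:
                tot[k] += 1
                wet[k] += w
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, wet / np.maximum(tot, 1), np.nan)
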