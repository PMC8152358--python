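"""Seeded synthetic central-place-foraging data generator.

Produces every input stream the analysis pipeline consumes — GPS fix tables,
1 Hz depth traces, 6 s immersion logs, kleptoparasitism event tables, isotope
and prey tables, morphometrics — with known ground-truth parameters, so each
downstream stage can be tested by parameter recovery.

Conventions
-----------
* All movement is simulated on a local azimuthal-equidistant plane centred on
  the colony (km); lon/lat are emitted by inverse projection.
* Behavioural states are integers: 0 = rest, 1 = forage, 2 = travel.
* Depth is positive down (metres).
* One integer seed feeds splittable per-stream RNGs (see `cpforage._rng`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely.geometry import Point, Polygon

from ._rng import substream
from .projection import AzimuthalEquidistant

REST, FORAGE, TRAVEL = 0, 1, 2
STATE_NAMES = ("rest", "forage", "travel")


class InvalidSpecError(ValueError):
    """A simulation specification implies an empty or impossible output."""


# ---------------------------------------------------------------------------
# World
# ---------------------------------------------------------------------------


@dataclass
class World:
    """Colony, coastline and bathymetry for a simulated study system.

    ``coastline`` is a closed polygon in projected km (land); the colony sits
    inside it.  ``bathymetry`` is water depth in metres (positive down) on a
    regular grid spanned by ``bx`` and ``by`` (km).
    """

    colony_lon: float
    colony_lat: float
    coastline: Polygon
    bx: np.ndarray
    by: np.ndarray
    bathymetry: np.ndarray  # shape (len(by), len(bx)), metres positive down
    grid_resolution_km: float
    depth_convention: str = "positive_down"

    def __post_init__(self) -> None:
        if not self.coastline.contains(Point(0.0, 0.0)):
            raise ValueError("colony (projection origin) must lie inside the coastline polygon")

    @property
    def projection(self) -> AzimuthalEquidistant:
        return AzimuthalEquidistant(self.colony_lon, self.colony_lat)

    def coast_distance(self, x, y) -> np.ndarray:
        """Signed distance (km) to the coastline boundary: positive offshore."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        boundary = self.coastline.exterior
        out = np.empty(x.shape, dtype=float)
        for i, (xi, yi) in enumerate(zip(x.ravel(), y.ravel())):
            p = Point(xi, yi)
            d = boundary.distance(p)
            out.ravel()[i] = -d if self.coastline.contains(p) else d
        return out

    def bathymetry_at(self, x, y) -> np.ndarray:
        """Nearest-cell water depth (m) under each point; NaN outside the raster."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.round((x - self.bx[0]) / (self.bx[1] - self.bx[0])).astype(int)
        iy = np.round((y - self.by[0]) / (self.by[1] - self.by[0])).astype(int)
        ok = (ix >= 0) & (ix < self.bx.size) & (iy >= 0) & (iy < self.by.size)
        out = np.full(np.shape(x), np.nan, dtype=float)
        out[ok] = self.bathymetry[iy[ok], ix[ok]]
        return out

    @classmethod
    def default(
        cls,
        colony_lon: float = -81.38,
        colony_lat: float = 19.30,
        island_radius_km: float = 4.0,
        extent_km: float = 160.0,
        resolution_km: float = 2.0,
        shelf_slope_m_per_km: float = 25.0,
    ) -> "World":
        """Irregular near-circular island with depth increasing offshore."""
        theta = np.linspace(0.0, 2 * np.pi, 33)[:-1]
        # fixed gentle irregularity; keeps the polygon convex-ish
        r = island_radius_km * (1.0 + 0.15 * np.cos(3 * theta) + 0.1 * np.sin(2 * theta))
        coast = Polygon(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
        bx = np.arange(-extent_km, extent_km + resolution_km, resolution_km)
        by = bx.copy()
        gx, gy = np.meshgrid(bx, by)
        dist = np.hypot(gx, gy) - island_radius_km
        depth = np.clip(dist, 0.0, None) * shelf_slope_m_per_km
        return cls(colony_lon, colony_lat, coast, bx, by, depth, resolution_km)


# ---------------------------------------------------------------------------
# Ground-truth parameters
# ---------------------------------------------------------------------------


def _default_isotope_model():
    return {
        "RFB_blood": (np.array([-17.2, 8.3]), np.array([[0.20, 0.05], [0.05, 0.30]])),
        "BB_blood": (np.array([-16.4, 9.6]), np.array([[0.25, 0.02], [0.02, 0.35]])),
        "flying_fish": (np.array([-17.6, 7.1]), np.array([[0.30, 0.0], [0.0, 0.40]])),
        "ballyhoo": (np.array([-16.8, 7.9]), np.array([[0.30, 0.0], [0.0, 0.40]])),
        "squid": (np.array([-17.9, 6.5]), np.array([[0.30, 0.0], [0.0, 0.40]])),
    }


def _default_prey_probs():
    return {
        "RFB": {"flying_fish": 0.55, "ballyhoo": 0.15, "squid": 0.30},
        "BB": {"flying_fish": 0.50, "ballyhoo": 0.35, "squid": 0.15},
    }


def _default_morpho_model():
    # mass g, wing mm, bill length mm, bill depth mm, tarsus mm, tail mm
    f_mean = np.array([1310.0, 390.0, 102.0, 30.0, 46.0, 195.0])
    m_mean = np.array([1080.0, 376.0, 95.0, 27.0, 43.0, 194.0])
    f_sd = np.array([90.0, 8.0, 2.5, 1.0, 1.5, 7.0])
    m_sd = np.array([80.0, 8.0, 2.5, 1.0, 1.5, 7.0])
    return {
        "female": (f_mean, np.diag(f_sd**2)),
        "male": (m_mean, np.diag(m_sd**2)),
    }


MORPHO_COLUMNS = ("mass_g", "wing_mm", "bill_length_mm", "bill_depth_mm", "tarsus_mm", "tail_mm")


@dataclass
class TruthParams:
    """Ground-truth parameters for every simulated data stream.

    Movement: 3-state Markov chain (rest/forage/travel) with gamma step
    lengths (km per step) and von Mises turn angles.  Dives: Poisson process
    in forage time, truncated-exponential maximum depths.  TEF defaults follow
    the blood→prey discrimination factors used in the analysis (Δ15N 1.96 ±
    0.79 ‰, Δ13C 0.32 ± 0.86 ‰).
    """

    transition_matrix: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.90, 0.08, 0.02], [0.05, 0.90, 0.05], [0.02, 0.08, 0.90]]
        )
    )
    # per-state (mean km, sd km), rows ordered rest/forage/travel
    step_gamma: np.ndarray = field(
        default_factory=lambda: np.array([[0.005, 0.004], [0.08, 0.05], [0.40, 0.12]])
    )
    # per-state (mean angle rad, concentration kappa)
    turn_vonmises: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.5], [np.pi, 1.0], [0.0, 8.0]])
    )
    dive_rate_forage: float = 12.0  # dives per forage-hour
    dive_depth_mean: float = 0.5  # m, truncated exponential
    dive_depth_max: float = 3.0  # m
    sensor_drift: tuple = (0.3, 0.02)  # slope m/h, noise sd m
    immersion_rule: dict = field(
        default_factory=lambda: {REST: 0.95, FORAGE: 0.5, TRAVEL: 0.05}
    )
    # logistic coefficients for per-forage-fix klepto probability
    klepto_model: dict = field(
        default_factory=lambda: {"intercept": -4.0, "male": -2.5, "coast_km": 0.02}
    )
    isotope_model: dict = field(default_factory=_default_isotope_model)
    tef: tuple = (1.96, 0.79, 0.32, 0.86)  # dN mean, dN sd, dC mean, dC sd
    prey_probs: dict = field(default_factory=_default_prey_probs)
    morpho_model: dict = field(default_factory=_default_morpho_model)

    def validate(self) -> None:
        tm = np.asarray(self.transition_matrix)
        if tm.shape != (3, 3) or not np.allclose(tm.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition_matrix must be 3x3 row-stochastic")
        if np.any(np.asarray(self.step_gamma) <= 0):
            raise ValueError("gamma step means and sds must be positive")
        if np.any(np.asarray(self.turn_vonmises)[:, 1] <= 0):
            raise ValueError("von Mises concentrations must be positive")
        if self.dive_depth_mean <= 0 or self.dive_depth_max <= 0:
            raise ValueError("dive depths must be positive")
        for g, probs in self.prey_probs.items():
            if not np.isclose(sum(probs.values()), 1.0):
                raise ValueError(f"prey probabilities for group {g!r} must sum to 1")

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        vals, vecs = np.linalg.eig(np.asarray(self.transition_matrix).T)
        v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
        return v / v.sum()


# ---------------------------------------------------------------------------
# Trip / bird specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TripSpec:
    """One simulated foraging trip.

    ``commute_h`` hours at the start are forced into the travel state (an
    outbound commute), after which states follow the Markov chain; the trip
    ends with a biased-walk homing phase back to the colony (flagged
    ``phase='homing'`` in the truth table so recovery tests can exclude it).
    """

    start: pd.Timestamp
    duration_h: float = 4.0
    fix_interval_s: int = 30
    commute_h: float = 0.25

    def __post_init__(self) -> None:
        if self.fix_interval_s not in (30, 120):
            raise InvalidSpecError("fix interval must be 30 s or 120 s")
        if int(round(self.duration_h * 3600 / self.fix_interval_s)) < 1:
            raise InvalidSpecError("trip specification implies zero fixes")


@dataclass(frozen=True)
class BirdSpec:
    bird_id: str
    sex: str  # 'female' | 'male'
    species: str = "BB"
    trips: tuple = ()


@dataclass
class TrackSet:
    """Simulated GPS output plus aligned ground truth."""

    fixes: pd.DataFrame  # bird_id, timestamp, lon, lat
    truth: pd.DataFrame  # bird_id, timestamp, x, y, state, phase, trip_index
    birds: pd.DataFrame  # bird_id, sex, species
    world: World


def default_birds(
    n_birds: int,
    trip_spec: TripSpec | None = None,
    n_trips: int = 1,
    start: pd.Timestamp | None = None,
) -> list[BirdSpec]:
    """Convenience roster: alternating sexes, one shared trip template."""
    if trip_spec is None:
        trip_spec = TripSpec(start=start or pd.Timestamp("2017-06-01 06:00:00", tz="UTC"))
    birds = []
    for i in range(n_birds):
        trips = []
        t0 = trip_spec.start
        for j in range(n_trips):
            trips.append(replace(trip_spec, start=t0))
            t0 = t0 + pd.Timedelta(hours=trip_spec.duration_h + 2.0)
        birds.append(
            BirdSpec(
                bird_id=f"bird{i:03d}",
                sex="female" if i % 2 == 0 else "male",
                trips=tuple(trips),
            )
        )
    return birds


# ---------------------------------------------------------------------------
# Track generation
# ---------------------------------------------------------------------------


def simulate_state_chain(
    transition: np.ndarray, n: int, rng: np.random.Generator, start_state: int = TRAVEL
) -> np.ndarray:
    """Sample a Markov chain of length n (first state = start_state)."""
    states = np.empty(n, dtype=np.int64)
    states[0] = start_state
    cum = np.cumsum(np.asarray(transition), axis=1)
    u = rng.random(n)
    for t in range(1, n):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return states


def _simulate_trip(world, truth, spec: TripSpec, rng):
    """Simulate one trip; returns (times, x, y, state, phase) arrays."""
    dt = spec.fix_interval_s
    n_main = int(round(spec.duration_h * 3600 / dt))
    n_commute = min(int(round(spec.commute_h * 3600 / dt)), n_main)

    states = simulate_state_chain(truth.transition_matrix, n_main, rng, start_state=TRAVEL)
    states[:n_commute] = TRAVEL

    means, sds = truth.step_gamma[:, 0], truth.step_gamma[:, 1]
    shapes = (means / sds) ** 2
    scales = sds**2 / means
    steps = rng.gamma(shapes[states], scales[states])
    mus, kappas = truth.turn_vonmises[:, 0], truth.turn_vonmises[:, 1]
    turns = rng.vonmises(mus[states], kappas[states])

    # outbound commute holds a persistent bearing (directed flight); the
    # Markov-driven turn process takes over afterwards
    commute_bearing = rng.uniform(-np.pi, np.pi)
    commute_noise = rng.vonmises(0.0, 100.0, size=n_commute)
    heading = commute_bearing
    x = np.empty(n_main + 1)
    y = np.empty(n_main + 1)
    x[0] = y[0] = 0.0
    for t in range(n_main):
        if t < n_commute:
            heading = commute_bearing + commute_noise[t]
        else:
            heading = np.angle(np.exp(1j * (heading + turns[t])))
        x[t + 1] = x[t] + steps[t] * np.sin(heading)
        y[t + 1] = y[t] + steps[t] * np.cos(heading)

    # homing: biased walk back to the colony at travel speed
    hx, hy, hstates = [], [], []
    px, py = x[-1], y[-1]
    guard = 0
    while np.hypot(px, py) > 0.2 and guard < 20000:
        step = rng.gamma(shapes[TRAVEL], scales[TRAVEL])
        bearing = np.arctan2(-px, -py) + rng.vonmises(0.0, 20.0)
        step = min(step, np.hypot(px, py))
        px += step * np.sin(bearing)
        py += step * np.cos(bearing)
        hx.append(px)
        hy.append(py)
        hstates.append(TRAVEL)
        guard += 1

    # colony bookends (rest, tight jitter) so trip segmentation sees the return
    n_col = 3
    cx = rng.normal(0.0, 0.05, size=2 * n_col + 1)
    cy = rng.normal(0.0, 0.05, size=2 * n_col + 1)

    xs = np.concatenate([cx[:n_col], x, hx, [0.0], cx[n_col:]])
    ys = np.concatenate([cy[:n_col], y, hy, [0.0], cy[n_col:]])
    # fix i carries the state of its outgoing step (last main fix repeats)
    st = np.concatenate(
        [
            np.full(n_col, REST),
            states,
            [states[-1]],
            hstates,
            [REST],
            np.full(n_col + 1, REST),
        ]
    )
    phase = np.concatenate(
        [
            np.full(n_col, "colony"),
            np.full(n_main + 1, "main"),
            np.full(len(hx), "homing"),
            np.full(n_col + 2, "colony"),
        ]
    )
    times = spec.start - pd.Timedelta(seconds=n_col * dt) + pd.to_timedelta(
        np.arange(xs.size) * dt, unit="s"
    )
    return times, xs, ys, st, phase


def generate_tracks(
    world: World,
    truth: TruthParams,
    birds: list[BirdSpec] | int,
    trip_spec: TripSpec | None = None,
    seed: int = 0,
) -> TrackSet:
    """Simulate GPS tracks for a roster of birds.

    ``birds`` may be a list of :class:`BirdSpec` or an integer count (a
    default roster is built with ``trip_spec`` as template).  Same seed, same
    arguments ⇒ bit-identical output.
    """
    truth.validate()
    if isinstance(birds, int):
        if birds < 1:
            raise InvalidSpecError("n_birds must be >= 1")
        birds = default_birds(birds, trip_spec)
    if not birds:
        raise InvalidSpecError("empty bird roster")

    proj = world.projection
    fix_rows, truth_rows, bird_rows = [], [], []
    for b in birds:
        if not b.trips:
            raise InvalidSpecError(f"bird {b.bird_id} has no trips")
        rng = substream(seed, f"tracks/{b.bird_id}")
        for j, spec in enumerate(b.trips):
            times, xs, ys, st, phase = _simulate_trip(world, truth, spec, rng)
            lon, lat = proj.inverse(xs, ys)
            fix_rows.append(
                pd.DataFrame(
                    {"bird_id": b.bird_id, "timestamp": times, "lon": lon, "lat": lat}
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "bird_id": b.bird_id,
                        "timestamp": times,
                        "x": xs,
                        "y": ys,
                        "state": st,
                        "phase": phase,
                        "trip_index": j,
                    }
                )
            )
        bird_rows.append({"bird_id": b.bird_id, "sex": b.sex, "species": b.species})

    fixes = pd.concat(fix_rows, ignore_index=True)
    truth_df = pd.concat(truth_rows, ignore_index=True)
    return TrackSet(fixes, truth_df, pd.DataFrame(bird_rows), world)


# ---------------------------------------------------------------------------
# Depth traces and immersion
# ---------------------------------------------------------------------------


def build_depth_trace(
    dive_starts_s: np.ndarray,
    max_depths_m: np.ndarray,
    durations_s: np.ndarray,
    n_seconds: int,
    t0: pd.Timestamp,
    drift_m_per_h: float = 0.0,
    noise_sd_m: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assemble a 1 Hz depth trace from explicit dives plus drift and noise.

    Each dive is a triangular excursion: linear descent to max depth at the
    midpoint, linear ascent back to the surface.  Drift and noise are applied
    after dive construction (as a pressure sensor would see them).
    """
    depth = np.zeros(n_seconds)
    for s, d, dur in zip(dive_starts_s, max_depths_m, durations_s):
        s, dur = int(s), int(dur)
        tt = np.arange(1, dur)  # interior samples; endpoints at surface
        prof = d * (1.0 - np.abs(2.0 * tt / dur - 1.0))
        end = min(s + dur, n_seconds)
        depth[s + 1 : end] = np.maximum(depth[s + 1 : end], prof[: end - s - 1])
    t_h = np.arange(n_seconds) / 3600.0
    raw = depth + drift_m_per_h * t_h
    if noise_sd_m > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        raw = raw + rng.normal(0.0, noise_sd_m, size=n_seconds)
    timestamps = t0 + pd.to_timedelta(np.arange(n_seconds), unit="s")
    return pd.DataFrame({"timestamp": timestamps, "depth_m": raw})


def generate_dive_trace(
    states: pd.DataFrame,
    truth: TruthParams,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a 1 Hz depth trace conditioned on one bird's state sequence.

    ``states`` needs columns ``timestamp`` and ``state`` at a constant fix
    interval; dives are a Poisson process restricted to forage-state seconds.
    Returns (trace, true_dives); true_dives has start/end/max_depth_m columns.
    """
    rng = substream(seed, "dives")
    if len(states) == 0:
        empty = pd.DataFrame(columns=["timestamp", "depth_m"])
        return empty, pd.DataFrame(columns=["start", "end", "max_depth_m", "duration_s"])
    states = states.sort_values("timestamp").reset_index(drop=True)
    t0 = states["timestamp"].iloc[0]
    dt = (
        int((states["timestamp"].iloc[1] - states["timestamp"].iloc[0]).total_seconds())
        if len(states) > 1
        else 1
    )
    n_seconds = dt * len(states)
    sec_state = np.repeat(states["state"].to_numpy(), dt)

    forage_sec = np.flatnonzero(sec_state == FORAGE)
    n_dives = 0
    if forage_sec.size and truth.dive_rate_forage > 0:
        n_dives = rng.poisson(truth.dive_rate_forage * forage_sec.size / 3600.0)

    starts, depths, durs = [], [], []
    if n_dives > 0:
        cand = np.sort(rng.choice(forage_sec, size=n_dives, replace=False if n_dives <= forage_sec.size else True))
        last_end = -1
        for s in cand:
            # truncated exponential max depth on (0.05, depth_max]
            u = rng.random()
            d = -truth.dive_depth_mean * np.log(
                1 - u * (1 - np.exp(-truth.dive_depth_max / truth.dive_depth_mean))
            )
            d = max(d, 0.05)
            dur = int(np.clip(round(2 + 4 * d), 2, 30))
            if s <= last_end or s + dur >= n_seconds:
                continue
            if np.any(sec_state[s : s + dur + 1] != FORAGE):
                continue
            starts.append(s)
            depths.append(d)
            durs.append(dur)
            last_end = s + dur + 1

    slope, noise = truth.sensor_drift
    trace = build_depth_trace(
        np.array(starts), np.array(depths), np.array(durs), n_seconds, t0, slope, noise, rng
    )
    dives = pd.DataFrame(
        {
            "start": t0 + pd.to_timedelta(np.array(starts, dtype=int) + 1, unit="s"),
            "end": t0 + pd.to_timedelta(np.array(starts, dtype=int) + np.array(durs, dtype=int) - 1, unit="s"),
            "max_depth_m": depths,
            "duration_s": np.array(durs, dtype=int) - 1,
        }
    )
    return trace, dives


def generate_immersion(states: pd.DataFrame, truth: TruthParams, seed: int = 0) -> pd.DataFrame:
    """6 s wet/dry log driven by the per-state wet probability."""
    rng = substream(seed, "immersion")
    if len(states) == 0:
        return pd.DataFrame(columns=["timestamp", "state"])
    states = states.sort_values("timestamp").reset_index(drop=True)
    t0 = states["timestamp"].iloc[0]
    dt = (
        int((states["timestamp"].iloc[1] - states["timestamp"].iloc[0]).total_seconds())
        if len(states) > 1
        else 6
    )
    n_blocks = max(dt * len(states) // 6, 1)
    block_state = np.repeat(states["state"].to_numpy(), dt)[: n_blocks * 6 : 6]
    p_wet = np.array([truth.immersion_rule[s] for s in block_state], dtype=float)
    wet = rng.random(block_state.size) < p_wet
    return pd.DataFrame(
        {
            "timestamp": t0 + pd.to_timedelta(np.arange(block_state.size) * 6, unit="s"),
            "state": np.where(wet, "wet", "dry"),
        }
    )


# ---------------------------------------------------------------------------
# Isotopes, prey, klepto, morphometrics
# ---------------------------------------------------------------------------


def generate_isotope_and_prey(
    truth: TruthParams,
    n_per_group: int | dict,
    seed: int = 0,
    n_prey_items: int = 60,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw isotope samples per group and multinomial prey counts.

    Returns (isotope table, prey count table).  The isotope table has columns
    sample_id, group, tissue, d13C, d15N; prey counts are groups x families.
    """
    rng = substream(seed, "isotopes")
    if isinstance(n_per_group, dict):
        missing = set(n_per_group) - set(truth.isotope_model)
        if missing:
            raise KeyError(f"groups absent from truth isotope model: {sorted(missing)}")
        wanted = n_per_group
    else:
        wanted = {g: int(n_per_group) for g in truth.isotope_model}

    rows = []
    for group, n in wanted.items():
        mean, cov = truth.isotope_model[group]
        draws = rng.multivariate_normal(mean, cov, size=n)
        tissue = "blood_RBC" if group.endswith("blood") else "prey_muscle"
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{group}_{i:04d}",
                    "group": group,
                    "tissue": tissue,
                    "d13C": draws[i, 0],
                    "d15N": draws[i, 1],
                }
            )
    iso = pd.DataFrame(rows)

    prey_rng = substream(seed, "prey")
    families = sorted({f for probs in truth.prey_probs.values() for f in probs})
    prey_rows = {}
    for group, probs in truth.prey_probs.items():
        p = np.array([probs.get(f, 0.0) for f in families])
        prey_rows[group] = prey_rng.multinomial(n_prey_items, p)
    prey = pd.DataFrame(prey_rows, index=families).T
    prey.index.name = "group"
    return iso, prey


def klepto_probability(truth: TruthParams, is_male, coast_km) -> np.ndarray:
    """Per-forage-fix logistic attack probability from the truth model."""
    km = truth.klepto_model
    eta = km["intercept"] + km["male"] * np.asarray(is_male, dtype=float) + km[
        "coast_km"
    ] * np.asarray(coast_km, dtype=float)
    return expit(eta)


def generate_klepto_and_morpho(
    truth: TruthParams,
    tracks: TrackSet,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kleptoparasitism events at forage fixes + per-sex morphometrics.

    Events are Bernoulli per forage-state fix with logistic probability in
    (sex, distance to coast); durations follow the observed 4–45 s range.
    """
    rng = substream(seed, "klepto")
    sex_of = dict(zip(tracks.birds["bird_id"], tracks.birds["sex"]))
    t = tracks.truth
    forage = t[t["state"] == FORAGE]
    rows = []
    if len(forage):
        coast = tracks.world.coast_distance(forage["x"].to_numpy(), forage["y"].to_numpy())
        is_male = forage["bird_id"].map(sex_of).eq("male").to_numpy()
        p = klepto_probability(truth, is_male, coast)
        hit = rng.random(p.size) < p
        durations = rng.integers(4, 46, size=p.size)
        attacker = rng.choice(
            ["adult_female", "juvenile"], size=p.size, p=[10 / 12, 2 / 12]
        )
        sel = np.flatnonzero(hit)
        for i in sel:
            start = forage["timestamp"].iloc[i]
            rows.append(
                {
                    "bird_id": forage["bird_id"].iloc[i],
                    "start": start,
                    "end": start + pd.Timedelta(seconds=int(durations[i])),
                    "attacker_class": attacker[i],
                }
            )
    events = pd.DataFrame(rows, columns=["bird_id", "start", "end", "attacker_class"])

    mrng = substream(seed, "morpho")
    morpho_rows = []
    for _, b in tracks.birds.iterrows():
        mean, cov = truth.morpho_model[b["sex"]]
        draw = mrng.multivariate_normal(mean, cov)
        rec = {"bird_id": b["bird_id"], "sex": b["sex"]}
        rec.update(dict(zip(MORPHO_COLUMNS, draw)))
        morpho_rows.append(rec)
    return events, pd.DataFrame(morpho_rows)


def generate_morpho(
    truth: TruthParams, n_per_sex: int, seed: int = 0
) -> pd.DataFrame:
    """Standalone morphometric table with n birds per sex."""
    rng = substream(seed, "morpho")
    rows = []
    for sex in ("female", "male"):
        mean, cov = truth.morpho_model[sex]
        draws = rng.multivariate_normal(mean, cov, size=n_per_sex)
        for i in range(n_per_sex):
            rec = {"bird_id": f"{sex[0]}{i:04d}", "sex": sex}
            rec.update(dict(zip(MORPHO_COLUMNS, draws[i])))
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV writers (plain-text external interface)
# ---------------------------------------------------------------------------


def write_tracks_csv(tracks: TrackSet, path) -> None:
    out = tracks.fixes.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def write_depth_csv(trace: pd.DataFrame, path) -> None:
    out = trace.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)
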