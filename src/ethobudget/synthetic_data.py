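"""Synthetic tag data with the statistical structure the analyses assume.

Emulates a GPS-accelerometer tag on a dabbling duck:

* behaviour: a sticky first-order Markov chain over the 8-class ethogram at
  the 2-s epoch scale.  Stickiness (the diagonal weight) tunes the short-lag
  dependence between consecutive records while leaving the stationary budget
  free to set; the default stationary budget is resting-dominated with flying
  the rarest class (1%).
* movement: a multi-site diurnal routine (night roost, day feeding sites).
  Displacement is produced only during flying / walking / running epochs;
  flight legs are *scheduled* site-to-site commutes flown at a fixed cruise
  speed (default 15 m/s), so ground-truth distances are analytic.  A
  tortuosity multiplier τ ≥ 1 bends each leg into a two-segment dog-leg whose
  path length is exactly τ × the straight-line displacement.
* GPS: the dense (per-epoch) trajectory sampled on the hour.
* ODBA: 10-min means of behaviour-specific per-epoch intensity draws.

Simulation geometry lives in a local metric plane and is converted to WGS84
via a tangent projection at the site-layout centroid.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .io_formats import (
    EPOCH_S,
    EPOCHS_PER_DAY,
    ETHOGRAM,
    FLYING,
    LABEL_TO_INDEX,
    N_BEHAVIOURS,
    ODBA_WINDOW_S,
    DEFAULT_TIMEZONE,
    BehaviourSequence,
    GpsTrack,
    LocalTangentProjection,
    OdbaSeries,
)

# --------------------------------------------------------------------------
# Default study conditions
# --------------------------------------------------------------------------

#: Stationary time-activity budget of the default Markov chain (ethogram
#: order): resting most common, flying rarest, echoing a dabbling duck's
#: day.  Sums to 1.
DEFAULT_STATIONARY_BUDGET = np.array(
    [0.08, 0.12, 0.20, 0.01, 0.12, 0.35, 0.04, 0.08]
)

#: Behaviour budget used for i.i.d.-epoch oracle simulations (flying = 1%,
#: other classes spanning 4–25% so that rare and common behaviours are both
#: represented while every class stays in the small-p regime where the
#: binomial sampling theory's log-log slopes are ±1/2).
IID_VALIDATION_BUDGET = np.array(
    [0.05, 0.15, 0.20, 0.01, 0.14, 0.25, 0.04, 0.16]
)

#: Diagonal (stay) weight of the default sticky chain; mean bout length
#: 1/(1-s) epochs ≈ 67 s, a realistic behavioural bout at 2-s resolution.
DEFAULT_STICKINESS = 0.97

#: Cruise flight speed, m/s (median non-migratory mallard flight speed ~15.5).
DEFAULT_FLIGHT_SPEED = 15.0

DEFAULT_BEHAVIOUR_SPEEDS = {
    "flying": DEFAULT_FLIGHT_SPEED,
    "walking": 0.3,
    "running": 0.8,
}

#: Per-behaviour ODBA intensity (mean, sd) in arbitrary tag units: flight is
#: by far the most energetic, resting/floating the least.
DEFAULT_ODBA_INTENSITY = {
    "dabbling": (0.60, 0.12),
    "feeding": (0.50, 0.10),
    "floating": (0.20, 0.05),
    "flying": (2.00, 0.30),
    "preening": (0.35, 0.08),
    "resting": (0.10, 0.03),
    "running": (1.20, 0.25),
    "walking": (0.80, 0.15),
}

#: Non-flying budgets conditioned on site role (night roost vs day feeding).
ROOST_BUDGET = {
    "resting": 0.55,
    "floating": 0.18,
    "preening": 0.15,
    "feeding": 0.05,
    "dabbling": 0.04,
    "walking": 0.025,
    "running": 0.005,
}
FEED_BUDGET = {
    "feeding": 0.40,
    "walking": 0.25,
    "dabbling": 0.12,
    "floating": 0.08,
    "resting": 0.08,
    "preening": 0.05,
    "running": 0.02,
}


@dataclasses.dataclass(frozen=True)
class Site:
    """A named location in the routine: a roost or a feeding site."""

    x: float  # local-plane easting, m
    y: float  # local-plane northing, m
    radius_m: float
    role: str  # "roost" | "feed"


def sticky_transition_matrix(
    stationary: np.ndarray, stickiness: float = DEFAULT_STICKINESS
) -> np.ndarray:
    """Row-stochastic P = s·I + (1−s)·1πᵀ with stationary distribution π.

    The mixture form keeps the stationary budget exactly π for any stickiness
    s ∈ [0, 1) while the diagonal weight controls bout length and hence the
    short-lag dependence between records.
    """
    pi = np.asarray(stationary, dtype=float)
    if pi.ndim != 1 or abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
        raise ValueError("stationary budget must be a probability vector")
    if not 0.0 <= stickiness < 1.0:
        raise ValueError("stickiness must be in [0, 1)")
    k = pi.size
    return stickiness * np.eye(k) + (1.0 - stickiness) * np.tile(pi, (k, 1))


def _role_matrix(budget: dict[str, float], stickiness: float) -> np.ndarray:
    """Full 8x8 sticky matrix whose stationary budget is the role budget
    (flying weight 0 — flight is scheduled, not emergent)."""
    pi = np.zeros(N_BEHAVIOURS)
    for label, w in budget.items():
        pi[LABEL_TO_INDEX[label]] = w
    pi = pi / pi.sum()
    return sticky_transition_matrix(pi, stickiness)


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic duck.

    ``diurnal_schedule`` maps hour-of-day (0–23, local) to a site role; when
    several sites share a role the routine rotates among them by day index,
    which produces the multi-day site alternation real ducks show.
    """

    transition_matrix: np.ndarray
    site_layout: list[Site]
    diurnal_schedule: dict[int, str]
    behaviour_speeds: dict[str, float]
    odba_intensity: dict[str, tuple[float, float]]
    tortuosity: float = 1.0
    seed: int = 0
    n_days: int = 6
    fixes_per_day: int = 24
    animal_id: str = "sim01"
    start_day: dt.date = dt.date(2021, 1, 1)
    timezone: str = "UTC"
    stickiness: float = DEFAULT_STICKINESS
    origin_lat: float = -38.0
    origin_lon: float = 144.5

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.shape != (N_BEHAVIOURS, N_BEHAVIOURS):
            raise ValueError("transition matrix must be 8x8")
        if np.abs(P.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("transition matrix rows must sum to 1 within 1e-12")
        if (P < 0).any():
            raise ValueError("transition matrix entries must be non-negative")
        self.transition_matrix = P
        if self.tortuosity < 1.0:
            raise ValueError("tortuosity must be >= 1")
        if any(v < 0 for v in self.behaviour_speeds.values()):
            raise ValueError("behaviour speeds must be >= 0")
        roles = {s.role for s in self.site_layout}
        missing = set(self.diurnal_schedule.values()) - roles
        if missing and self.site_layout:
            raise ValueError(f"diurnal schedule references undefined site role(s) {missing}")

    # -- canned scenarios ---------------------------------------------------

    @classmethod
    def default(cls, seed: int = 0, n_days: int = 6, tortuosity: float = 1.2,
                **overrides) -> "SimulationConfig":
        """Four-site routine: 2 night roosts, 2 day feeding sites, rotated
        by day; legs 1.8 km so every commute is an exact number of epochs."""
        sites = [
            Site(0.0, 0.0, 12.0, "roost"),
            Site(450.0, 0.0, 12.0, "roost"),
            Site(0.0, -1800.0, 12.0, "feed"),
            Site(450.0, -1800.0, 12.0, "feed"),
        ]
        schedule = {h: ("feed" if 6 <= h <= 18 else "roost") for h in range(24)}
        kwargs = dict(
            transition_matrix=sticky_transition_matrix(DEFAULT_STATIONARY_BUDGET),
            site_layout=sites,
            diurnal_schedule=schedule,
            behaviour_speeds=dict(DEFAULT_BEHAVIOUR_SPEEDS),
            odba_intensity=dict(DEFAULT_ODBA_INTENSITY),
            tortuosity=tortuosity,
            seed=seed,
            n_days=n_days,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def commute(cls, tortuosity: float = 1.0, seed: int = 0, n_days: int = 4,
                leg_m: float = 9000.0, **overrides) -> "SimulationConfig":
        """Degenerate two-site scenario for distance validation: single
        hourly flight legs (9 km roost↔feed commutes at hours 6, 12 and 18),
        no walking/running displacement, so behaviour-based and GPS-based
        daily distances coincide analytically when tortuosity is 1."""
        sites = [
            Site(0.0, 0.0, 50.0, "roost"),
            Site(0.0, -leg_m, 50.0, "feed"),
        ]
        schedule = {}
        for h in range(24):
            schedule[h] = "feed" if (6 <= h <= 11 or h >= 18) else "roost"
        speeds = dict(DEFAULT_BEHAVIOUR_SPEEDS)
        speeds["walking"] = 0.0
        speeds["running"] = 0.0
        kwargs = dict(
            transition_matrix=sticky_transition_matrix(DEFAULT_STATIONARY_BUDGET),
            site_layout=sites,
            diurnal_schedule=schedule,
            behaviour_speeds=speeds,
            odba_intensity=dict(DEFAULT_ODBA_INTENSITY),
            tortuosity=tortuosity,
            seed=seed,
            n_days=n_days,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def projection(self) -> LocalTangentProjection:
        return LocalTangentProjection(self.origin_lat, self.origin_lon)


@dataclasses.dataclass
class GroundTruth:
    """Analytic truth accompanying a simulation."""

    budgets: pd.DataFrame  # day x behaviour daily proportions
    dense_paths: dict[dt.date, np.ndarray]  # (n_epochs, 2) local xy per epoch
    site_occupancy_s: dict[int, float]  # site index -> seconds
    flight_legs: pd.DataFrame  # day, hour, from_site, to_site, straight_m, path_m, duration_s

    def daily_straight_distance_m(self) -> pd.Series:
        if self.flight_legs.empty:
            return pd.Series(dtype=float)
        return self.flight_legs.groupby("day")["straight_m"].sum()

    def daily_path_distance_m(self) -> pd.Series:
        if self.flight_legs.empty:
            return pd.Series(dtype=float)
        return self.flight_legs.groupby("day")["path_m"].sum()


# --------------------------------------------------------------------------
# Stationary distribution
# --------------------------------------------------------------------------


def stationary_distribution(transition_matrix: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Stationary (left eigenvalue-1) distribution of a row-stochastic matrix.

    For an irreducible aperiodic chain this is the unique probability vector
    with πP = π.  If the eigen decomposition does not give a unique
    non-negative solution (reducible or periodic chain) a warning is issued
    and power iteration from the uniform vector is used instead (tolerance
    1e-12, up to 100,000 iterations).
    """
    P = np.asarray(transition_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.abs(P.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("rows must sum to 1")
    vals, vecs = scipy.linalg.eig(P.T)
    close = np.isclose(vals, 1.0, atol=1e-10)
    if close.sum() == 1:
        v = np.real(vecs[:, close].ravel())
        if v.sum() < 0:
            v = -v
        if (v >= -1e-12).all():
            v = np.clip(v, 0.0, None)
            return v / v.sum()
    warnings.warn(
        "transition matrix has no unique eigenvalue-1 distribution "
        "(reducible or periodic chain); falling back to power iteration",
        stacklevel=2,
    )
    v = np.full(P.shape[0], 1.0 / P.shape[0])
    for _ in range(100_000):
        nxt = v @ P
        if np.abs(nxt - v).max() < tol:
            return nxt / nxt.sum()
        v = nxt
    return v / v.sum()


# --------------------------------------------------------------------------
# Behaviour simulation
# --------------------------------------------------------------------------


def _day_times(day: dt.date, timezone: str, n_epochs: int = EPOCHS_PER_DAY) -> np.ndarray:
    """UTC epoch-start times for a local day (datetime64[s])."""
    start = pd.Timestamp(day, tz=timezone).tz_convert("UTC").tz_localize(None)
    start = np.datetime64(start, "s")
    return start + np.arange(n_epochs, dtype="int64") * np.timedelta64(EPOCH_S, "s")


def _simulate_chain(P: np.ndarray, init: np.ndarray, n_steps: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Simulate independent Markov chains (one per row of ``init``) for
    ``n_steps`` steps; vectorized across chains."""
    n_chains = init.size
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    out = np.empty((n_chains, n_steps), dtype=np.int8)
    state = init.astype(np.intp)
    out[:, 0] = state
    u = rng.random((n_steps - 1, n_chains))
    for t in range(1, n_steps):
        state = (u[t - 1][:, None] > cum[state]).sum(axis=1).astype(np.intp)
        out[:, t] = state
    return out


def simulate_behaviour_days(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[BehaviourSequence], GroundTruth]:
    """Simulate ``n_days`` full days of the configured Markov chain.

    Each day is an independent chain started from the stationary
    distribution, so pooled empirical proportions converge to it.  Identical
    seeds give identical output.
    """
    if config.n_days <= 0:
        raise ValueError("n_days must be positive")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pi = stationary_distribution(config.transition_matrix)
    init = rng.choice(N_BEHAVIOURS, size=config.n_days, p=pi)
    codes = _simulate_chain(config.transition_matrix, init, EPOCHS_PER_DAY, rng)
    sequences = []
    budgets = []
    for d in range(config.n_days):
        day = config.start_day + dt.timedelta(days=d)
        times = _day_times(day, config.timezone)
        seq = BehaviourSequence(config.animal_id, day, times, codes[d])
        sequences.append(seq)
        budgets.append(np.bincount(codes[d], minlength=N_BEHAVIOURS) / EPOCHS_PER_DAY)
    budget_df = pd.DataFrame(
        budgets, index=[s.day for s in sequences], columns=list(ETHOGRAM)
    )
    truth = GroundTruth(
        budgets=budget_df,
        dense_paths={},
        site_occupancy_s={},
        flight_legs=pd.DataFrame(
            columns=["day", "hour", "from_site", "to_site", "straight_m", "path_m", "duration_s"]
        ),
    )
    return sequences, truth


def simulate_iid_days(
    p: np.ndarray,
    n_days: int,
    seed: int = 0,
    animal_id: str = "iid01",
    start_day: dt.date = dt.date(2021, 1, 1),
) -> list[BehaviourSequence]:
    """Days whose 2-s epochs are drawn i.i.d. from the budget ``p`` — the
    independence regime under which the binomial expected-error-ratio oracle
    is exact."""
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must sum to 1")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(p)
    cum[-1] = 1.0
    draws = rng.random((n_days, EPOCHS_PER_DAY))
    codes = np.searchsorted(cum, draws, side="right").astype(np.int8)
    out = []
    for d in range(n_days):
        day = start_day + dt.timedelta(days=d)
        out.append(BehaviourSequence(animal_id, day, _day_times(day, "UTC"), codes[d]))
    return out


# --------------------------------------------------------------------------
# Scheduled routine (behaviour + trajectory + GPS + ODBA)
# --------------------------------------------------------------------------


def _sites_by_role(config: SimulationConfig) -> dict[str, list[int]]:
    roles: dict[str, list[int]] = {}
    for i, s in enumerate(config.site_layout):
        roles.setdefault(s.role, []).append(i)
    return roles


def _site_for(config: SimulationConfig, role: str, day_index: int) -> int:
    """Rotate among same-role sites by day index (multi-day alternation)."""
    candidates = _sites_by_role(config)[role]
    return candidates[day_index % len(candidates)]


def _planned_day(config: SimulationConfig, day_index: int, current_site: int):
    """Per-hour target site and the flight legs a day requires.

    Returns (hour_sites, legs) where legs are (hour, from_site, to_site).
    """
    hour_sites = []
    legs = []
    site = current_site
    for h in range(24):
        role = config.diurnal_schedule[h]
        target = _site_for(config, role, day_index)
        if target != site:
            legs.append((h, site, target))
            site = target
        hour_sites.append(site)
    return hour_sites, legs


def _leg_geometry(a: np.ndarray, b: np.ndarray, path_m: float) -> tuple[np.ndarray, float]:
    """Two-segment dog-leg from a to b with total length ``path_m`` >= |b-a|.

    Returns the kink point and the actual path length.  Straight when
    path_m equals the displacement.
    """
    d = b - a
    L = float(np.hypot(*d))
    if path_m <= L + 1e-9 or L == 0.0:
        return (a + d / 2.0, max(L, path_m))
    half = path_m / 2.0
    mid = a + d / 2.0
    # kink offset perpendicular to the direct line
    off = math.sqrt(max(half**2 - (L / 2.0) ** 2, 0.0))
    perp = np.array([-d[1], d[0]]) / L
    return (mid + off * perp, path_m)


def _positions_along_leg(a, kink, b, arc: np.ndarray) -> np.ndarray:
    """Positions at arc lengths ``arc`` along the polyline a-kink-b."""
    seg1 = float(np.hypot(*(kink - a)))
    seg2 = float(np.hypot(*(b - kink)))
    total = seg1 + seg2
    arc = np.clip(arc, 0.0, total)
    pos = np.empty((arc.size, 2))
    first = arc <= seg1
    if seg1 > 0:
        t = (arc[first] / seg1)[:, None]
        pos[first] = a + t * (kink - a)
    else:
        pos[first] = a
    if seg2 > 0:
        t = ((arc[~first] - seg1) / seg2)[:, None]
        pos[~first] = kink + t * (b - kink)
    else:
        pos[~first] = b
    return pos


def simulate_routine_days(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[BehaviourSequence], pd.DataFrame]:
    """Behaviour sequences following the diurnal site schedule.

    Each hour is filled from a role-conditioned sticky chain (roost: resting-
    dominated; feed: feeding/walking-dominated); at every scheduled site
    change a flight bout of exactly the commute duration (τ·distance / speed,
    rounded up to the 2-s grid) is written at the top of the hour.

    Returns the sequences and the planned flight-leg table.
    """
    if config.n_days <= 0:
        raise ValueError("n_days must be positive")
    if not config.site_layout:
        raise ValueError("site_layout must be non-empty")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    v = config.behaviour_speeds.get("flying", DEFAULT_FLIGHT_SPEED)
    if v <= 0:
        raise ValueError("flying speed must be positive to commute between sites")
    role_mats = {
        "roost": _role_matrix(ROOST_BUDGET, config.stickiness),
        "feed": _role_matrix(FEED_BUDGET, config.stickiness),
    }
    role_pis = {r: stationary_distribution(m) for r, m in role_mats.items()}
    xy = np.array([[s.x, s.y] for s in config.site_layout])

    site = _site_for(config, config.diurnal_schedule[0], 0)
    # plan all days first so the hourly chains can be simulated vectorized
    # across days (the schedule's hour->role map is day-independent)
    plans = []
    for d in range(config.n_days):
        hour_sites, legs = _planned_day(config, d, site)
        plans.append((hour_sites, legs))
        site = hour_sites[-1]
    all_codes = np.empty((config.n_days, EPOCHS_PER_DAY), dtype=np.int8)
    steps_per_hour = EPOCHS_PER_DAY // 24
    for h in range(24):
        role = config.diurnal_schedule[h]
        P = role_mats[role]
        init = rng.choice(N_BEHAVIOURS, size=config.n_days, p=role_pis[role])
        all_codes[:, h * steps_per_hour : (h + 1) * steps_per_hour] = _simulate_chain(
            P, init, steps_per_hour, rng
        )
    sequences = []
    leg_rows = []
    for d in range(config.n_days):
        day = config.start_day + dt.timedelta(days=d)
        hour_sites, legs = plans[d]
        codes = all_codes[d]
        # overwrite scheduled flight bouts at the top of each commuting hour
        for h, s_from, s_to in legs:
            L = float(np.hypot(*(xy[s_to] - xy[s_from])))
            path = config.tortuosity * L
            n_fly = int(math.ceil(path / (v * EPOCH_S)))
            if n_fly > 1800:
                raise ValueError("commute leg does not fit within one hour")
            codes[h * 1800 : h * 1800 + n_fly] = FLYING
            leg_rows.append(
                {
                    "day": day,
                    "hour": h,
                    "from_site": s_from,
                    "to_site": s_to,
                    "straight_m": L,
                    "path_m": n_fly * EPOCH_S * v,
                    "duration_s": n_fly * EPOCH_S,
                }
            )
        times = _day_times(day, config.timezone)
        sequences.append(BehaviourSequence(config.animal_id, day, times, codes))
    legs_df = pd.DataFrame(
        leg_rows,
        columns=["day", "hour", "from_site", "to_site", "straight_m", "path_m", "duration_s"],
    )
    return sequences, legs_df


def simulate_trajectory(
    sequences: Sequence[BehaviourSequence],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    legs: pd.DataFrame | None = None,
) -> tuple[dict[dt.date, np.ndarray], GpsTrack, OdbaSeries, GroundTruth]:
    """Dense per-epoch trajectory, hourly GPS fixes and ODBA series.

    Displacement happens only during flying / walking / running epochs.
    Flying bouts that coincide with a scheduled commute fly a dog-leg to the
    target site (path length = speed × bout duration, endpoint exactly the
    target); unscheduled flying bouts are flown out-and-back so they add path
    but no net displacement.  Walking/running is a bounded random walk inside
    the current site's radius.  ODBA windows average per-epoch Gaussian draws
    whose mean/sd depend on behaviour.
    """
    if not config.site_layout:
        raise ValueError("site_layout must be non-empty")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    v_fly = config.behaviour_speeds.get("flying", DEFAULT_FLIGHT_SPEED)
    v_walk = config.behaviour_speeds.get("walking", 0.0)
    v_run = config.behaviour_speeds.get("running", 0.0)
    xy_sites = np.array([[s.x, s.y] for s in config.site_layout])
    proj = config.projection

    if legs is None:
        legs = pd.DataFrame(columns=["day", "hour", "from_site", "to_site"])
    legs_by_day: dict[dt.date, list] = {}
    for _, row in legs.iterrows():
        legs_by_day.setdefault(row["day"], []).append(row)

    start_site = _site_for(config, config.diurnal_schedule[0], 0) if config.diurnal_schedule else 0
    pos = xy_sites[start_site].astype(float).copy()
    current_site = start_site
    site_occ = {i: 0.0 for i in range(len(config.site_layout))}

    dense: dict[dt.date, np.ndarray] = {}
    fix_rows = []
    odba_rows = []
    budgets = []
    mu = np.array([config.odba_intensity[b][0] for b in ETHOGRAM])
    sd = np.array([config.odba_intensity[b][1] for b in ETHOGRAM])

    for seq in sequences:
        codes = seq.codes
        n = codes.size
        path = np.empty((n, 2))
        # scheduled commute bouts for this day, keyed by start epoch (hour top)
        day_legs = {int(r["hour"]) * 1800: r for r in legs_by_day.get(seq.day, [])}
        # locate flying runs
        fly = codes == FLYING
        boundaries = np.flatnonzero(np.diff(fly.astype(np.int8)) != 0) + 1
        starts = [0] + boundaries.tolist()
        ends = boundaries.tolist() + [n]
        for s0, e0 in zip(starts, ends):
            seg = codes[s0:e0]
            if fly[s0]:
                T = (e0 - s0) * EPOCH_S
                if s0 in day_legs:
                    row = day_legs[s0]
                    target = xy_sites[int(row["to_site"])]
                    a = pos.copy()
                    kink, total = _leg_geometry(a, target, v_fly * T)
                    arcs = np.arange(e0 - s0) * EPOCH_S * v_fly
                    path[s0:e0] = _positions_along_leg(a, kink, target, arcs)
                    pos = target.astype(float).copy()
                    current_site = int(row["to_site"])
                else:
                    # out-and-back local flight: no net displacement
                    heading = rng.uniform(0, 2 * math.pi)
                    u = np.array([math.cos(heading), math.sin(heading)])
                    arcs = np.arange(e0 - s0) * EPOCH_S * v_fly
                    half = v_fly * T / 2.0
                    out = np.minimum(arcs, half)
                    back = np.maximum(arcs - half, 0.0)
                    path[s0:e0] = pos + np.outer(out - back, u)
            else:
                steps = np.zeros((e0 - s0, 2))
                speeds = np.where(
                    seg == LABEL_TO_INDEX["walking"],
                    v_walk,
                    np.where(seg == LABEL_TO_INDEX["running"], v_run, 0.0),
                )
                moving = speeds > 0
                if moving.any():
                    theta = rng.uniform(0, 2 * math.pi, size=int(moving.sum()))
                    steps[moving, 0] = speeds[moving] * EPOCH_S * np.cos(theta)
                    steps[moving, 1] = speeds[moving] * EPOCH_S * np.sin(theta)
                    centre = xy_sites[current_site]
                    radius = config.site_layout[current_site].radius_m
                    p = pos.copy()
                    for i in range(e0 - s0):
                        path[s0 + i] = p
                        cand = p + steps[i]
                        if np.hypot(*(cand - centre)) > radius:
                            cand = p  # step rejected at the site boundary
                        p = cand
                    pos = p
                else:
                    path[s0:e0] = pos
        dense[seq.day] = path
        # site occupancy: epochs attributed to the nearest site
        d2 = ((path[:, None, :] - xy_sites[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)
        for i in range(len(config.site_layout)):
            site_occ[i] += float((nearest == i).sum()) * EPOCH_S
        budgets.append(np.bincount(codes, minlength=N_BEHAVIOURS) / codes.size)

        # hourly fixes: dense path sampled on the hour
        fix_idx = np.arange(config.fixes_per_day) * (3600 // EPOCH_S)
        fix_idx = fix_idx[fix_idx < n]
        lat, lon = proj.inverse(path[fix_idx, 0], path[fix_idx, 1])
        for idx, la, lo in zip(fix_idx, np.atleast_1d(lat), np.atleast_1d(lon)):
            fix_rows.append(
                {
                    "timestamp": pd.Timestamp(seq.times[idx]).tz_localize("UTC"),
                    "lat": float(la),
                    "lon": float(lo),
                }
            )

        # ODBA: mean of per-epoch behaviour-specific draws per 10-min window
        draws = np.clip(rng.normal(mu[codes], sd[codes]), 0.0, None)
        n_windows = n // (ODBA_WINDOW_S // EPOCH_S)
        win = ODBA_WINDOW_S // EPOCH_S
        means = draws[: n_windows * win].reshape(n_windows, win).mean(axis=1)
        for w in range(n_windows):
            odba_rows.append(
                {
                    "timestamp": pd.Timestamp(seq.times[w * win]).tz_localize("UTC"),
                    "odba": float(means[w]),
                }
            )

    track = GpsTrack(config.animal_id, pd.DataFrame(fix_rows))
    odba = OdbaSeries(config.animal_id, pd.DataFrame(odba_rows))
    budget_df = pd.DataFrame(
        budgets, index=[s.day for s in sequences], columns=list(ETHOGRAM)
    )
    truth = GroundTruth(
        budgets=budget_df,
        dense_paths=dense,
        site_occupancy_s=site_occ,
        flight_legs=legs,
    )
    return dense, track, odba, truth


def simulate_tag_data(
    config: SimulationConfig,
) -> tuple[list[BehaviourSequence], GpsTrack, OdbaSeries, GroundTruth]:
    """Full synthetic deployment: scheduled routine behaviour + trajectory +
    hourly GPS + ODBA, with analytic ground truth.  Deterministic in the
    config seed."""
    rng = np.random.default_rng(config.seed)
    sequences, legs = simulate_routine_days(config, rng)
    _, track, odba, truth = simulate_trajectory(sequences, config, rng, legs=legs)
    return sequences, track, odba, truth
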