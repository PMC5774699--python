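"""Domain types shared by every task: positions, clocks, particles, ensembles.

The particle container is a structure-of-arrays (:class:`Ensemble`) so that
propagation is vectorized over the whole stack; :class:`Particle` is a
lightweight per-index view for inspection and tests.  Biology-defined state
lives in ``Ensemble.state`` as a dict of parallel arrays owned by the biology
model — core code never interprets it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

from .geometry import normalize_lon


class Mobility(enum.IntEnum):
    """Particle mobility / accounting status.

    FREE particles move; FROZEN particles are held in place but remain part
    of the active stack (used e.g. for staggered releases); DEAD, SETTLED
    and LEFT_DOMAIN are deactivated — excluded from propagation but retained
    for accounting (conservation: active + deactivated = released).
    """

    FREE = 0
    FROZEN = 1
    DEAD = 2
    SETTLED = 3
    LEFT_DOMAIN = 4


#: statuses that count as deactivated (excluded from propagation, kept for
#: bookkeeping)
DEACTIVATED_STATUSES = (Mobility.DEAD, Mobility.SETTLED, Mobility.LEFT_DOMAIN)


@dataclass(frozen=True)
class GeoPosition:
    """A point in geographic coordinates.

    Parameters
    ----------
    lon : float
        Degrees East; any value in [-180, 360) is accepted and normalized
        to the [-180, 180) branch.
    lat : float
        Degrees North, in [-90, 90].
    depth : float
        Metres below the sea surface, positive downward, >= 0.
    """

    lon: float
    lat: float
    depth: float = 0.0

    def __post_init__(self):
        if not -180.0 <= self.lon < 360.0:
            raise ValueError(f"longitude {self.lon} outside admitted range [-180, 360)")
        object.__setattr__(self, "lon", float(normalize_lon(self.lon)))
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if self.depth < 0.0:
            raise ValueError(f"depth {self.depth} must be >= 0 (positive downward)")


class Direction(str, enum.Enum):
    FORWARD = "forward"
    BACKWARD = "backward"


@dataclass(frozen=True)
class SimClock:
    """Master simulation clock: a calendar datetime plus a time direction.

    Clock arithmetic is exact at second (indeed microsecond) resolution:
    advancing by ``s`` seconds then by ``-s`` restores the datetime bitwise.
    The calendar is proleptic Gregorian without leap seconds, matching
    hydrographic model practice.
    """

    time: datetime
    direction: Direction = Direction.FORWARD

    @property
    def signed_step_sign(self) -> int:
        return 1 if self.direction == Direction.FORWARD else -1

    def advanced(self, seconds: float) -> "SimClock":
        return replace(self, time=self.time + timedelta(seconds=seconds))


def advance_clock(clock: SimClock, seconds: float) -> SimClock:
    """Return a new clock offset by `seconds` (signed); original unchanged."""
    return clock.advanced(seconds)


@dataclass(frozen=True)
class BoundaryPolicy:
    """Per-axis response when a candidate position leaves the wet domain.

    ``reflect``: specular mirror at the offending surface/coast face;
    ``absorb``: deactivate with reason ``left_domain``;
    ``sticky``: freeze at the last wet position.
    """

    horizontal: str = "reflect"
    vertical: str = "reflect"

    def __post_init__(self):
        for name in (self.horizontal, self.vertical):
            if name not in ("reflect", "absorb", "sticky"):
                raise ValueError(f"unknown boundary policy {name!r}")


@dataclass(frozen=True)
class SpatialAttributes:
    """Spatial component of a particle: position, mobility, boundary policy."""

    position: GeoPosition
    mobility: Mobility = Mobility.FREE
    boundary_policy: BoundaryPolicy = BoundaryPolicy()


@dataclass(frozen=True)
class Particle:
    """Read-only view of one particle: spatial attributes + opaque state.

    `state` holds the biology-defined scalars for this particle (empty for
    the passive null model); core code never interprets them.
    """

    id: int
    spatial: SpatialAttributes
    state: dict = field(default_factory=dict)


@dataclass
class ReleaseSpec:
    """Where, when and how many particles to release.

    The region is a lon/lat box (optionally a habitat polygon id resolved by
    the connectivity task).  Vertical placement is either a fixed depth or
    uniform through the local water column.  Positions are drawn uniformly
    over the region with rejection against the provider's wet mask, capped
    at `max_attempts` trials per particle.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    count: int
    depth: float = 0.0
    vertical: str = "fixed"  # "fixed" | "uniform"
    start: Optional[datetime] = None
    end: Optional[datetime] = None
    seed: int = 0
    region_name: str = "release-box"
    max_attempts: int = 1000

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("release count must be >= 0")
        if self.vertical not in ("fixed", "uniform"):
            raise ValueError(f"unknown vertical placement {self.vertical!r}")


class Ensemble:
    """A stack of particles stored as parallel arrays.

    Iteration order is release order and deterministic.  Deactivated
    particles keep their last position (e.g. the settlement position) so the
    connectivity tally can read it back.
    """

    def __init__(self, lon, lat, depth, ids=None,
                 boundary_policy: BoundaryPolicy = BoundaryPolicy(),
                 release_time=None, origin=None):
        self.lon = np.atleast_1d(np.asarray(lon, dtype=np.float64)).copy()
        self.lat = np.atleast_1d(np.asarray(lat, dtype=np.float64)).copy()
        self.depth = np.atleast_1d(np.asarray(depth, dtype=np.float64)).copy()
        n = self.lon.size
        if not (self.lat.size == n and self.depth.size == n):
            raise ValueError("lon/lat/depth arrays must have equal length")
        self.ids = (np.arange(n, dtype=np.int64) if ids is None
                    else np.asarray(ids, dtype=np.int64).copy())
        self.status = np.full(n, Mobility.FREE, dtype=np.int8)
        self.boundary_policy = boundary_policy
        # seconds offset of each particle's release relative to run start;
        # particles are FROZEN until the clock passes it (staggered windows)
        self.release_offset = (np.zeros(n) if release_time is None
                               else np.asarray(release_time, float).copy())
        # source habitat index for connectivity runs, -1 otherwise
        self.origin = (np.full(n, -1, dtype=np.int32) if origin is None
                       else np.asarray(origin, dtype=np.int32).copy())
        self.settle_habitat = np.full(n, -1, dtype=np.int32)
        self.settle_age = np.full(n, np.nan)
        self.state: dict[str, np.ndarray] = {}
        self.released = n

    # -- factory -----------------------------------------------------------
    @classmethod
    def empty(cls, boundary_policy: BoundaryPolicy = BoundaryPolicy()) -> "Ensemble":
        e = cls(np.empty(0), np.empty(0), np.empty(0),
                boundary_policy=boundary_policy)
        return e

    # -- basic queries ------------------------------------------------------
    def __len__(self) -> int:
        return self.lon.size

    @property
    def capacity(self) -> int:
        return self.lon.size

    @property
    def active_mask(self) -> np.ndarray:
        return self.status < Mobility.DEAD

    @property
    def moving_mask(self) -> np.ndarray:
        return self.status == Mobility.FREE

    @property
    def active_count(self) -> int:
        return int(np.count_nonzero(self.active_mask))

    @property
    def deactivated_count(self) -> int:
        return len(self) - self.active_count

    def particle(self, id: int) -> Particle:
        """Return a read-only view of the particle with the given id."""
        idx = self._index_of(id)
        pos = GeoPosition(self.lon[idx], self.lat[idx], max(self.depth[idx], 0.0))
        spatial = SpatialAttributes(pos, Mobility(int(self.status[idx])),
                                    self.boundary_policy)
        state = {k: v[idx] for k, v in self.state.items()}
        return Particle(int(self.ids[idx]), spatial, state)

    def __iter__(self):
        for pid in self.ids:
            yield self.particle(int(pid))

    def _index_of(self, id: int) -> int:
        idx = np.flatnonzero(self.ids == id)
        if idx.size == 0:
            raise KeyError(f"unknown particle id {id}")
        return int(idx[0])


def deactivate(ensemble: Ensemble, id: int, reason: str) -> Ensemble:
    """Flag a particle as dead / settled / left_domain (in place).

    The particle is excluded from further propagation but keeps its position
    and state for accounting.  Unknown ids raise ``KeyError``.
    """
    status = {"dead": Mobility.DEAD, "settled": Mobility.SETTLED,
              "left_domain": Mobility.LEFT_DOMAIN}.get(reason)
    if status is None:
        raise ValueError(f"unknown deactivation reason {reason!r}")
    idx = ensemble._index_of(id)
    ensemble.status[idx] = status
    return ensemble


def release_ensemble(spec: ReleaseSpec, physics) -> Ensemble:
    """Draw `spec.count` wet positions uniformly over the release region.

    Identical spec (including seed) gives bit-identical positions.  Raises
    ``RuntimeError`` naming the region if no wet position is found within
    ``spec.max_attempts`` rejection-sampling rounds.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.count
    lon = np.empty(n)
    lat = np.empty(n)
    depth = np.empty(n)
    pending = np.arange(n)
    attempts = 0
    while pending.size:
        if attempts >= spec.max_attempts:
            raise RuntimeError(
                f"release region {spec.region_name!r}: no wet position found "
                f"for {pending.size} particle(s) after {attempts} attempts "
                "(region may be entirely dry)")
        m = pending.size
        cand_lon = rng.uniform(spec.lon_min, spec.lon_max, m)
        cand_lat = rng.uniform(spec.lat_min, spec.lat_max, m)
        if spec.vertical == "uniform":
            wd = np.asarray(physics.wdepth(cand_lon, cand_lat), float)
            cand_depth = rng.uniform(0.0, np.maximum(wd, 0.0), m)
        else:
            cand_depth = np.full(m, spec.depth)
        ok = np.asarray(physics.is_wet(cand_lon, cand_lat, cand_depth), bool)
        take = pending[ok]
        lon[take] = cand_lon[ok]
        lat[take] = cand_lat[ok]
        depth[take] = cand_depth[ok]
        pending = pending[~ok]
        attempts += 1

    release_offset = np.zeros(n)
    if spec.start is not None and spec.end is not None and spec.end > spec.start:
        window = (spec.end - spec.start).total_seconds()
        release_offset = np.sort(rng.uniform(0.0, window, n))
    ens = Ensemble(lon, lat, depth, release_time=release_offset)
    if np.any(release_offset > 0):
        ens.status[release_offset > 0] = Mobility.FROZEN
    return ens
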