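"""Task drivers: Lagrangian simulation, connectivity, averaging, Eulerian ADR.

The four offline workflows built on the physics/biology contracts:

* :func:`run_simulation` — forward or backward ensemble propagation with
  trajectory recording;
* :func:`compute_connectivity` — release propagules per source habitat,
  tally survival-weighted settlements per sink, and estimate the transport
  probability matrix T[j, i] = N[j, i] / R[i];
* :func:`extract_average` — region/period statistics of provider fields on
  a regular space-time sampling lattice;
* :func:`run_eulerian` — an explicit finite-volume solver for the
  advection-diffusion-reaction equation dC/dt = -div(u C - K grad C) + G(C)
  in a closed box, first-order upwind advection + centred diffusion in
  conservative flux form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from datetime import datetime
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box as shapely_box, shape as shapely_shape

from .core import (Ensemble, Mobility, ReleaseSpec, SimClock, Direction,
                   release_ensemble)
from .geometry import M_PER_DEG_LAT, m_per_deg_lon
from .kinematics import StepConfig, step_ensemble


# ---------------------------------------------------------------------------
# Habitats
# ---------------------------------------------------------------------------

@dataclass
class Habitat:
    """A named habitat polygon with a role and a suitability weight.

    role: 'source' (spawning only), 'sink' (settlement only) or 'both'.
    suitability scales the probability that a first entry of a competent
    propagule becomes a settlement.
    """

    id: str
    geometry: "shapely.Geometry"
    role: str = "both"
    suitability: float = 1.0

    def __post_init__(self):
        if self.role not in ("source", "sink", "both"):
            raise ValueError(f"habitat {self.id!r}: unknown role {self.role!r}")
        if not (0.0 <= self.suitability <= 1.0):
            raise ValueError(f"habitat {self.id!r}: suitability must be in [0,1]")
        if self.geometry.is_empty:
            raise ValueError(f"habitat {self.id!r}: empty geometry")
        if not self.geometry.is_valid:
            raise ValueError(f"habitat {self.id!r}: polygon is not simple/valid")

    @classmethod
    def from_box(cls, id, lon_min, lon_max, lat_min, lat_max, role="both",
                 suitability=1.0):
        return cls(id, shapely_box(lon_min, lat_min, lon_max, lat_max),
                   role, suitability)

    def contains(self, lon, lat):
        return shapely.contains_xy(self.geometry, np.asarray(lon, float),
                                   np.asarray(lat, float))

    @property
    def area_km2(self) -> float:
        """Polygon area in km^2 in the local metric at the centroid latitude."""
        lat0 = self.geometry.centroid.y
        return float(self.geometry.area * m_per_deg_lon(lat0)
                     * M_PER_DEG_LAT / 1e6)


class HabitatSet:
    """An ordered collection of habitats with unique ids."""

    def __init__(self, habitats: Sequence[Habitat]):
        ids = [h.id for h in habitats]
        if len(set(ids)) != len(ids):
            raise ValueError("habitat ids must be unique")
        self.habitats = list(habitats)

    def __iter__(self):
        return iter(self.habitats)

    def __len__(self):
        return len(self.habitats)

    def __getitem__(self, id):
        for h in self.habitats:
            if h.id == id:
                return h
        raise KeyError(id)

    @property
    def sources(self):
        return [h for h in self.habitats if h.role in ("source", "both")]

    @property
    def sinks(self):
        return [h for h in self.habitats if h.role in ("sink", "both")]

    @classmethod
    def from_geojson(cls, path) -> "HabitatSet":
        with open(path) as fh:
            gj = json.load(fh)
        habitats = []
        for feat in gj["features"]:
            props = feat.get("properties", {})
            habitats.append(Habitat(
                id=str(props.get("id", len(habitats))),
                geometry=shapely_shape(feat["geometry"]),
                role=props.get("role", "both"),
                suitability=float(props.get("suitability", 1.0))))
        return cls(habitats)

    @classmethod
    def from_csv(cls, path) -> "HabitatSet":
        df = pd.read_csv(path, comment="#")
        habitats = [Habitat.from_box(
            str(r.id), r.lon_min, r.lon_max, r.lat_min, r.lat_max,
            getattr(r, "role", "both"),
            float(getattr(r, "suitability", 1.0)))
            for r in df.itertuples(index=False)]
        return cls(habitats)


# ---------------------------------------------------------------------------
# Lagrangian simulation driver
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryRecord:
    """Recorded trajectory: times plus (n_snapshots, n_particles) arrays."""

    times: list
    ids: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    status: np.ndarray
    state: dict = dc_field(default_factory=dict)
    events: dict = dc_field(default_factory=dict)
    meta: dict = dc_field(default_factory=dict)


def _check_coverage(physics, start: datetime, end: datetime):
    """Fail before stepping begins when the forcing does not span the run."""
    for t in (start, end):
        physics.update(t)
    physics.update(start)


def run_simulation(ensemble: Ensemble, physics, biology, cfg: StepConfig,
                   start: datetime, n_steps: int, record_every: int = 1,
                   record_state: Sequence[str] = ()) -> TrajectoryRecord:
    """Propagate the ensemble n_steps of cfg.dt from `start`.

    Runs backward in time when cfg.direction == 'backward'.  Positions (and
    the requested state variables) are recorded every `record_every` steps,
    including the initial and final instants.  Raises before the first step
    if the provider does not cover the simulated window.
    """
    direction = (Direction.FORWARD if cfg.direction == "forward"
                 else Direction.BACKWARD)
    clock = SimClock(start, direction)
    end = clock.advanced(cfg.sign * cfg.dt * n_steps).time
    _check_coverage(physics, start, end)

    if biology is not None and not ensemble.state:
        ensemble.state = biology.init_state(len(ensemble),
                                            np.random.default_rng(cfg.seed + 1))

    events: dict = {}
    times = [clock.time]
    snaps_lon = [ensemble.lon.copy()]
    snaps_lat = [ensemble.lat.copy()]
    snaps_z = [ensemble.depth.copy()]
    snaps_status = [ensemble.status.copy()]
    snaps_state = {k: [ensemble.state[k].copy()] for k in record_state}
    elapsed = 0.0
    for step in range(n_steps):
        # staggered-window releases: free the particles whose time has come
        pending = (ensemble.status == Mobility.FROZEN) \
            & (ensemble.release_offset <= elapsed)
        if pending.any():
            ensemble.status[pending] = Mobility.FREE
        physics.update(clock.time)
        clock = step_ensemble(ensemble, physics, biology, cfg, clock,
                              events=events)
        elapsed += cfg.dt
        if (step + 1) % record_every == 0 or step == n_steps - 1:
            times.append(clock.time)
            snaps_lon.append(ensemble.lon.copy())
            snaps_lat.append(ensemble.lat.copy())
            snaps_z.append(ensemble.depth.copy())
            snaps_status.append(ensemble.status.copy())
            for k in record_state:
                snaps_state[k].append(ensemble.state[k].copy())

    return TrajectoryRecord(
        times=times, ids=ensemble.ids.copy(),
        lon=np.array(snaps_lon), lat=np.array(snaps_lat),
        depth=np.array(snaps_z), status=np.array(snaps_status),
        state={k: np.array(v) for k, v in snaps_state.items()},
        events=events,
        meta={"direction": cfg.direction, "dt": cfg.dt, "scheme": cfg.scheme,
              "seed": cfg.seed, "n_steps": n_steps})


# ---------------------------------------------------------------------------
# Habitat connectivity (T[j,i] = N[j,i] / R[i])
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """Transport-probability estimate between habitats.

    T.loc[j, i] is the survival-weighted probability that a propagule
    released in source i settles in sink j; N holds the raw weighted
    tallies and R the release counts.  T_per_area is T divided by the sink
    area in km^2 (settlement probability density), reported alongside the
    raw matrix because habitats may differ in size.
    """

    T: pd.DataFrame
    N: pd.DataFrame
    R: pd.Series
    T_per_area: pd.DataFrame
    accounting: pd.DataFrame

    def to_csv(self, path_T, path_companion=None):
        self.T.to_csv(path_T)
        if path_companion:
            comp = self.N.copy()
            comp.loc["R"] = self.R
            comp.to_csv(path_companion)


def release_in_habitat(habitat: Habitat, count: int, physics, depth=0.0,
                       vertical="fixed", seed=0,
                       max_attempts=1000) -> Ensemble:
    """Uniform wet release inside a habitat polygon (rejection sampling)."""
    minx, miny, maxx, maxy = habitat.geometry.bounds
    rng = np.random.default_rng(seed)
    lon = np.empty(count)
    lat = np.empty(count)
    z = np.empty(count)
    pending = np.arange(count)
    for attempt in range(max_attempts):
        if not pending.size:
            break
        m = pending.size
        clon = rng.uniform(minx, maxx, m)
        clat = rng.uniform(miny, maxy, m)
        if vertical == "uniform":
            wd = np.asarray(physics.wdepth(clon, clat), float)
            cz = rng.uniform(0.0, np.maximum(wd, 0.0), m)
        else:
            cz = np.full(m, depth)
        ok = habitat.contains(clon, clat) \
            & np.asarray(physics.is_wet(clon, clat, cz), bool)
        take = pending[ok]
        lon[take], lat[take], z[take] = clon[ok], clat[ok], cz[ok]
        pending = pending[~ok]
    else:
        raise RuntimeError(
            f"habitat {habitat.id!r}: no wet in-polygon position found after "
            f"{max_attempts} attempts")
    return Ensemble(lon, lat, z)


def compute_connectivity(habitats: HabitatSet, physics, biology,
                         cfg: StepConfig, start: datetime, n_steps: int,
                         releases_per_source: int | dict = 100,
                         release_depth: float = 0.0,
                         release_vertical: str = "fixed",
                         release_positions: dict | None = None) -> ConnectivityMatrix:
    """Estimate the habitat connectivity matrix from a Lagrangian run.

    Propagules are released uniformly over each source habitat (or at the
    explicit per-habitat (lon, lat, depth) arrays in `release_positions`),
    propagated with the given physics/biology, and settle at their *first*
    entry into a sink polygon while settlement-eligible (no re-suspension);
    the sink's suitability is applied as a seeded Bernoulli thinning of
    that first entry.  Each settlement adds the propagule's survival weight
    to N[sink, source]; T = N / R.
    """
    sources = habitats.sources
    sinks = habitats.sinks
    if not sources or not sinks:
        raise ValueError("need at least one source and one sink habitat")

    # release, tagged by origin
    parts = []
    R = {}
    for si, hab in enumerate(sources):
        if release_positions is not None and hab.id in release_positions:
            plon, plat, pz = (np.asarray(a, float)
                              for a in release_positions[hab.id])
            ens = Ensemble(plon, plat, pz)
            n = len(ens)
        else:
            n = (releases_per_source if isinstance(releases_per_source, int)
                 else releases_per_source[hab.id])
            if n <= 0:
                raise ValueError(
                    f"release count for habitat {hab.id!r} must be > 0")
            ens = release_in_habitat(hab, n, physics, depth=release_depth,
                                     vertical=release_vertical,
                                     seed=cfg.seed + 101 + si)
        R[hab.id] = n
        ens.origin[:] = si
        parts.append(ens)
    lon = np.concatenate([e.lon for e in parts])
    lat = np.concatenate([e.lat for e in parts])
    z = np.concatenate([e.depth for e in parts])
    ensemble = Ensemble(lon, lat, z)
    ensemble.origin = np.concatenate([e.origin for e in parts])
    n_total = len(ensemble)
    rng_settle = np.random.default_rng(cfg.seed + 577)

    direction = (Direction.FORWARD if cfg.direction == "forward"
                 else Direction.BACKWARD)
    clock = SimClock(start, direction)
    _check_coverage(physics, start,
                    clock.advanced(cfg.sign * cfg.dt * n_steps).time)
    ensemble.state = biology.init_state(n_total,
                                        np.random.default_rng(cfg.seed + 1))

    N = np.zeros((len(sinks), len(sources)))
    attempted = np.zeros((n_total, len(sinks)), bool)
    events: dict = {}

    def _settlement_sweep():
        live = ensemble.status == Mobility.FREE
        if not live.any():
            return
        eligible = np.asarray(biology.settle_eligible(
            {k: v for k, v in ensemble.state.items()} if ensemble.state else None))
        cand = live & np.broadcast_to(eligible, live.shape)
        if not cand.any():
            return
        idx = np.flatnonzero(cand)
        for j, sink in enumerate(sinks):
            if not idx.size:
                break
            inside = sink.contains(ensemble.lon[idx], ensemble.lat[idx])
            first = inside & ~attempted[idx, j]
            hit = idx[first]
            if not hit.size:
                continue
            attempted[hit, j] = True
            if sink.suitability >= 1.0:
                ok = np.ones(hit.size, bool)
            else:
                ok = rng_settle.random(hit.size) < sink.suitability
            settled = hit[ok]
            if settled.size:
                ensemble.status[settled] = Mobility.SETTLED
                ensemble.settle_habitat[settled] = j
                if "survival_weight" in ensemble.state:
                    w = ensemble.state["survival_weight"][settled]
                else:
                    w = np.ones(settled.size)
                np.add.at(N[j], ensemble.origin[settled], w)
                if "age" in ensemble.state:
                    ensemble.settle_age[settled] = \
                        ensemble.state["age"][settled]
                idx = idx[~np.isin(idx, settled)]

    _settlement_sweep()  # particles may start eligible inside a sink
    for _ in range(n_steps):
        physics.update(clock.time)
        clock = step_ensemble(ensemble, physics, biology, cfg, clock,
                              events=events)
        _settlement_sweep()

    src_ids = [h.id for h in sources]
    sink_ids = [h.id for h in sinks]
    R_ser = pd.Series([R[i] for i in src_ids], index=src_ids, name="R")
    N_df = pd.DataFrame(N, index=sink_ids, columns=src_ids)
    T_df = N_df / R_ser
    areas = pd.Series([h.area_km2 for h in sinks], index=sink_ids)
    acc = pd.DataFrame({
        "released": [R[i] for i in src_ids],
        "settled": [int(np.count_nonzero(
            (ensemble.status == Mobility.SETTLED)
            & (ensemble.origin == si))) for si in range(len(sources))],
        "active": [int(np.count_nonzero(
            ensemble.active_mask & (ensemble.origin == si)))
            for si in range(len(sources))],
        "deactivated_other": [int(np.count_nonzero(
            (~ensemble.active_mask) & (ensemble.status != Mobility.SETTLED)
            & (ensemble.origin == si))) for si in range(len(sources))],
    }, index=src_ids)
    return ConnectivityMatrix(T=T_df, N=N_df, R=R_ser,
                              T_per_area=T_df.div(areas, axis=0),
                              accounting=acc)


# ---------------------------------------------------------------------------
# Region / period averaging
# ---------------------------------------------------------------------------

def extract_average(physics, regions, times, fields,
                    depth_range=(0.0, 0.0), n_lon: int = 10, n_lat: int = 10,
                    n_depth: int = 5) -> pd.DataFrame:
    """Mean/min/max of provider fields over regions and a time window.

    `regions` is a list of Habitat (polygon) or (id, lon_min, lon_max,
    lat_min, lat_max) tuples; samples lie on a regular lon x lat x depth
    lattice restricted to the region and to wet points; dry samples are
    excluded and counted.  Regions with zero wet samples yield a flagged
    (NaN) row rather than an error.
    """
    rows = []
    z0, z1 = depth_range
    zs = np.linspace(z0, z1, n_depth) if n_depth > 1 else np.array([z0])
    for region in regions:
        if isinstance(region, Habitat):
            rid = region.id
            minx, miny, maxx, maxy = region.geometry.bounds
            inside = region.contains
        else:
            rid, minx, maxx, miny, maxy = region
            inside = None
        lons = np.linspace(minx, maxx, n_lon)
        lats = np.linspace(miny, maxy, n_lat)
        LO, LA, Z = np.meshgrid(lons, lats, zs, indexing="ij")
        lo, la, zz = LO.ravel(), LA.ravel(), Z.ravel()
        if inside is not None:
            keep = inside(lo, la)
            lo, la, zz = lo[keep], la[keep], zz[keep]
        wet = np.asarray(physics.is_wet(lo, la, zz), bool)
        n_dry = int(np.count_nonzero(~wet))
        lo, la, zz = lo[wet], la[wet], zz[wet]
        for name in fields:
            vals = []
            for t in times:
                physics.update(t)
                if lo.size:
                    vals.append(np.asarray(
                        physics.scalar(name, lo, la, zz), float))
            if vals:
                allv = np.concatenate(vals)
                rows.append(dict(region=rid, field=name,
                                 mean=float(allv.mean()),
                                 min=float(allv.min()),
                                 max=float(allv.max()),
                                 count=int(allv.size), n_dry=n_dry,
                                 flagged=False))
            else:
                rows.append(dict(region=rid, field=name, mean=np.nan,
                                 min=np.nan, max=np.nan, count=0,
                                 n_dry=n_dry, flagged=True))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Eulerian advection-diffusion-reaction solver
# ---------------------------------------------------------------------------

@dataclass
class ReactionOperator:
    """Local reaction term G(C): zero, logistic, or logistic with grazing.

    logistic: G = r C (1 - C / Ccap) with r in 1/day.
    logistic_with_grazing adds -g C inside the grazing mask (g in 1/day),
    the simplest closure for localized predation pressure on a growing
    prey field.
    """

    name: str = "zero"
    r: float = 0.0
    Ccap: float = 1.0
    grazing: float = 0.0
    grazing_mask: Optional[np.ndarray] = None

    def __call__(self, C: np.ndarray, t: float = 0.0) -> np.ndarray:
        if self.name == "zero":
            return np.zeros_like(C)
        r_s = self.r / 86400.0
        G = r_s * C * (1.0 - C / self.Ccap)
        if self.name == "logistic":
            return G
        if self.name == "logistic_with_grazing":
            g_s = self.grazing / 86400.0
            mask = (np.ones_like(C) if self.grazing_mask is None
                    else self.grazing_mask)
            return G - g_s * C * mask
        raise ValueError(f"unknown reaction {self.name!r}")


@dataclass
class EulerianField:
    """A scalar concentration on a closed uniform box grid.

    C has 1-3 axes; `spacing` gives the (uniform) cell size per axis in
    metres; `velocity` holds a cell-centred component per axis (m/s) and
    `K` a diffusivity per axis (m^2/s, scalar broadcasts).  Boundaries are
    closed (zero total flux).
    """

    C: np.ndarray
    spacing: tuple
    velocity: tuple = ()
    K: float | tuple = 0.0
    reaction: ReactionOperator = dc_field(default_factory=ReactionOperator)
    time: float = 0.0
    #: optional staggered velocity: component a given on the interior faces
    #: normal to axis a (shape = C.shape with axis a one smaller).  A
    #: discretely divergence-free face field (e.g. from a streamfunction)
    #: preserves constants exactly; cell-centred `velocity` is averaged to
    #: faces otherwise.
    face_velocity: tuple = ()
    #: boundary condition: None = closed (zero total flux through every
    #: boundary face); or a dict {axis: (low_value, high_value)} imposing a
    #: Dirichlet concentration on boundary faces where the flow enters
    #: (advective inflow; outflow stays upwind, diffusive boundary flux
    #: stays zero).  Entries may be None to keep a face closed.
    inflow: dict | None = None

    def __post_init__(self):
        self.C = np.asarray(self.C, float)
        nd = self.C.ndim
        if len(self.spacing) != nd:
            raise ValueError("spacing must give one cell size per axis")
        if not self.velocity:
            self.velocity = tuple(np.zeros_like(self.C) for _ in range(nd))
        self.velocity = tuple(np.broadcast_to(np.asarray(v, float),
                                              self.C.shape).copy()
                              for v in self.velocity)
        if self.face_velocity:
            for a, fv in enumerate(self.face_velocity):
                want = list(self.C.shape)
                want[a] -= 1
                if list(np.shape(fv)) != want:
                    raise ValueError(
                        f"face_velocity[{a}] must have shape {tuple(want)}")
            self.face_velocity = tuple(np.asarray(fv, float)
                                       for fv in self.face_velocity)
        if np.isscalar(self.K):
            self.K = tuple(float(self.K) for _ in range(nd))

    def _face_u(self, axis):
        if self.face_velocity:
            return self.face_velocity[axis]
        u = self.velocity[axis]
        sl_lo = [slice(None)] * self.C.ndim
        sl_hi = list(sl_lo)
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        return 0.5 * (u[tuple(sl_lo)] + u[tuple(sl_hi)])

    @property
    def mass(self) -> float:
        return float(self.C.sum() * np.prod(self.spacing))


def _axis_flux(C, u_face, K, dx, axis):
    """Face fluxes along one axis: upwind advective + centred diffusive."""
    sl = [slice(None)] * C.ndim
    sl_lo = list(sl); sl_lo[axis] = slice(None, -1)
    sl_hi = list(sl); sl_hi[axis] = slice(1, None)
    C_lo = C[tuple(sl_lo)]
    C_hi = C[tuple(sl_hi)]
    adv = np.where(u_face >= 0.0, u_face * C_lo, u_face * C_hi)
    dif = -K * (C_hi - C_lo) / dx
    return adv + dif  # flux through interior faces, positive along +axis


def eulerian_step(field: EulerianField, dt: float) -> EulerianField:
    """One explicit step: conservative transport then local reaction.

    Raises on CFL violation — per axis max|u| dt / dx <= 1 and
    2 K dt / dx^2 <= 0.5 — naming the admissible dt.  The reaction term is
    integrated with Heun's explicit trapezoidal rule, keeping the whole
    update explicit and local.
    """
    C = field.C
    nd = C.ndim
    for a in range(nd):
        dx = field.spacing[a]
        fu = field._face_u(a)
        umax = float(np.abs(fu).max()) if fu.size else 0.0
        lim_a = dx / umax if umax > 0 else np.inf
        lim_d = 0.25 * dx * dx / field.K[a] if field.K[a] > 0 else np.inf
        admissible = min(lim_a, lim_d)
        if dt > admissible:
            raise ValueError(
                f"CFL violation on axis {a}: dt={dt} s exceeds admissible "
                f"{admissible:.6g} s")
    dC = np.zeros_like(C)
    for a in range(nd):
        dx = field.spacing[a]
        F = _axis_flux(C, field._face_u(a), field.K[a], dx, a)
        sl = [slice(None)] * nd
        sl_int_lo = list(sl); sl_int_lo[a] = slice(None, -1)
        sl_int_hi = list(sl); sl_int_hi[a] = slice(1, None)
        # divergence of face fluxes; boundary faces carry zero flux unless
        # an inflow condition is set for this axis
        dC[tuple(sl_int_lo)] -= F * dt / dx
        dC[tuple(sl_int_hi)] += F * dt / dx
        if field.inflow and a in field.inflow and field.inflow[a] is not None:
            lo_val, hi_val = field.inflow[a]
            first = list(sl); first[a] = 0
            last = list(sl); last[a] = -1
            u_lo = field.velocity[a][tuple(first)]
            u_hi = field.velocity[a][tuple(last)]
            if lo_val is not None:
                F_lo = np.where(u_lo >= 0.0, u_lo * lo_val,
                                u_lo * C[tuple(first)])
                dC[tuple(first)] += F_lo * dt / dx
            if hi_val is not None:
                F_hi = np.where(u_hi >= 0.0, u_hi * C[tuple(last)],
                                u_hi * hi_val)
                dC[tuple(last)] -= F_hi * dt / dx
    C_new = C + dC
    # reaction (Heun)
    k1 = field.reaction(C_new, field.time)
    k2 = field.reaction(C_new + k1 * dt, field.time + dt)
    field.C = C_new + 0.5 * dt * (k1 + k2)
    field.time += dt
    return field


def run_eulerian(field: EulerianField, dt: float, n_steps: int,
                 snapshot_every: int = 0,
                 refresh_velocity: Optional[Callable] = None,
                 refresh_every: int = 0):
    """Iterate :func:`eulerian_step`; return (field, snapshots, time_average).

    `refresh_velocity(field, step)` may replace field.velocity from a
    physics provider every `refresh_every` steps (e.g. at forcing-frame
    boundaries).  The time average is accumulated with running sums.
    """
    snapshots = []
    avg = np.zeros_like(field.C)
    for step in range(n_steps):
        if refresh_velocity is not None and refresh_every \
                and step % refresh_every == 0:
            refresh_velocity(field, step)
        eulerian_step(field, dt)
        avg += field.C
        if snapshot_every and (step + 1) % snapshot_every == 0:
            snapshots.append((field.time, field.C.copy()))
    avg /= max(n_steps, 1)
    return field, snapshots, avg
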