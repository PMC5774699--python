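"""Particle propagation: advection + active motion + turbulent random walk.

Each step applies, per particle, the stochastic increment

    dx = (u + w) dt + grad(K) dt + rho * sqrt(2 K(x + grad(K) dt / 2) dt)

per axis (x, y in local metric metres, z in metres): the deterministic part
is integrated with Euler, RK2 (midpoint) or RK4; the random-walk part uses
Euler-Maruyama with the diffusivity-gradient correction — the drift term
``grad(K) dt`` plus midpoint evaluation of K — which keeps passive tracers
well mixed under spatially varying K.  Deterministic and stochastic
displacements are both evaluated from the start-of-step position, summed,
and boundaries are enforced once on the combined candidate.

Backward time reverses the currents and the biology's active velocity and
state increment, but the random walk keeps positive diffusivity (running
diffusion backwards is ill-posed; turbulence still spreads a backtracked
ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Ensemble, Mobility, BoundaryPolicy
from .geometry import M_PER_DEG_LAT, m_per_deg_lon

_SQRT3 = np.sqrt(3.0)


@dataclass
class StepConfig:
    """Time-stepping configuration.

    dt is in seconds (> 0 even for backward runs — direction carries the
    sign); `deviate_kind` selects the unit-variance random deviate: standard
    normal or uniform on [-sqrt(3), sqrt(3)].  Identical config + seed gives
    bit-identical trajectories.
    """

    dt: float = 300.0
    scheme: str = "rk2"
    direction: str = "forward"
    seed: int = 0
    deviate_kind: str = "normal"
    #: diagnostic switch: False drops the grad(K) drift and midpoint-K
    #: evaluation, reproducing the naive random walk that aggregates
    #: particles at diffusivity minima (for well-mixed-condition checks)
    gradient_correction: bool = True
    rng: np.random.Generator = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.scheme not in ("euler", "rk2", "rk4"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.deviate_kind not in ("normal", "uniform"):
            raise ValueError(f"unknown deviate kind {self.deviate_kind!r}")
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "forward" else -1.0


def _deviates(cfg: StepConfig, n: int) -> np.ndarray:
    """(n, 3) unit-variance deviates, one per axis per particle."""
    if cfg.deviate_kind == "normal":
        return cfg.rng.standard_normal((n, 3))
    return cfg.rng.uniform(-_SQRT3, _SQRT3, (n, 3))


def deterministic_velocity(lon, lat, z, physics, biology, cfg: StepConfig,
                           state=None, env=None):
    """(vlon_east, vnorth, vdown) in m/s: currents + active motion.

    Forward: u + w.  Backward: -u + the biology's reversed active velocity
    (default -w), implementing adjoint backtracking by reversal of (u, G).
    """
    u, v, w = physics.currents(lon, lat, z)
    if biology is not None:
        wu, wv, ww = biology.active_velocity(state, lon, lat, z, env, cfg.dt)
        if cfg.direction == "backward":
            wu, wv, ww = biology.reversed_active_velocity(wu, wv, ww)
    else:
        wu = wv = ww = 0.0
    s = cfg.sign
    return s * u + wu, s * v + wv, s * w + ww


def _rates(lon, lat, z, physics, biology, cfg, state, env):
    """Angular/vertical rates (dlon/dt deg/s, dlat/dt deg/s, dz/dt m/s)."""
    ve, vn, vd = deterministic_velocity(lon, lat, z, physics, biology, cfg,
                                        state, env)
    return ve / m_per_deg_lon(lat), vn / M_PER_DEG_LAT, vd


def integrate_step(lon, lat, z, physics, biology, cfg: StepConfig,
                   state=None, env=None, events=None):
    """Deterministic displacement (dlon deg, dlat deg, dz m) for one step.

    RK substep positions that leave the wet domain trigger a per-particle
    fallback to the Euler rate for this step (counted in
    ``events['rk_fallback']``).
    """
    dt = cfg.dt
    k1 = _rates(lon, lat, z, physics, biology, cfg, state, env)
    if cfg.scheme == "euler":
        return k1[0] * dt, k1[1] * dt, k1[2] * dt

    def _wet(lo, la, zz):
        return np.asarray(physics.is_wet(
            lo, la, np.clip(zz, 0.0, None)), bool)

    if cfg.scheme == "rk2":
        lon_m = lon + k1[0] * dt / 2
        lat_m = lat + k1[1] * dt / 2
        z_m = z + k1[2] * dt / 2
        ok = _wet(lon_m, lat_m, z_m)
        k2 = _rates(np.where(ok, lon_m, lon), np.where(ok, lat_m, lat),
                    np.where(ok, z_m, z), physics, biology, cfg, state, env)
        dlon = np.where(ok, k2[0], k1[0]) * dt
        dlat = np.where(ok, k2[1], k1[1]) * dt
        dz = np.where(ok, k2[2], k1[2]) * dt
        if events is not None:
            events["rk_fallback"] += int(np.count_nonzero(~ok))
        return dlon, dlat, dz

    # rk4
    ok_all = np.ones(np.broadcast(np.asarray(lon), np.asarray(lat)).shape, bool)

    def _eval(lo, la, zz):
        nonlocal ok_all
        ok = _wet(lo, la, zz)
        ok_all &= ok
        return _rates(np.where(ok, lo, lon), np.where(ok, la, lat),
                      np.where(ok, zz, z), physics, biology, cfg, state, env)

    k2 = _eval(lon + k1[0] * dt / 2, lat + k1[1] * dt / 2, z + k1[2] * dt / 2)
    k3 = _eval(lon + k2[0] * dt / 2, lat + k2[1] * dt / 2, z + k2[2] * dt / 2)
    k4 = _eval(lon + k3[0] * dt, lat + k3[1] * dt, z + k3[2] * dt)
    if events is not None:
        events["rk_fallback"] += int(np.count_nonzero(~ok_all))
    out = []
    for a in range(3):
        rk4 = (k1[a] + 2 * k2[a] + 2 * k3[a] + k4[a]) / 6.0
        out.append(np.where(ok_all, rk4, k1[a]) * dt)
    return tuple(out)


def random_walk_increment(lon, lat, z, physics, cfg: StepConfig,
                          deviates=None):
    """Turbulent displacement (dx_m, dy_m, dz_m) with the gradient correction.

    Per axis a:  da = (dK/da) dt + rho sqrt(2 K(a + (dK/da) dt / 2) dt),
    with K evaluated at the half-gradient-offset point and rho a fresh
    unit-variance deviate per axis per particle.  Applied identically in
    forward and backward runs (diffusion is never reversed).
    """
    dt = cfg.dt
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    z = np.asarray(z, float)
    n = lon.size
    if deviates is None:
        deviates = _deviates(cfg, n)
    if cfg.gradient_correction:
        gx, gy, gz = physics.turbulence_gradient(lon, lat, z)
    else:
        gx = gy = gz = np.zeros(lon.shape)
    mplon = m_per_deg_lon(lat)
    # midpoint-K evaluation, offset applied per axis independently
    kh_x, _ = physics.turbulence(lon + 0.5 * gx * dt / mplon, lat, z)
    kh_y, _ = physics.turbulence(lon, lat + 0.5 * gy * dt / M_PER_DEG_LAT, z)
    _, kv_z = physics.turbulence(lon, lat, z + 0.5 * gz * dt)
    for k in (kh_x, kh_y, kv_z):
        if np.any(np.asarray(k) < 0):
            raise ValueError("provider returned negative diffusivity")
    dx = gx * dt + deviates[..., 0] * np.sqrt(2.0 * kh_x * dt)
    dy = gy * dt + deviates[..., 1] * np.sqrt(2.0 * kh_y * dt)
    dz = gz * dt + deviates[..., 2] * np.sqrt(2.0 * kv_z * dt)
    return dx, dy, dz


def _fold(v, lo, hi):
    """Reflect values into [lo, hi] (closed form of repeated mirroring)."""
    v = np.asarray(v, float)
    lo = np.asarray(lo, float)
    span = np.maximum(np.asarray(hi, float) - lo, 1e-300)
    f = np.mod(v - lo, 2.0 * span)
    return lo + span - np.abs(f - span)


def enforce_boundaries(old_lon, old_lat, old_z, lon, lat, z, physics,
                       policy: BoundaryPolicy, events=None,
                       max_reflections: int = 5):
    """Resolve a candidate position against coast, surface, bottom and domain.

    Returns (lon, lat, z, deactivate_mask, freeze_mask).  Horizontal
    violations are handled first (specular coast/domain reflection, or
    absorb/sticky per policy), then the vertical coordinate is mirrored into
    [0, wdepth] at the final horizontal position.  A particle whose coast
    reflection does not resolve within `max_reflections` mirrors has its
    sub-step cancelled (stays at the old position).
    """
    lon = np.array(lon, float, copy=True)
    lat = np.array(lat, float, copy=True)
    z = np.array(z, float, copy=True)
    n = lon.size
    deact = np.zeros(n, bool)
    freeze = np.zeros(n, bool)
    ev = events if events is not None else {}
    ev.setdefault("coast_reflection", 0)
    ev.setdefault("vertical_reflection", 0)
    ev.setdefault("cancelled_substep", 0)
    ev.setdefault("left_domain", 0)

    lo, hi, la, lb = physics.bounds
    dry = ~(np.asarray(physics.horizontal_range_check(lon, lat), bool)
            & ~np.asarray(physics.is_land(lon, lat), bool))
    if dry.any():
        if policy.horizontal == "absorb":
            deact |= dry
            ev["left_domain"] += int(np.count_nonzero(dry))
            lon[dry] = old_lon[dry]
            lat[dry] = old_lat[dry]
            z[dry] = old_z[dry]
        elif policy.horizontal == "sticky":
            freeze |= dry
            lon[dry] = old_lon[dry]
            lat[dry] = old_lat[dry]
            z[dry] = old_z[dry]
        elif physics.coast is None:
            lon[dry] = _fold(lon[dry], lo, hi)
            lat[dry] = _fold(lat[dry], la, lb)
            ev["coast_reflection"] += int(np.count_nonzero(dry))
        else:
            coast = physics.coast
            for i in np.flatnonzero(dry):
                olon, olat = old_lon[i], old_lat[i]
                clon, clat = lon[i], lat[i]
                resolved = False
                for _ in range(max_reflections):
                    res = coast.first_crossing(olon, olat, clon, clat)
                    if not res.crossed:
                        # candidate may still be dry through numeric grazing
                        if not bool(coast.is_land(clon, clat)):
                            resolved = True
                        break
                    ev["coast_reflection"] += 1
                    nlon, nlat = res.reflected
                    if nlon == olon and nlat == olat and (clon, clat) != (nlon, nlat):
                        break  # corner tie -> cancel
                    clon, clat = nlon, nlat
                    if not bool(coast.is_land(clon, clat)):
                        resolved = True
                        break
                if resolved:
                    lon[i], lat[i] = clon, clat
                else:
                    ev["cancelled_substep"] += 1
                    lon[i], lat[i] = olon, olat
                    z[i] = old_z[i]

    # vertical: mirror into [0, wdepth] at the (resolved) horizontal position
    wd = np.asarray(physics.wdepth(lon, lat), float)
    bad = (z < 0.0) | (z > wd)
    if bad.any():
        if policy.vertical == "absorb":
            deact |= bad
            ev["left_domain"] += int(np.count_nonzero(bad))
        elif policy.vertical == "sticky":
            freeze |= bad
            z = np.clip(z, 0.0, wd)
        else:
            ev["vertical_reflection"] += int(np.count_nonzero(bad))
            # mirror at surface and bottom; closed form handles repeats
            wdb = wd[bad]
            z[bad] = _fold(z[bad], 0.0, np.maximum(wdb, 1e-12))
    z = np.clip(z, 0.0, wd)
    return lon, lat, z, deact, freeze


def step_ensemble(ensemble: Ensemble, physics, biology, cfg: StepConfig,
                  clock=None, events=None):
    """Advance every moving particle by one step of cfg.dt (in place).

    Sequence per step: deterministic displacement (chosen scheme) and
    random-walk displacement are both computed from the start-of-step
    position, summed into one candidate, boundaries enforced once; then the
    biology state is updated (ds = G dt, reversed in backward runs) and any
    die / settle signals are applied.  Returns the advanced clock (or None).
    """
    ev = events if events is not None else {}
    ev.setdefault("rk_fallback", 0)
    moving = ensemble.moving_mask
    idx = np.flatnonzero(moving)
    if idx.size:
        lon = ensemble.lon[idx]
        lat = ensemble.lat[idx]
        z = ensemble.depth[idx]
        state = {k: v[idx] for k, v in ensemble.state.items()} or None
        env = None
        if biology is not None:
            from .biology import sample_environment
            t = clock.time if clock is not None else None
            env = sample_environment(physics, biology, lon, lat, z, t)
        dlon, dlat, dz = integrate_step(lon, lat, z, physics, biology, cfg,
                                        state, env, events=ev)
        dx_m, dy_m, dz_m = random_walk_increment(lon, lat, z, physics, cfg)
        cand_lon = lon + dlon + dx_m / m_per_deg_lon(lat)
        cand_lat = lat + dlat + dy_m / M_PER_DEG_LAT
        cand_z = z + dz + dz_m
        flon, flat, fz, deact, freeze = enforce_boundaries(
            lon, lat, z, cand_lon, cand_lat, cand_z, physics,
            ensemble.boundary_policy, events=ev)
        ensemble.lon[idx] = flon
        ensemble.lat[idx] = flat
        ensemble.depth[idx] = fz
        if deact.any():
            ensemble.status[idx[deact]] = Mobility.LEFT_DOMAIN
        if freeze.any():
            ensemble.status[idx[freeze]] = Mobility.FROZEN

        if biology is not None and state is not None:
            still = ~deact
            sub = idx[still]
            sub_state = {k: v[still] for k, v in state.items()}
            from .biology import sample_environment
            t2 = clock.time if clock is not None else None
            env2 = sample_environment(physics, biology, ensemble.lon[sub],
                                      ensemble.lat[sub], ensemble.depth[sub], t2)
            signals = biology.update_state(sub_state, env2, cfg.dt,
                                           cfg.direction)
            for k, v in sub_state.items():
                ensemble.state[k][sub] = v
            if signals is not None:
                die = signals.get("die")
                if die is not None and np.any(die):
                    ensemble.status[sub[die]] = Mobility.DEAD
    if clock is not None:
        return clock.advanced(cfg.sign * cfg.dt)
    return None
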