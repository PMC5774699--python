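"""Biology models: internal particle state and active motion.

A biology model supplies the three services the propagation loop consumes:

* ``init_state``      — allocate the per-particle state arrays (ds/dt = G);
* ``active_velocity`` — the swimming/buoyancy velocity w added to currents;
* ``update_state``    — integrate the state one step (reversed sign in
  backward runs, so a forward-then-backward pass restores the state).

Reference models:

``PassiveParticle``
    The null model: no state, zero active velocity.  A run with this model
    is bit-identical to a run with no biology attached.
``DVMLarva``
    Diel vertical migration: swims vertically toward a shallow target
    (10 m) when the sun is below the configured elevation threshold (night
    and dusk) and a deep target (40 m) in daylight.
``StagedLarva``
    Egg -> yolk-sac larva -> feeding larva -> competent, for a cod-like
    early life history: a non-feeding, passively dispersing egg stage of
    about two weeks; hatching at 3 mm; linear growth with age thereafter;
    DVM switched on two weeks after hatching; a settlement-competency
    window opening at a configured age; optional constant mortality
    decaying a survival weight used by the connectivity tally.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np

DAY_S = 86400.0

EGG, YOLK_LARVA, FEEDING_LARVA, COMPETENT = 0, 1, 2, 3
STAGE_NAMES = {EGG: "egg", YOLK_LARVA: "yolk_larva",
               FEEDING_LARVA: "feeding_larva", COMPETENT: "competent"}


def solar_elevation_deg(time: datetime, lon, lat):
    """Apparent solar elevation (degrees) from a low-precision ephemeris.

    Declination from the day-of-year cosine approximation; hour angle from
    UTC time plus longitude.  Accurate to ~1 degree, ample for a day/night
    flag.
    """
    doy = time.timetuple().tm_yday
    hour = time.hour + time.minute / 60.0 + time.second / 3600.0
    decl = -23.44 * np.cos(2.0 * np.pi * (doy + 10) / 365.0)
    hour_angle = np.deg2rad(15.0 * (hour + np.asarray(lon, float) / 15.0 - 12.0))
    phi = np.deg2rad(np.asarray(lat, float))
    d = np.deg2rad(decl)
    sin_e = np.sin(phi) * np.sin(d) + np.cos(phi) * np.cos(d) * np.cos(hour_angle)
    return np.rad2deg(np.arcsin(np.clip(sin_e, -1.0, 1.0)))


def is_daylight(time: datetime, lon, lat, threshold_deg: float = 0.0):
    """True where the sun is above `threshold_deg` elevation.

    The default threshold 0 (geometric horizon) groups dusk with night, so
    a migrating larva holds its shallow night-time depth through dusk; set
    -6 for a civil-twilight convention instead.
    """
    return solar_elevation_deg(time, lon, lat) > threshold_deg


def sample_environment(provider, biology, lon, lat, z, time=None) -> dict:
    """Assemble the per-particle environment dict a biology model reads.

    Pulls every field the model declares in ``required_fields`` through the
    physics scalar registry and adds the day/night flag (None when the run
    has no clock).
    """
    env = {"time": time}
    for name in getattr(biology, "required_fields", ()):
        env[name] = np.asarray(provider.scalar(name, lon, lat, z), float)
    if time is not None:
        env["daylight"] = is_daylight(
            time, lon, lat, getattr(biology, "twilight_deg", 0.0))
    else:
        env["daylight"] = None
    return env


class BiologyModel:
    """Contract: state definition, active velocity w, state increment G."""

    required_fields: tuple = ()
    twilight_deg: float = 0.0

    def init_state(self, n: int, rng=None, release_info=None) -> dict:
        return {}

    def active_velocity(self, state, lon, lat, z, env, dt):
        shp = np.shape(np.asarray(lon))
        return np.zeros(shp), np.zeros(shp), np.zeros(shp)

    def reversed_active_velocity(self, wu, wv, ww):
        """Behavior reversal used in backtracking; default is -w."""
        return -np.asarray(wu), -np.asarray(wv), -np.asarray(ww)

    def update_state(self, state, env, dt, direction) -> dict | None:
        return None

    def settle_eligible(self, state):
        raise NotImplementedError


class PassiveParticle(BiologyModel):
    """Null model: a passive point particle floating with the water.

    Carries no state; its settle-eligibility is unconditional, so a
    connectivity run with passive propagules scores any sink entry.
    """

    def settle_eligible(self, state):
        return True


def _target_seek_w(z, target, speed, dt):
    """Vertical velocity (positive down) toward `target`, clamped to reach
    it within one step at most."""
    return np.clip((np.asarray(target) - np.asarray(z, float)) / dt,
                   -speed, speed)


class DVMLarva(BiologyModel):
    """Diel vertical migrator: shallow at night and dusk, deep by day.

    Parameters
    ----------
    swim_speed : vertical swim speed, m/s (default 5 mm/s).
    night_depth, day_depth : target depths in metres (10 / 40).
    twilight_deg : solar elevation separating day from night-and-dusk.
    """

    def __init__(self, swim_speed=0.005, night_depth=10.0, day_depth=40.0,
                 twilight_deg=0.0):
        if swim_speed < 0:
            raise ValueError("swim_speed must be >= 0")
        self.swim_speed = float(swim_speed)
        self.night_depth = float(night_depth)
        self.day_depth = float(day_depth)
        self.twilight_deg = float(twilight_deg)

    def target_depth(self, daylight):
        if daylight is None:
            return np.float64(self.day_depth)
        return np.where(np.asarray(daylight), self.day_depth, self.night_depth)

    def active_velocity(self, state, lon, lat, z, env, dt):
        shp = np.shape(np.asarray(lon))
        target = self.target_depth(None if env is None else env.get("daylight"))
        ww = _target_seek_w(z, target, self.swim_speed, dt)
        return np.zeros(shp), np.zeros(shp), np.broadcast_to(ww, shp).copy()

    def settle_eligible(self, state):
        return True


class StagedLarva(BiologyModel):
    """Egg / yolk-sac / feeding / competent larva with linear growth.

    Stages are a pure function of developmental age, so the stage sequence
    is monotone forward and reverses exactly at the same thresholds when
    integrated backward.  Durations are in days:

    * ``egg_duration``: non-feeding, passively dispersing egg phase
      (default 14 d ~ two weeks); hatching sets length to ``hatch_length``
      (3 mm).
    * ``yolk_duration``: yolk-sac phase after hatch (default 5 d).
    * DVM starts ``dvm_onset`` days after hatch (default 14 d).
    * Competency to settle opens at total age ``competency_age`` (days).
    * Length grows linearly: hatch_length + growth * (age - egg_duration).
    * Optional constant mortality ``mortality`` (1/d) decays the survival
      weight as exp(-m t); the weight multiplies the connectivity tally.
    * Optional Q10 temperature scaling of development rate (needs a
      ``temperature`` field from the physics provider).
    """

    def __init__(self, egg_duration=14.0, hatch_length=3.0, growth=0.2,
                 yolk_duration=5.0, dvm_onset=14.0, competency_age=40.0,
                 mortality=0.0, initial_survival=1.0, swim_speed=0.005,
                 night_depth=10.0, day_depth=40.0, twilight_deg=0.0,
                 q10=None, q10_t_ref=10.0):
        for name, v in [("egg_duration", egg_duration),
                        ("yolk_duration", yolk_duration),
                        ("dvm_onset", dvm_onset),
                        ("competency_age", competency_age),
                        ("mortality", mortality), ("swim_speed", swim_speed),
                        ("growth", growth)]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        self.egg_duration = float(egg_duration)
        self.hatch_length = float(hatch_length)
        self.growth = float(growth)
        self.yolk_duration = float(yolk_duration)
        self.dvm_onset = float(dvm_onset)
        self.competency_age = float(competency_age)
        self.mortality = float(mortality)
        if not 0.0 < initial_survival <= 1.0:
            raise ValueError("initial_survival must be in (0, 1]")
        self.initial_survival = float(initial_survival)
        self.q10 = q10
        self.q10_t_ref = float(q10_t_ref)
        self._dvm = DVMLarva(swim_speed, night_depth, day_depth, twilight_deg)
        self.twilight_deg = float(twilight_deg)
        if q10 is not None:
            self.required_fields = ("temperature",)

    # -- state -------------------------------------------------------------
    def init_state(self, n: int, rng=None, release_info=None) -> dict:
        return {
            "age": np.zeros(n),                      # days since release
            "dev_age": np.zeros(n),                  # development-scaled age
            "length": np.full(n, np.nan),            # mm, undefined pre-hatch
            "stage": np.zeros(n, dtype=np.int8),
            "survival_weight": np.full(n, self.initial_survival),
        }

    def stage_of(self, dev_age):
        """Stage from developmental age (pure, hence exactly reversible)."""
        dev_age = np.asarray(dev_age, float)
        stage = np.zeros(dev_age.shape, dtype=np.int8)
        stage[dev_age >= self.egg_duration] = YOLK_LARVA
        stage[dev_age >= self.egg_duration + self.yolk_duration] = FEEDING_LARVA
        stage[dev_age >= self.competency_age] = COMPETENT
        return stage

    def length_of(self, age):
        age = np.asarray(age, float)
        post = age - self.egg_duration
        return np.where(post >= 0.0, self.hatch_length + self.growth * post,
                        np.nan)

    def dvm_active(self, age):
        return np.asarray(age, float) >= self.egg_duration + self.dvm_onset

    # -- contract ----------------------------------------------------------
    def active_velocity(self, state, lon, lat, z, env, dt):
        shp = np.shape(np.asarray(lon))
        if state is None:
            return np.zeros(shp), np.zeros(shp), np.zeros(shp)
        _, _, ww = self._dvm.active_velocity(state, lon, lat, z, env, dt)
        ww = np.where(self.dvm_active(state["age"]), ww, 0.0)
        return np.zeros(shp), np.zeros(shp), ww

    def update_state(self, state, env, dt, direction) -> dict | None:
        sgn = 1.0 if direction == "forward" else -1.0
        dt_d = sgn * dt / DAY_S
        rate = 1.0
        if self.q10 is not None:
            temp = env.get("temperature")
            if temp is None:
                raise ValueError("Q10 scaling requires a 'temperature' field")
            rate = self.q10 ** ((np.asarray(temp, float) - self.q10_t_ref) / 10.0)
        state["age"] = state["age"] + dt_d
        state["dev_age"] = state["dev_age"] + rate * dt_d
        state["stage"] = self.stage_of(state["dev_age"])
        state["length"] = self.length_of(state["age"])
        if self.mortality > 0.0:
            state["survival_weight"] = (state["survival_weight"]
                                        * np.exp(-self.mortality * dt_d))
        return None

    def settle_eligible(self, state):
        return np.asarray(state["stage"]) == COMPETENT


_MODELS = {
    "passive": PassiveParticle,
    "dvm_larva": DVMLarva,
    "staged_larva": StagedLarva,
}


def make_biology(name: str, **params) -> BiologyModel:
    """Build a biology model by registry name (config-file entry point)."""
    try:
        cls = _MODELS[name]
    except KeyError:
        raise ValueError(f"unknown biology model {name!r}; "
                         f"available: {sorted(_MODELS)}")
    return cls(**params)
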