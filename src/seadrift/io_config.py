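"""Run configuration, trajectory output, and synthetic hydrography files.

A run is fully determined by one TOML configuration file plus the seed it
contains: the file names the task, the physics provider, the biology model,
the stepping parameters and the release(s).  Every primary output echoes
the configuration and the package version string, so results can be
reproduced from the output alone.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field as dc_field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .biology import make_biology
from .core import ReleaseSpec
from .kinematics import StepConfig
from .physics import make_provider

_TASKS = ("simulate", "backtrack", "connectivity", "extract", "eulerian")
_TOP_KEYS = {"task", "physics", "biology", "step", "release", "habitats",
             "output", "run", "eulerian", "extract"}
_STEP_KEYS = {"dt", "scheme", "seed", "direction", "deviate_kind"}


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Validated run configuration with documented defaults filled in."""

    task: str
    physics: dict
    step: dict
    biology: dict | None = None
    release: dict | None = None
    habitats: dict | None = None
    output: dict = dc_field(default_factory=dict)
    run: dict = dc_field(default_factory=dict)
    eulerian: dict = dc_field(default_factory=dict)
    extract: dict = dc_field(default_factory=dict)

    def echo(self) -> str:
        """Compact JSON echo of the configuration (for output provenance)."""
        def _clean(v):
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, datetime):
                return v.isoformat()
            return v
        return json.dumps({k: _clean(getattr(self, k)) for k in
                           ("task", "physics", "biology", "step", "release",
                            "habitats", "output", "run", "eulerian",
                            "extract")},
                          separators=(",", ":"), sort_keys=True)

    # -- object builders ---------------------------------------------------
    def build_physics(self):
        params = dict(self.physics)
        name = params.pop("provider")
        return make_provider(name, **params)

    def build_biology(self):
        if not self.biology:
            return None
        params = dict(self.biology)
        name = params.pop("model")
        return make_biology(name, **params)

    def build_step(self) -> StepConfig:
        step = dict(self.step)
        if self.task == "backtrack":
            step.setdefault("direction", "backward")
        return StepConfig(**step)

    def build_release(self) -> ReleaseSpec:
        if not self.release:
            raise ConfigError("missing mandatory section [release]")
        return ReleaseSpec(**self.release)


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"missing mandatory key {key!r} in {where}")
    return mapping[key]


def parse_config(path, overrides: dict | None = None,
                 validate: bool = True) -> RunConfig:
    """Parse and validate a TOML run-configuration file.

    Rejects unknown sections/keys, fills documented defaults, and checks
    physics/biology compatibility (a biology model that needs a scalar
    field the provider does not register fails here, before any stepping).
    `overrides` maps dotted keys ('step.dt') to replacement values.
    """
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    for key, value in (overrides or {}).items():
        parts = key.split(".")
        node = raw
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    task = _require(raw, "task", "top level")
    if task not in _TASKS:
        raise ConfigError(f"unknown task {task!r}; choose from {_TASKS}")
    physics = dict(_require(raw, "physics", "top level"))
    _require(physics, "provider", "[physics]")
    step = dict(_require(raw, "step", "top level"))
    bad = set(step) - _STEP_KEYS
    if bad:
        raise ConfigError(f"unknown [step] keys: {sorted(bad)}")
    step.setdefault("dt", 300.0)
    step.setdefault("scheme", "rk2")
    step.setdefault("seed", 0)

    cfg = RunConfig(task=task, physics=physics, step=step,
                    biology=raw.get("biology"), release=raw.get("release"),
                    habitats=raw.get("habitats"),
                    output=raw.get("output", {}), run=raw.get("run", {}),
                    eulerian=raw.get("eulerian", {}),
                    extract=raw.get("extract", {}))

    if not validate:
        # fixture-generation configs carry grid parameters the providers
        # themselves do not take; skip the construction check
        return cfg
    # impossible physics x biology combinations fail at parse time
    try:
        provider = cfg.build_physics()
        biology = cfg.build_biology()
        cfg.build_step()
    except TypeError as exc:
        raise ConfigError(f"bad provider/model parameters: {exc}") from exc
    if biology is not None:
        missing = [f for f in biology.required_fields
                   if f not in provider.fields]
        if missing:
            raise ConfigError(
                f"biology model {cfg.biology.get('model')!r} requires "
                f"field(s) {missing} not provided by physics "
                f"{cfg.physics.get('provider')!r} "
                f"(available: {sorted(provider.fields)})")
    return cfg


# ---------------------------------------------------------------------------
# Trajectory output
# ---------------------------------------------------------------------------

def _version_string() -> str:
    from . import __version__
    return f"seadrift {__version__}"


def write_trajectories(record, path, format: str = "csv",
                       config_echo: str = "") -> Path:
    """Write a TrajectoryRecord to CSV or NetCDF.

    CSV: one row per (particle, snapshot), columns id, time, lon, lat,
    depth, status plus any recorded state variables; provenance (version
    string and config echo) in leading ``#`` comment lines.  NetCDF:
    particle x time arrays with NaN fill after a particle's deactivation,
    provenance in global attributes.
    """
    path = Path(path)
    if len(record.times) == 0 or record.ids.size == 0:
        raise ValueError("empty trajectory record")
    nsnap, n = record.lon.shape
    if format == "csv":
        frames = []
        for k, t in enumerate(record.times):
            df = pd.DataFrame({
                "id": record.ids,
                "time": t.isoformat(),
                "lon": record.lon[k], "lat": record.lat[k],
                "depth": record.depth[k], "status": record.status[k]})
            for name, arr in record.state.items():
                df[name] = arr[k]
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        with open(path, "w") as fh:
            fh.write(f"# {_version_string()}\n")
            if config_echo:
                fh.write(f"# config {config_echo}\n")
            out.to_csv(fh, index=False, float_format="%.17g",
                       lineterminator="\n")
    elif format == "netcdf":
        import xarray as xr
        inactive = record.status >= 2  # deactivated statuses
        def _masked(a):
            return np.where(inactive, np.nan, a)
        ds = xr.Dataset(
            {"lon": (("time", "particle"), _masked(record.lon)),
             "lat": (("time", "particle"), _masked(record.lat)),
             "depth": (("time", "particle"), _masked(record.depth)),
             "status": (("time", "particle"), record.status)},
            coords={"time": [np.datetime64(t) for t in record.times],
                    "particle": record.ids},
            attrs={"source": _version_string(), "config": config_echo})
        for name, arr in record.state.items():
            ds[name] = (("time", "particle"), arr)
        ds.to_netcdf(path, engine="scipy")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return path


def read_trajectories(path) -> pd.DataFrame:
    """Read a CSV trajectory file back into a tidy DataFrame."""
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Synthetic hydrography fixtures
# ---------------------------------------------------------------------------

def generate_synthetic_hydrography(kind: str, path, nlon=10, nlat=10, nz=5,
                                   bounds=(-1.0, 1.0, -1.0, 1.0),
                                   water_depth=100.0, times=None,
                                   land_mask=None, **params) -> Path:
    """Write a NetCDF hydrography file sampling an analytic field at nodes.

    `kind` names one of the analytic providers (uniform_flow, linear_shear,
    solid_body_rotation, parabolic_kv) or ``toy_coast``; grid node values
    equal the analytic field exactly, so a gridded provider reading the
    file reproduces the generating field at nodes to round-off.  Any
    parameter given as a list with one entry per frame varies across
    frames (e.g. ``u=[0.0, 1.0]``).
    """
    import xarray as xr
    if nlon < 1 or nlat < 1 or nz < 1:
        raise ValueError(f"invalid grid shape ({nlon}, {nlat}, {nz})")
    if times is None:
        times = [datetime(2004, 1, 1)]
    lon_e = np.linspace(bounds[0], bounds[1], nlon + 1)
    lat_e = np.linspace(bounds[2], bounds[3], nlat + 1)
    lon_c = 0.5 * (lon_e[:-1] + lon_e[1:])
    lat_c = 0.5 * (lat_e[:-1] + lat_e[1:])
    z_e = np.linspace(0.0, water_depth, nz + 1)
    z_c = 0.5 * (z_e[:-1] + z_e[1:])
    LO, LA = np.meshgrid(lon_c, lat_c, indexing="xy")

    nT = len(times)
    per_frame = {k: v for k, v in params.items()
                 if isinstance(v, (list, tuple)) and len(v) == nT
                 and not k.endswith("_edges")}
    static = {k: v for k, v in params.items() if k not in per_frame}

    def _provider(k):
        p = dict(static)
        p.update({name: vals[k] for name, vals in per_frame.items()})
        if kind == "toy_coast":
            p.setdefault("lon_edges", lon_e)
            p.setdefault("lat_edges", lat_e)
            p.setdefault("land_mask",
                         np.zeros((nlat, nlon), bool) if land_mask is None
                         else land_mask)
            return make_provider("toy_coast", water_depth=water_depth, **p)
        return make_provider(kind, bounds=bounds, water_depth=water_depth, **p)

    shape = (nT, nz, nlat, nlon)
    U = np.zeros(shape); V = np.zeros(shape); W = np.zeros(shape)
    KH = np.zeros(shape); KV = np.zeros(shape)
    scalars = {}
    prov0 = _provider(0)
    for name in prov0.fields:
        scalars[name] = np.zeros(shape)
    for k in range(nT):
        prov = _provider(k)
        for iz, zz in enumerate(z_c):
            u, v, w = prov.currents(LO, LA, zz)
            U[k, iz], V[k, iz], W[k, iz] = u, v, w
            kh, kv = prov.turbulence(LO, LA, zz)
            KH[k, iz], KV[k, iz] = kh, kv
            for name in scalars:
                scalars[name][k, iz] = prov.scalar(name, LO, LA, zz)
    mask2d = np.asarray(prov0.is_land(LO, LA), bool)

    data = {"u": (("time", "z", "lat", "lon"), U),
            "v": (("time", "z", "lat", "lon"), V),
            "w": (("time", "z", "lat", "lon"), W),
            "landmask": (("lat", "lon"), mask2d.astype(np.int32)),
            "wdepth": (("lat", "lon"),
                       np.asarray(prov0.wdepth(LO, LA), float))}
    if KH.any():
        data["Kh"] = (("time", "z", "lat", "lon"), KH)
    if KV.any() or kind == "parabolic_kv":
        data["Kv"] = (("time", "z", "lat", "lon"), KV)
    for name, arr in scalars.items():
        data[name] = (("time", "z", "lat", "lon"), arr)
    ds = xr.Dataset(
        data,
        coords={"time": [np.datetime64(t) for t in times],
                "z": ("z", z_c, {"units": "m", "positive": "down"}),
                "lat": ("lat", lat_c, {"units": "degrees_north"}),
                "lon": ("lon", lon_c, {"units": "degrees_east"})},
        attrs={"source": _version_string(), "kind": kind})
    ds.to_netcdf(path, engine="scipy")
    return Path(path)
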