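"""Physics providers: hydrographic fields behind one opaque query interface.

A provider answers, at the frozen lookup time set by :func:`update_physical_fields`:

* local currents (u east, v north, w vertical — positive *down*, matching
  the depth axis),
* eddy diffusivity (Kh horizontal, Kv vertical) and its spatial gradient,
* named scalar fields (temperature, salinity, ...) through a registry,
* topography: water depth, land mask, domain range, 3-D wet test,
* coastline crossings of a straight particle displacement.

Concrete providers are either closed-form analytic fields (used for
validation against exact trajectories) or a gridded NetCDF reader with
linear time blending and trilinear space interpolation.  Callers never see
grid indices, layout or frame times.

Array-first convention: the low-level methods (``currents``, ``turbulence``,
``scalar`` ...) accept numpy arrays and do not validate wetness — that is
the propagation loop's job, which queries from known-wet start positions.
The module-level ``interpolate_*`` wrappers take a single
:class:`~seadrift.core.GeoPosition` and enforce the full contract
(dry / out-of-range positions raise, distinguishing the two).
"""

from __future__ import annotations

import abc
from dataclasses import dataclass
from datetime import datetime
from typing import Callable, Optional

import numpy as np

from .core import GeoPosition, SimClock
from .geometry import M_PER_DEG_LAT, m_per_deg_lon, normalize_lon


@dataclass(frozen=True)
class FlowSample:
    """Local current vector in m/s (w positive downward)."""
    u: float
    v: float
    w: float = 0.0


@dataclass(frozen=True)
class DiffusivitySample:
    """Horizontal and vertical eddy diffusivity in m^2/s (both >= 0)."""
    Kh: float
    Kv: float


@dataclass(frozen=True)
class DiffusivityGradient:
    """Diffusivity gradient in metric metres: (dKh/dx, dKh/dy, dKv/dz), m/s."""
    dKh_dx: float
    dKh_dy: float
    dKv_dz: float


@dataclass(frozen=True)
class CrossingResult:
    """Outcome of testing a straight displacement against the coast."""
    crossed: bool
    intersection: Optional[GeoPosition] = None
    reflected: Optional[GeoPosition] = None


class OutsideCoverage(ValueError):
    """Requested time is outside the provider's temporal coverage."""


class DryPositionError(ValueError):
    """Query at a position that is on land or below the seabed."""


class OutOfRangeError(ValueError):
    """Query outside the provider's horizontal domain."""


class UnknownFieldError(KeyError):
    """Scalar field not present in the provider's registry."""


# ---------------------------------------------------------------------------
# Rasterized coastline
# ---------------------------------------------------------------------------

class RasterCoast:
    """Stair-step coastline on a regular lon/lat cell grid.

    The coast is the set of faces between wet and land cells of the mask
    (cells outside the grid count as land, closing the basin).  Crossing
    detection walks the segment cell by cell (a 2-D DDA traversal) and
    reports the first wet->land face; the reflected endpoint is the specular
    mirror of the candidate across that face.  A corner hit reflects across
    the face with the larger penetration depth; an exact tie cancels the
    sub-step (reflected endpoint = start).
    """

    def __init__(self, lon_edges, lat_edges, land_mask):
        self.lon_edges = np.asarray(lon_edges, float)
        self.lat_edges = np.asarray(lat_edges, float)
        mask = np.asarray(land_mask, bool)
        if mask.shape != (self.lat_edges.size - 1, self.lon_edges.size - 1):
            raise ValueError("land mask shape must be (nlat_cells, nlon_cells)")
        self.land = mask

    def cell_index(self, lon, lat):
        i = np.searchsorted(self.lon_edges, lon, side="right") - 1
        j = np.searchsorted(self.lat_edges, lat, side="right") - 1
        return i, j

    def is_land(self, lon, lat):
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        i, j = self.cell_index(lon, lat)
        out = ((i < 0) | (i >= self.land.shape[1]) |
               (j < 0) | (j >= self.land.shape[0]))
        i = np.clip(i, 0, self.land.shape[1] - 1)
        j = np.clip(j, 0, self.land.shape[0] - 1)
        return np.where(out, True, self.land[j, i])

    def _cell_is_land(self, i, j):
        if i < 0 or i >= self.land.shape[1] or j < 0 or j >= self.land.shape[0]:
            return True
        return bool(self.land[j, i])

    def first_crossing(self, lon0, lat0, lon1, lat1) -> CrossingResult:
        """First wet->land face crossed by the segment, with specular mirror."""
        dlon = lon1 - lon0
        dlat = lat1 - lat0
        if dlon == 0.0 and dlat == 0.0:
            return CrossingResult(False)
        i, j = self.cell_index(np.float64(lon0), np.float64(lat0))
        i, j = int(i), int(j)
        step_i = 1 if dlon > 0 else -1
        step_j = 1 if dlat > 0 else -1
        INF = np.inf
        # parametric t of the next lon / lat edge crossing
        if dlon != 0.0:
            nxt = i + 1 if dlon > 0 else i
            t_x = (self.lon_edges[nxt] - lon0) / dlon if 0 <= nxt < self.lon_edges.size else INF
        else:
            t_x = INF
        if dlat != 0.0:
            nxt = j + 1 if dlat > 0 else j
            t_y = (self.lat_edges[nxt] - lat0) / dlat if 0 <= nxt < self.lat_edges.size else INF
        else:
            t_y = INF
        dt_x = abs((self.lon_edges[1] - self.lon_edges[0]) / dlon) if dlon != 0.0 else INF
        dt_y = abs((self.lat_edges[1] - self.lat_edges[0]) / dlat) if dlat != 0.0 else INF

        while True:
            t = min(t_x, t_y)
            if t > 1.0:
                return CrossingResult(False)
            corner = (t_x == t_y)
            if corner:
                # candidate enters the diagonal cell; compare penetrations
                face_lon = self.lon_edges[i + (1 if step_i > 0 else 0)]
                face_lat = self.lat_edges[j + (1 if step_j > 0 else 0)]
                ni, nj = i + step_i, j + step_j
                if self._cell_is_land(ni, nj) or self._cell_is_land(ni, j) \
                        or self._cell_is_land(i, nj):
                    pen_x = abs(lon1 - face_lon) * np.cos(np.deg2rad(lat0))
                    pen_y = abs(lat1 - face_lat)
                    inter = (lon0 + t * dlon, lat0 + t * dlat)
                    if pen_x > pen_y:
                        return CrossingResult(True, inter,
                                              (2.0 * face_lon - lon1, lat1))
                    if pen_y > pen_x:
                        return CrossingResult(True, inter,
                                              (lon1, 2.0 * face_lat - lat1))
                    return CrossingResult(True, inter, (lon0, lat0))  # cancel
                i, j = ni, nj
                t_x += dt_x
                t_y += dt_y
                continue
            if t_x < t_y:
                face_lon = self.lon_edges[i + (1 if step_i > 0 else 0)]
                ni = i + step_i
                if self._cell_is_land(ni, j):
                    inter = (face_lon, lat0 + t * dlat)
                    return CrossingResult(True, inter,
                                          (2.0 * face_lon - lon1, lat1))
                i = ni
                t_x += dt_x
            else:
                face_lat = self.lat_edges[j + (1 if step_j > 0 else 0)]
                nj = j + step_j
                if self._cell_is_land(i, nj):
                    inter = (lon0 + t * dlon, face_lat)
                    return CrossingResult(True, inter,
                                          (lon1, 2.0 * face_lat - lat1))
                j = nj
                t_y += dt_y


# ---------------------------------------------------------------------------
# Provider contract
# ---------------------------------------------------------------------------

class PhysicsProvider(abc.ABC):
    """Contract served to kinematics, biology and the task drivers.

    Attributes
    ----------
    bounds : (lon_min, lon_max, lat_min, lat_max)
        Horizontal domain limits.
    fields : frozenset of str
        Names of scalar fields answerable by :meth:`scalar`.
    coast : RasterCoast or None
        Rasterized coastline, if the domain has land.
    """

    bounds: tuple
    fields: frozenset = frozenset()
    coast: Optional[RasterCoast] = None

    @abc.abstractmethod
    def update(self, time) -> None:
        """Freeze the lookup time; raise OutsideCoverage when unsupported."""

    @abc.abstractmethod
    def currents(self, lon, lat, z):
        """(u, v, w) in m/s at the frozen time, elementwise over arrays."""

    def turbulence(self, lon, lat, z):
        """(Kh, Kv) in m^2/s; zero when the provider carries no turbulence."""
        shp = np.broadcast(np.asarray(lon), np.asarray(lat), np.asarray(z)).shape
        return np.zeros(shp), np.zeros(shp)

    def turbulence_gradient(self, lon, lat, z):
        """(dKh/dx, dKh/dy, dKv/dz) in m/s, metric metres."""
        shp = np.broadcast(np.asarray(lon), np.asarray(lat), np.asarray(z)).shape
        return np.zeros(shp), np.zeros(shp), np.zeros(shp)

    def scalar(self, name, lon, lat, z):
        raise UnknownFieldError(
            f"field {name!r} not provided; available: {sorted(self.fields)}")

    @abc.abstractmethod
    def wdepth(self, lon, lat):
        """Water depth in metres (bathymetry), elementwise."""

    def horizontal_range_check(self, lon, lat):
        lon = normalize_lon(lon)
        lat = np.asarray(lat, float)
        lo, hi, la, lb = self.bounds
        return (lon >= lo) & (lon <= hi) & (lat >= la) & (lat <= lb)

    def is_land(self, lon, lat):
        if self.coast is None:
            return np.zeros(np.broadcast(np.asarray(lon), np.asarray(lat)).shape,
                            bool)
        return self.coast.is_land(lon, lat)

    def is_wet(self, lon, lat, z):
        """range-check AND not-land AND 0 <= z <= wdepth."""
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        z = np.asarray(z, float)
        ok = self.horizontal_range_check(lon, lat)
        ok = ok & ~self.is_land(lon, lat)
        wd = np.where(ok, self.wdepth(np.where(ok, lon, self.bounds[0]),
                                      np.where(ok, lat, self.bounds[2])), 0.0)
        return ok & (z >= 0.0) & (z <= wd)

    def coast_line_intersection(self, start: GeoPosition,
                                end: GeoPosition) -> CrossingResult:
        """Test the straight segment start->end against the coastline."""
        if not bool(self.is_wet(start.lon, start.lat, min(start.depth,
                                float(self.wdepth(start.lon, start.lat))))):
            raise DryPositionError("coast_line_intersection: start is not wet")
        if self.coast is None:
            return CrossingResult(False)
        res = self.coast.first_crossing(start.lon, start.lat, end.lon, end.lat)
        if not res.crossed:
            return CrossingResult(False)
        inter = GeoPosition(res.intersection[0], res.intersection[1], start.depth)
        refl = GeoPosition(res.reflected[0], res.reflected[1], end.depth)
        return CrossingResult(True, inter, refl)


# ---------------------------------------------------------------------------
# Analytic providers
# ---------------------------------------------------------------------------

def _as_field(value):
    """Lift a constant into a (lon, lat, z) -> value callable."""
    if callable(value):
        return value
    return lambda lon, lat, z: np.broadcast_to(
        np.float64(value), np.broadcast(np.asarray(lon), np.asarray(lat),
                                        np.asarray(z)).shape).copy()


class AnalyticProvider(PhysicsProvider):
    """Closed-form flow field over a flat-bottom box; infinite time coverage.

    Subclasses override :meth:`currents` (and the turbulence methods where
    relevant).  Scalar fields are supplied as constants or callables of
    (lon, lat, z) in the ``scalars`` mapping.
    """

    def __init__(self, bounds=(-1.0, 1.0, -1.0, 1.0), water_depth=100.0,
                 scalars=None, coast: Optional[RasterCoast] = None):
        self.bounds = tuple(float(b) for b in bounds)
        self._wdepth = float(water_depth)
        self._scalars = {k: _as_field(v) for k, v in (scalars or {}).items()}
        self.fields = frozenset(self._scalars)
        self.coast = coast
        self.clock: Optional[SimClock] = None
        self.time: Optional[datetime] = None

    def update(self, time) -> None:
        self.time = time.time if isinstance(time, SimClock) else time

    def wdepth(self, lon, lat):
        shp = np.broadcast(np.asarray(lon), np.asarray(lat)).shape
        return np.broadcast_to(self._wdepth, shp).copy()

    def scalar(self, name, lon, lat, z):
        try:
            f = self._scalars[name]
        except KeyError:
            raise UnknownFieldError(
                f"field {name!r} not provided; available: {sorted(self.fields)}")
        return np.asarray(f(np.asarray(lon, float), np.asarray(lat, float),
                            np.asarray(z, float)), float)


class UniformFlow(AnalyticProvider):
    """Spatially uniform currents with optional constant diffusivity."""

    def __init__(self, u=0.0, v=0.0, w=0.0, Kh=0.0, Kv=0.0, **kw):
        super().__init__(**kw)
        self.u, self.v, self.w = float(u), float(v), float(w)
        if Kh < 0 or Kv < 0:
            raise ValueError("diffusivities must be >= 0")
        self.Kh, self.Kv = float(Kh), float(Kv)

    def currents(self, lon, lat, z):
        shp = np.broadcast(np.asarray(lon), np.asarray(lat), np.asarray(z)).shape
        return (np.full(shp, self.u), np.full(shp, self.v), np.full(shp, self.w))

    def turbulence(self, lon, lat, z):
        shp = np.broadcast(np.asarray(lon), np.asarray(lat), np.asarray(z)).shape
        return np.full(shp, self.Kh), np.full(shp, self.Kv)


class LinearShearFlow(AnalyticProvider):
    """Eastward current increasing linearly with depth: u(z) = u0 + g z."""

    def __init__(self, u0=0.1, shear=0.01, **kw):
        super().__init__(**kw)
        self.u0, self.shear = float(u0), float(shear)

    def currents(self, lon, lat, z):
        z = np.asarray(z, float)
        shp = np.broadcast(np.asarray(lon), np.asarray(lat), z).shape
        u = np.broadcast_to(self.u0 + self.shear * z, shp).copy()
        return u, np.zeros(shp), np.zeros(shp)


class SolidBodyRotation(AnalyticProvider):
    """Horizontal solid-body rotation about a centre: u = -omega y, v = omega x.

    (x, y) are local-metric offsets from the centre; the exact trajectories
    are closed orbits with period 2 pi / omega, the classic oracle for
    trajectory-integration order checks.
    """

    def __init__(self, lon0=0.0, lat0=0.0, omega=2.0 * np.pi / 86400.0, **kw):
        super().__init__(**kw)
        self.lon0, self.lat0, self.omega = float(lon0), float(lat0), float(omega)

    def currents(self, lon, lat, z):
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        x = normalize_lon(lon - self.lon0) * m_per_deg_lon(lat)
        y = (lat - self.lat0) * M_PER_DEG_LAT
        shp = np.broadcast(lon, lat, np.asarray(z)).shape
        return (-self.omega * np.broadcast_to(y, shp).copy(),
                self.omega * np.broadcast_to(x, shp).copy(),
                np.zeros(shp))


class ParabolicKvBasin(AnalyticProvider):
    """Quiescent basin with a parabolic vertical-diffusivity profile.

    Kv(z) = K0 + K1 z (H - z) on 0 <= z <= H: minimal (K0) at surface and
    bottom, maximal at mid-depth.  The analytic gradient dKv/dz = K1 (H - 2z)
    feeds the random-walk correction term; this is the standard well-mixed
    test bed.
    """

    def __init__(self, K0=1e-4, K1=4e-6, Kh=0.0, water_depth=50.0, **kw):
        super().__init__(water_depth=water_depth, **kw)
        if K0 < 0 or Kh < 0:
            raise ValueError("diffusivities must be >= 0")
        self.K0, self.K1, self.Kh = float(K0), float(K1), float(Kh)

    def currents(self, lon, lat, z):
        shp = np.broadcast(np.asarray(lon), np.asarray(lat), np.asarray(z)).shape
        return np.zeros(shp), np.zeros(shp), np.zeros(shp)

    def turbulence(self, lon, lat, z):
        z = np.clip(np.asarray(z, float), 0.0, self._wdepth)
        kv = self.K0 + self.K1 * z * (self._wdepth - z)
        shp = np.broadcast(np.asarray(lon), np.asarray(lat), z).shape
        return np.full(shp, self.Kh), np.broadcast_to(kv, shp).copy()

    def turbulence_gradient(self, lon, lat, z):
        z = np.clip(np.asarray(z, float), 0.0, self._wdepth)
        g = self.K1 * (self._wdepth - 2.0 * z)
        shp = np.broadcast(np.asarray(lon), np.asarray(lat), z).shape
        return (np.zeros(shp), np.zeros(shp), np.broadcast_to(g, shp).copy())


class ToyCoastBasin(UniformFlow):
    """Uniform-flow basin with a stair-step land mask for boundary tests."""

    def __init__(self, lon_edges, lat_edges, land_mask, **kw):
        coast = RasterCoast(lon_edges, lat_edges, land_mask)
        bounds = (float(coast.lon_edges[0]), float(coast.lon_edges[-1]),
                  float(coast.lat_edges[0]), float(coast.lat_edges[-1]))
        kw.setdefault("bounds", bounds)
        super().__init__(coast=coast, **kw)


# ---------------------------------------------------------------------------
# Gridded NetCDF provider
# ---------------------------------------------------------------------------

def _axis_interp_weights(centres, x):
    """Indices (i, i+1) and fraction for linear interpolation on cell centres.

    Queries beyond the outermost centres clamp to the end value (fraction 0
    against a duplicated node), implementing the documented extrapolation
    rule.
    """
    x = np.asarray(x, float)
    i = np.searchsorted(centres, x) - 1
    i = np.clip(i, 0, centres.size - 2)
    denom = centres[i + 1] - centres[i]
    frac = np.clip((x - centres[i]) / denom, 0.0, 1.0)
    return i, frac


class GriddedProvider(PhysicsProvider):
    """Regular lon-lat-depth hydrography from a NetCDF file.

    Expects coordinates ``lon`` (degrees east), ``lat`` (degrees north),
    ``z`` (layer-centre depth, metres positive down) and ``time``; data
    variables ``u``, ``v`` and optionally ``w``, ``Kh``, ``Kv`` plus any
    named scalars (all dims time x z x lat x lon); a 2-D integer/boolean
    ``landmask`` and bathymetry ``wdepth``.  Cells are centred on the
    coordinate values with uniform spacing.

    On :meth:`update` the two frames bracketing the requested time are
    blended linearly and held; all spatial queries then interpolate
    trilinearly on the blended arrays, so values at grid nodes reproduce
    file values exactly.  Diffusivity gradients are central finite
    differences of the interpolant with a half-cell stencil.
    """

    _BASIC = ("u", "v", "w", "Kh", "Kv")

    def __init__(self, path_or_dataset):
        import xarray as xr
        if isinstance(path_or_dataset, (str,)) or hasattr(path_or_dataset, "__fspath__"):
            ds = xr.open_dataset(path_or_dataset, engine="scipy")
        else:
            ds = path_or_dataset
        self._ds = ds
        self.lon_c = np.asarray(ds["lon"].values, float)
        self.lat_c = np.asarray(ds["lat"].values, float)
        self.z_c = np.asarray(ds["z"].values, float)
        self.times = np.asarray(ds["time"].values)
        dlon = np.diff(self.lon_c).mean() if self.lon_c.size > 1 else 1.0
        dlat = np.diff(self.lat_c).mean() if self.lat_c.size > 1 else 1.0
        self.bounds = (float(self.lon_c[0] - dlon / 2), float(self.lon_c[-1] + dlon / 2),
                       float(self.lat_c[0] - dlat / 2), float(self.lat_c[-1] + dlat / 2))
        if "landmask" in ds:
            mask = np.asarray(ds["landmask"].values, bool)
            lon_e = np.concatenate([[self.lon_c[0] - dlon / 2],
                                    self.lon_c + dlon / 2])
            lat_e = np.concatenate([[self.lat_c[0] - dlat / 2],
                                    self.lat_c + dlat / 2])
            self.coast = RasterCoast(lon_e, lat_e, mask) if mask.any() else None
        else:
            self.coast = None
        self._wdepth2d = (np.asarray(ds["wdepth"].values, float)
                         if "wdepth" in ds else None)
        data_vars = [v for v in ds.data_vars
                     if ds[v].dims == ("time", "z", "lat", "lon")]
        self.fields = frozenset(v for v in data_vars if v not in self._BASIC)
        self._vars = {v: np.nan_to_num(np.asarray(ds[v].values, float))
                      for v in data_vars}
        self._frames: dict[str, np.ndarray] = {}
        self._frame_time = None

    # -- time handling ------------------------------------------------------
    def update(self, time) -> None:
        t = time.time if isinstance(time, SimClock) else time
        t64 = np.datetime64(t)
        t0, t1 = self.times[0], self.times[-1]
        if t64 < t0 or t64 > t1:
            raise OutsideCoverage(
                f"time {t} outside coverage [{t0}, {t1}]")
        k = int(np.searchsorted(self.times, t64, side="right") - 1)
        k = min(k, self.times.size - 2) if self.times.size > 1 else 0
        if self.times.size == 1:
            wgt = 0.0
        else:
            span = (self.times[k + 1] - self.times[k]) / np.timedelta64(1, "s")
            wgt = float((t64 - self.times[k]) / np.timedelta64(1, "s")) / float(span)
        for name, arr in self._vars.items():
            if self.times.size == 1:
                self._frames[name] = arr[0]
            else:
                self._frames[name] = (1.0 - wgt) * arr[k] + wgt * arr[k + 1]
        self._frame_time = t

    def _require_frames(self):
        if not self._frames:
            raise RuntimeError("provider not updated; call update_physical_fields first")

    # -- interpolation ------------------------------------------------------
    def _interp3(self, name, lon, lat, z):
        self._require_frames()
        arr = self._frames[name]  # (z, lat, lon)
        iz, fz = _axis_interp_weights(self.z_c, z) if self.z_c.size > 1 else (
            np.zeros(np.shape(z), int), np.zeros(np.shape(z)))
        iy, fy = _axis_interp_weights(self.lat_c, lat) if self.lat_c.size > 1 else (
            np.zeros(np.shape(lat), int), np.zeros(np.shape(lat)))
        ix, fx = _axis_interp_weights(self.lon_c, lon) if self.lon_c.size > 1 else (
            np.zeros(np.shape(lon), int), np.zeros(np.shape(lon)))
        iz1 = np.minimum(iz + 1, arr.shape[0] - 1)
        iy1 = np.minimum(iy + 1, arr.shape[1] - 1)
        ix1 = np.minimum(ix + 1, arr.shape[2] - 1)
        c000 = arr[iz, iy, ix]; c001 = arr[iz, iy, ix1]
        c010 = arr[iz, iy1, ix]; c011 = arr[iz, iy1, ix1]
        c100 = arr[iz1, iy, ix]; c101 = arr[iz1, iy, ix1]
        c110 = arr[iz1, iy1, ix]; c111 = arr[iz1, iy1, ix1]
        c00 = c000 * (1 - fx) + c001 * fx
        c01 = c010 * (1 - fx) + c011 * fx
        c10 = c100 * (1 - fx) + c101 * fx
        c11 = c110 * (1 - fx) + c111 * fx
        c0 = c00 * (1 - fy) + c01 * fy
        c1 = c10 * (1 - fy) + c11 * fy
        return c0 * (1 - fz) + c1 * fz

    def currents(self, lon, lat, z):
        lon = np.asarray(lon, float); lat = np.asarray(lat, float)
        z = np.asarray(z, float)
        u = self._interp3("u", lon, lat, z)
        v = self._interp3("v", lon, lat, z)
        w = (self._interp3("w", lon, lat, z) if "w" in self._vars
             else np.zeros(np.broadcast(lon, lat, z).shape))
        return u, v, w

    def turbulence(self, lon, lat, z):
        lon = np.asarray(lon, float); lat = np.asarray(lat, float)
        z = np.asarray(z, float)
        shp = np.broadcast(lon, lat, z).shape
        kh = (self._interp3("Kh", lon, lat, z) if "Kh" in self._vars
              else np.zeros(shp))
        kv = (self._interp3("Kv", lon, lat, z) if "Kv" in self._vars
              else np.zeros(shp))
        return kh, kv

    def turbulence_gradient(self, lon, lat, z):
        lon = np.asarray(lon, float); lat = np.asarray(lat, float)
        z = np.asarray(z, float)
        shp = np.broadcast(lon, lat, z).shape
        out = [np.zeros(shp), np.zeros(shp), np.zeros(shp)]
        if "Kh" in self._vars:
            hx_deg = 0.5 * (self.lon_c[1] - self.lon_c[0]) if self.lon_c.size > 1 else 0.0
            hy_deg = 0.5 * (self.lat_c[1] - self.lat_c[0]) if self.lat_c.size > 1 else 0.0
            if hx_deg:
                hx_m = hx_deg * m_per_deg_lon(lat)
                out[0] = (self._interp3("Kh", lon + hx_deg, lat, z)
                          - self._interp3("Kh", lon - hx_deg, lat, z)) / (2 * hx_m)
            if hy_deg:
                hy_m = hy_deg * M_PER_DEG_LAT
                out[1] = (self._interp3("Kh", lon, lat + hy_deg, z)
                          - self._interp3("Kh", lon, lat - hy_deg, z)) / (2 * hy_m)
        if "Kv" in self._vars and self.z_c.size > 1:
            hz = 0.5 * (self.z_c[1] - self.z_c[0])
            out[2] = (self._interp3("Kv", lon, lat, z + hz)
                      - self._interp3("Kv", lon, lat, z - hz)) / (2 * hz)
        return tuple(out)

    def scalar(self, name, lon, lat, z):
        if name not in self.fields:
            raise UnknownFieldError(
                f"field {name!r} not provided; available: {sorted(self.fields)}")
        return self._interp3(name, np.asarray(lon, float),
                             np.asarray(lat, float), np.asarray(z, float))

    def wdepth(self, lon, lat):
        lon = np.asarray(lon, float); lat = np.asarray(lat, float)
        if self._wdepth2d is None:
            return np.full(np.broadcast(lon, lat).shape,
                           float(self.z_c[-1]) * 2 if self.z_c.size else 0.0)
        iy, fy = _axis_interp_weights(self.lat_c, lat) if self.lat_c.size > 1 else (
            np.zeros(np.shape(lat), int), np.zeros(np.shape(lat)))
        ix, fx = _axis_interp_weights(self.lon_c, lon) if self.lon_c.size > 1 else (
            np.zeros(np.shape(lon), int), np.zeros(np.shape(lon)))
        a = self._wdepth2d
        iy1 = np.minimum(iy + 1, a.shape[0] - 1)
        ix1 = np.minimum(ix + 1, a.shape[1] - 1)
        c0 = a[iy, ix] * (1 - fx) + a[iy, ix1] * fx
        c1 = a[iy1, ix] * (1 - fx) + a[iy1, ix1] * fx
        return c0 * (1 - fy) + c1 * fy


# ---------------------------------------------------------------------------
# Module-level contract wrappers (scalar GeoPosition API)
# ---------------------------------------------------------------------------

def update_physical_fields(provider: PhysicsProvider, time) -> PhysicsProvider:
    provider.update(time)
    return provider


def _check_pos(provider, pos: GeoPosition):
    if not bool(provider.horizontal_range_check(pos.lon, pos.lat)):
        raise OutOfRangeError(f"position {pos} outside domain {provider.bounds}")
    if not bool(provider.is_wet(pos.lon, pos.lat, pos.depth)):
        raise DryPositionError(f"position {pos} is dry (land or below seabed)")


def interpolate_currents(provider, pos: GeoPosition, time=None) -> FlowSample:
    if time is not None:
        provider.update(time)
    _check_pos(provider, pos)
    u, v, w = provider.currents(pos.lon, pos.lat, pos.depth)
    return FlowSample(float(u), float(v), float(w))


def interpolate_turbulence(provider, pos: GeoPosition, time=None) -> DiffusivitySample:
    if time is not None:
        provider.update(time)
    _check_pos(provider, pos)
    kh, kv = provider.turbulence(pos.lon, pos.lat, pos.depth)
    return DiffusivitySample(float(kh), float(kv))


def interpolate_turbulence_deriv(provider, pos: GeoPosition,
                                 time=None) -> DiffusivityGradient:
    if time is not None:
        provider.update(time)
    _check_pos(provider, pos)
    gx, gy, gz = provider.turbulence_gradient(pos.lon, pos.lat, pos.depth)
    return DiffusivityGradient(float(gx), float(gy), float(gz))


def interpolate_scalar(provider, field_name: str, pos: GeoPosition,
                       time=None) -> float:
    if time is not None:
        provider.update(time)
    _check_pos(provider, pos)
    return float(provider.scalar(field_name, pos.lon, pos.lat, pos.depth))


def interpolate_wdepth(provider, lon: float, lat: float) -> float:
    return float(provider.wdepth(lon, lat))


def is_wet(provider, pos: GeoPosition) -> bool:
    return bool(provider.is_wet(pos.lon, pos.lat, pos.depth))


def is_land(provider, lon: float, lat: float) -> bool:
    return bool(provider.is_land(lon, lat))


def horizontal_range_check(provider, lon: float, lat: float) -> bool:
    return bool(provider.horizontal_range_check(lon, lat))


def coast_line_intersection(provider, start: GeoPosition,
                            end: GeoPosition) -> CrossingResult:
    return provider.coast_line_intersection(start, end)


# ---------------------------------------------------------------------------
# Factory (config-file entry point)
# ---------------------------------------------------------------------------

_ANALYTIC = {
    "uniform_flow": UniformFlow,
    "linear_shear": LinearShearFlow,
    "solid_body_rotation": SolidBodyRotation,
    "parabolic_kv": ParabolicKvBasin,
}


def make_provider(name: str, **params) -> PhysicsProvider:
    """Build a provider by name: analytic fields, toy coast, or ``gridded``."""
    if name == "gridded":
        return GriddedProvider(params["path"])
    if name == "toy_coast":
        return ToyCoastBasin(**params)
    try:
        cls = _ANALYTIC[name]
    except KeyError:
        raise ValueError(
            f"unknown physics provider {name!r}; "
            f"available: {sorted(_ANALYTIC) + ['toy_coast', 'gridded']}")
    return cls(**params)
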