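"""Local spherical metric and angular helpers.

All horizontal lengths in the package are measured in a local spherical
metric with Earth radius R = 6 371 000 m:

    metres per degree latitude  = 2 pi R / 360
    metres per degree longitude = (2 pi R / 360) * cos(lat)

Longitudes are normalized to the branch [-180, 180).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0
M_PER_DEG_LAT = 2.0 * np.pi * EARTH_RADIUS_M / 360.0


def normalize_lon(lon):
    """Map longitude(s) to the [-180, 180) branch."""
    return (np.asarray(lon) + 180.0) % 360.0 - 180.0


def m_per_deg_lon(lat):
    """Metres per degree of longitude at latitude `lat` (degrees)."""
    return M_PER_DEG_LAT * np.cos(np.deg2rad(lat))


def meters_to_degrees(dx_m, dy_m, lat):
    """Convert metric displacements (east, north) to (dlon, dlat) at `lat`."""
    return dx_m / m_per_deg_lon(lat), dy_m / M_PER_DEG_LAT


def degrees_to_meters(dlon, dlat, lat):
    """Convert angular displacements to metric (east, north) at `lat`."""
    return dlon * m_per_deg_lon(lat), dlat * M_PER_DEG_LAT


def horizontal_distance_m(lon1, lat1, lon2, lat2):
    """Local-metric distance between two points, evaluated at mid-latitude."""
    latm = 0.5 * (np.asarray(lat1) + np.asarray(lat2))
    dlon = normalize_lon(np.asarray(lon2) - np.asarray(lon1))
    dx = dlon * m_per_deg_lon(latm)
    dy = (np.asarray(lat2) - np.asarray(lat1)) * M_PER_DEG_LAT
    return np.hypot(dx, dy)
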