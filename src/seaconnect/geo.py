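"""Spherical-earth geometry helpers shared by the transport model.

All conversions assume a sphere of radius 6371 km. Longitude spacing shrinks
with cos(latitude); latitude spacing is uniform.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0
#: metres per degree of latitude (and of longitude at the equator)
M_PER_DEG = EARTH_RADIUS_M * np.pi / 180.0


def meters_to_degrees(dx_m, dy_m, lat):
    """Convert eastward/northward displacements in metres to (dlon, dlat) degrees
    at latitude ``lat`` (degrees)."""
    lat = np.asarray(lat, dtype=float)
    coslat = np.cos(np.deg2rad(lat))
    # guard the poles; the study domain never approaches them
    coslat = np.maximum(coslat, 1e-12)
    return np.asarray(dx_m, dtype=float) / (M_PER_DEG * coslat), np.asarray(dy_m, dtype=float) / M_PER_DEG


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees. Broadcasts."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * (EARTH_RADIUS_M / 1000.0) * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def wrap_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0
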