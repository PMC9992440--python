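"""Small geodesy helpers shared by the tracker and statistics modules.

All conversions use a spherical Earth of radius 6371 km and plate-carrée
degree/metre scaling (metres per degree of longitude shrink with cos(lat)).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: metres per degree of latitude on the R = 6371 km sphere
M_PER_DEG = EARTH_RADIUS_KM * 1000.0 * np.pi / 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def meters_to_degrees(de_m, dn_m, lat):
    """Convert eastward/northward displacements in metres to (dlon, dlat) degrees at latitude ``lat``."""
    lat = np.asarray(lat, dtype=float)
    dlat = np.asarray(dn_m, dtype=float) / M_PER_DEG
    dlon = np.asarray(de_m, dtype=float) / (M_PER_DEG * np.cos(np.radians(lat)))
    return dlon, dlat


def normalize_lon(lon):
    """Normalize longitudes to [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0
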