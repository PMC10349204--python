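"""Spherical-Earth geometry helpers shared across the package.

All distances are great-circle (haversine) kilometres on a sphere of radius
6371 km; degree/metre conversions use the local metric (metres per degree of
longitude scaled by cos(latitude)), which is adequate for the regional domains
this package targets.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: metres per degree of latitude (and of longitude at the equator)
M_PER_DEG = EARTH_RADIUS_KM * 1000.0 * np.pi / 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def m_per_deg_lon(lat_deg):
    """Metres per degree of longitude at the given latitude(s)."""
    return M_PER_DEG * np.cos(np.radians(np.asarray(lat_deg, dtype=float)))


def m_per_deg_lat():
    """Metres per degree of latitude (latitude-independent on a sphere)."""
    return M_PER_DEG
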