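"""Spherical geodesy helpers.

All distances use the haversine formula on a sphere of radius
``EARTH_RADIUS_KM`` = 6371 km. At the scale of migratory steps
(kilometers to a few hundred kilometers) the error against an
ellipsoid is well under 0.5%.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or numpy arrays (broadcast).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial compass bearing (degrees clockwise from north) from point 1 to 2."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(x, y)) % 360.0


def destination(lon, lat, bearing_deg, distance_km):
    """Point reached from (lon, lat) moving ``distance_km`` along ``bearing_deg``."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    d = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat1) * np.cos(d) + np.cos(lat1) * np.sin(d) * np.cos(brg))
    lon2 = lon1 + np.arctan2(np.sin(brg) * np.sin(d) * np.cos(lat1),
                             np.cos(d) - np.sin(lat1) * np.sin(lat2))
    lon2 = (np.degrees(lon2) + 540.0) % 360.0 - 180.0
    return lon2, np.degrees(lat2)


def aeq_project(lons, lats, lon0, lat0):
    """Azimuthal-equidistant projection centered on (lon0, lat0), in km.

    Metrically correct radially from the center; the standard choice for
    buffering short trajectory segments at any latitude.
    """
    c = haversine_km(lon0, lat0, lons, lats) / EARTH_RADIUS_KM
    az = np.radians(initial_bearing_deg(lon0, lat0, lons, lats))
    r = c * EARTH_RADIUS_KM
    return r * np.sin(az), r * np.cos(az)


def path_length_km(lons, lats):
    """Cumulative great-circle length of a polyline, in km."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size < 2:
        return 0.0
    return float(np.sum(haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:])))
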