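"""Small geodesy helpers used throughout the package.

All distances are great-circle distances on a sphere of radius
``EARTH_RADIUS_KM``.  The 5-km thinning grid lives in a world cylindrical
equal-area projection, where a "5 km x 5 km" cell is a metric statement that
holds at every latitude.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Inputs broadcast like numpy arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def sphere_xyz(lon, lat):
    """Unit-sphere Cartesian coordinates (n, 3) for lon/lat in degrees."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return np.column_stack((np.cos(lat) * np.cos(lon),
                            np.cos(lat) * np.sin(lon),
                            np.sin(lat)))


def chord_length(distance_km: float) -> float:
    """Chord on the unit sphere subtending a great-circle distance in km.

    Used to turn a geodesic radius into a Euclidean KD-tree radius.
    """
    return 2.0 * np.sin(distance_km / (2.0 * EARTH_RADIUS_KM))


def cea_project(lon, lat):
    """World cylindrical (Lambert) equal-area projection, metres.

    x = R * lon_rad, y = R * sin(lat).  Equal-area, so fixed-size cells in
    (x, y) have the same ground area everywhere.
    """
    R = EARTH_RADIUS_KM * 1000.0
    x = R * np.radians(np.asarray(lon, dtype=float))
    y = R * np.sin(np.radians(np.asarray(lat, dtype=float)))
    return x, y


def equal_area_cell(lon, lat, cell_km: float = 5.0):
    """Integer (ix, iy) id of the equal-area grid cell containing each point."""
    x, y = cea_project(lon, lat)
    cell_m = cell_km * 1000.0
    return (np.floor(x / cell_m).astype(np.int64),
            np.floor(y / cell_m).astype(np.int64))
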