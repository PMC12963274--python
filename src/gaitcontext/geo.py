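"""Spherical and local-plane geometry helpers.

Distances use the haversine formula on a sphere of radius 6,371,000 m.
Local planar work (clustering, synthetic trace generation) uses an
equirectangular projection about a reference latitude, which is sub-meter
accurate at the city scales involved and exactly invertible.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters; accepts scalars or arrays (degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def xy_to_latlon(x_m, y_m, ref_lat: float, ref_lon: float):
    """Equirectangular inverse: local meters east/north -> degrees."""
    lat = np.asarray(ref_lat, dtype=float) + np.degrees(
        np.asarray(y_m, dtype=float) / EARTH_RADIUS_M
    )
    lon = np.asarray(ref_lon, dtype=float) + np.degrees(
        np.asarray(x_m, dtype=float)
        / (EARTH_RADIUS_M * np.cos(np.radians(ref_lat)))
    )
    return lat, lon


def latlon_to_xy(lat, lon, ref_lat: float, ref_lon: float):
    """Equirectangular forward: degrees -> local meters east/north."""
    y = np.radians(np.asarray(lat, dtype=float) - ref_lat) * EARTH_RADIUS_M
    x = (
        np.radians(np.asarray(lon, dtype=float) - ref_lon)
        * EARTH_RADIUS_M
        * np.cos(np.radians(ref_lat))
    )
    return x, y
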