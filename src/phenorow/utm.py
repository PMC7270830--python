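"""WGS84 <-> UTM conversion (Krüger series transverse Mercator).

Vehicle tracks are logged as RTK latitude/longitude; all field geometry
lives in a metre-based UTM zone, so the track must be projected before
sensor positions can be intersected with plant polygons.  The sixth-order
Krüger series used here agrees with reference implementations to well
under a millimetre within a zone.
"""

from __future__ import annotations

import numpy as np

__all__ = ["latlon_to_utm", "utm_to_latlon", "epsg_for_zone", "zone_for_lon"]

# WGS84
_A = 6378137.0
_F = 1 / 298.257223563
_K0 = 0.9996
_E0 = 500000.0  # false easting
_N0_SOUTH = 10000000.0

_N = _F / (2 - _F)
_A_CAP = _A / (1 + _N) * (1 + _N**2 / 4 + _N**4 / 64 + _N**6 / 256)

_ALPHA = (
    _N / 2 - 2 * _N**2 / 3 + 5 * _N**3 / 16 + 41 * _N**4 / 180,
    13 * _N**2 / 48 - 3 * _N**3 / 5 + 557 * _N**4 / 1440,
    61 * _N**3 / 240 - 103 * _N**4 / 140,
    49561 * _N**4 / 161280,
)
_BETA = (
    _N / 2 - 2 * _N**2 / 3 - 37 * _N**3 / 96 + 1 * _N**4 / 360,
    _N**2 / 48 + _N**3 / 15 - 437 * _N**4 / 1440,
    17 * _N**3 / 480 - 37 * _N**4 / 840,
    4397 * _N**4 / 161280,
)
_DELTA = (
    2 * _N - 2 * _N**2 / 3 - 2 * _N**3 + 116 * _N**4 / 45,
    7 * _N**2 / 3 - 8 * _N**3 / 5 - 227 * _N**4 / 45,
    56 * _N**3 / 15 - 136 * _N**4 / 35,
    4279 * _N**4 / 630,
)


def zone_for_lon(lon_deg: float) -> int:
    return int((float(lon_deg) + 180) // 6) + 1


def epsg_for_zone(zone: int, south: bool) -> str:
    return f"EPSG:{(32700 if south else 32600) + zone}"


def _central_meridian(zone: int) -> float:
    return np.radians(zone * 6 - 183)


def latlon_to_utm(lat, lon, zone: int | None = None):
    """Project latitude/longitude (degrees) to UTM easting/northing (m).

    Returns ``(easting, northing, zone, south)``.  If ``zone`` is given the
    coordinates are forced into that zone (inputs more than ~5 degrees of
    longitude outside it raise, with a hint at the natural zone).
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 84):
        raise ValueError("latitude outside UTM validity (|lat| > 84)")
    natural = zone_for_lon(float(np.mean(lon)))
    if zone is None:
        zone = natural
    lon0 = np.degrees(_central_meridian(zone))
    if np.any(np.abs(lon - lon0) > 8):
        raise ValueError(
            f"longitude too far from zone {zone} central meridian "
            f"({lon0:.0f} deg); natural zone would be {natural}"
        )
    south = bool(np.mean(lat) < 0)

    phi = np.radians(lat)
    lam = np.radians(lon) - _central_meridian(zone)
    t = np.sinh(
        np.arctanh(np.sin(phi))
        - 2 * np.sqrt(_N) / (1 + _N) * np.arctanh(
            2 * np.sqrt(_N) / (1 + _N) * np.sin(phi)
        )
    )
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))
    xi = xi_p.copy()
    eta = eta_p.copy()
    for j, a in enumerate(_ALPHA, start=1):
        xi = xi + a * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
        eta = eta + a * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)
    easting = _E0 + _K0 * _A_CAP * eta
    northing = _K0 * _A_CAP * xi + (_N0_SOUTH if south else 0.0)
    return easting, northing, zone, south


def utm_to_latlon(easting, northing, zone: int, south: bool):
    """Inverse of :func:`latlon_to_utm`; returns (lat, lon) in degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    xi = (northing - (_N0_SOUTH if south else 0.0)) / (_K0 * _A_CAP)
    eta = (easting - _E0) / (_K0 * _A_CAP)
    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, b in enumerate(_BETA, start=1):
        xi_p = xi_p - b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p = eta_p - b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)
    chi = np.arcsin(np.sin(xi_p) / np.cosh(eta_p))
    phi = chi.copy()
    for j, d in enumerate(_DELTA, start=1):
        phi = phi + d * np.sin(2 * j * chi)
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
    lat = np.degrees(phi)
    lon = np.degrees(lam + _central_meridian(zone))
    return lat, lon
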