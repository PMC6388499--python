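"""WGS84 geographic <-> UTM planar coordinate conversion.

Implements the transverse Mercator mapping with the Krueger/Karney
flattening series (6th order in the third flattening n), which is exact to
well below a millimetre anywhere inside a UTM zone's domain of validity.
Coordinates are returned in metres (easting, northing) with the standard
UTM conventions: scale factor 0.9996 on the central meridian, 500 km false
easting, and a 10,000 km false northing in the southern hemisphere.
"""

from __future__ import annotations

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_N = _F / (2.0 - _F)
_E = np.sqrt(_F * (2.0 - _F))  # first eccentricity

_K0 = 0.9996
_FALSE_EASTING = 500000.0
_FALSE_NORTHING_S = 10000000.0

# Rectifying radius
_AR = _A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0)

# Karney (2011) series coefficients, order n^6
_ALPHA = np.array([
    _N / 2 - 2 * _N**2 / 3 + 5 * _N**3 / 16 + 41 * _N**4 / 180
    - 127 * _N**5 / 288 + 7891 * _N**6 / 37800,
    13 * _N**2 / 48 - 3 * _N**3 / 5 + 557 * _N**4 / 1440
    + 281 * _N**5 / 630 - 1983433 * _N**6 / 1935360,
    61 * _N**3 / 240 - 103 * _N**4 / 140 + 15061 * _N**5 / 26880
    + 167603 * _N**6 / 181440,
    49561 * _N**4 / 161280 - 179 * _N**5 / 168 + 6601661 * _N**6 / 7257600,
    34729 * _N**5 / 80640 - 3418889 * _N**6 / 1995840,
    212378941 * _N**6 / 319334400,
])
_BETA = np.array([
    _N / 2 - 2 * _N**2 / 3 + 37 * _N**3 / 96 - _N**4 / 360
    - 81 * _N**5 / 512 + 96199 * _N**6 / 604800,
    _N**2 / 48 + _N**3 / 15 - 437 * _N**4 / 1440
    + 46 * _N**5 / 105 - 1118711 * _N**6 / 3870720,
    17 * _N**3 / 480 - 37 * _N**4 / 840 - 209 * _N**5 / 4480
    + 5569 * _N**6 / 90720,
    4397 * _N**4 / 161280 - 11 * _N**5 / 504 - 830251 * _N**6 / 7257600,
    4583 * _N**5 / 161280 - 108847 * _N**6 / 3991680,
    20648693 * _N**6 / 638668800,
])
_J = np.arange(1, 7)


def utm_central_meridian(zone: int) -> float:
    """Central meridian (degrees east) of a UTM longitude zone (1-60)."""
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be in 1..60, got {zone}")
    return -183.0 + 6.0 * zone


def geographic_to_utm(lon, lat, zone: int, north: bool = True):
    """Project lon/lat (degrees, WGS84) to UTM easting/northing (metres).

    Raises ValueError when any point lies outside the projection's domain
    (|lat| > 84 deg or more than ~30 deg from the central meridian).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 84.0) or np.any(np.abs(lon) > 180.0):
        bad = np.flatnonzero((np.abs(lat) > 84.0) | (np.abs(lon) > 180.0))
        raise ValueError(f"coordinates outside projection validity at rows {bad.tolist()}")
    lam0 = np.deg2rad(utm_central_meridian(zone))
    lam = np.deg2rad(lon) - lam0
    lam = (lam + np.pi) % (2 * np.pi) - np.pi
    if np.any(np.abs(lam) > np.deg2rad(30.0)):
        bad = np.flatnonzero(np.abs(lam) > np.deg2rad(30.0))
        raise ValueError(f"longitude too far from zone {zone} central meridian at rows {bad.tolist()}")
    phi = np.deg2rad(lat)

    sphi = np.sin(phi)
    t = np.sinh(np.arctanh(sphi) - _E * np.arctanh(_E * sphi))
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arctanh(np.sin(lam) / np.sqrt(1.0 + t**2))

    two_j_xi = 2.0 * np.multiply.outer(_J, xi_p)
    two_j_eta = 2.0 * np.multiply.outer(_J, eta_p)
    xi = xi_p + np.tensordot(_ALPHA, np.sin(two_j_xi) * np.cosh(two_j_eta), axes=1)
    eta = eta_p + np.tensordot(_ALPHA, np.cos(two_j_xi) * np.sinh(two_j_eta), axes=1)

    easting = _FALSE_EASTING + _K0 * _AR * eta
    northing = _K0 * _AR * xi
    if not north:
        northing = northing + _FALSE_NORTHING_S
    return easting, northing


def utm_to_geographic(easting, northing, zone: int, north: bool = True):
    """Inverse UTM projection; returns (lon, lat) in degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    if not north:
        northing = northing - _FALSE_NORTHING_S
    xi = northing / (_K0 * _AR)
    eta = (easting - _FALSE_EASTING) / (_K0 * _AR)

    two_j_xi = 2.0 * np.multiply.outer(_J, xi)
    two_j_eta = 2.0 * np.multiply.outer(_J, eta)
    xi_p = xi - np.tensordot(_BETA, np.sin(two_j_xi) * np.cosh(two_j_eta), axes=1)
    eta_p = eta - np.tensordot(_BETA, np.cos(two_j_xi) * np.sinh(two_j_eta), axes=1)

    t_p = np.sin(xi_p) / np.sqrt(np.sinh(eta_p) ** 2 + np.cos(xi_p) ** 2)
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

    # Newton-solve tan(phi) from the conformal-latitude tangent t_p
    e2 = _E**2
    t = np.asarray(t_p / (1.0 - e2), dtype=float)
    for _ in range(6):
        sig = np.sinh(_E * np.arctanh(_E * t / np.sqrt(1.0 + t**2)))
        taup = t * np.sqrt(1.0 + sig**2) - sig * np.sqrt(1.0 + t**2)
        dtaup = (np.sqrt(1.0 + taup**2) * np.sqrt(1.0 + t**2) * (1.0 - e2)
                 / (1.0 + (1.0 - e2) * t**2))
        t = t - (taup - t_p) / dtaup
    phi = np.arctan(t)

    lon = np.rad2deg(lam + np.deg2rad(utm_central_meridian(zone)))
    lon = (lon + 180.0) % 360.0 - 180.0
    return lon, np.rad2deg(phi)
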