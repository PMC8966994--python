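"""WGS-84 geodesics and fix-error annotation.

Horizontal error is the length of the geodesic (shortest ellipsoidal
surface path) between a fix and the surveyed reference; vertical error is
the signed difference ``reference altitude - fix altitude``, so positive
values mean the device *under*-estimates the true altitude. Both altitudes
are heights above the WGS-84 ellipsoid; no geoid conversion is performed.

The inverse and direct geodesic problems are solved with Vincenty's
iterative formulae on the WGS-84 ellipsoid, vectorised over numpy arrays.
Vincenty is accurate to well under a millimetre at the sub-kilometre
scales of a stationary calibration test; it is not reliable for
near-antipodal point pairs, which cannot arise in this application.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .fix_io import GeoFix, ReferencePoint

__all__ = [
    "WGS84_A",
    "WGS84_F",
    "ErrorRecord",
    "geodesic_inverse",
    "geodesic_distance",
    "geodesic_direct",
    "vertical_error",
    "error_category",
    "annotate_errors",
    "ERROR_CATEGORIES",
]

# WGS-84 defining parameters
WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
_B = WGS84_A * (1.0 - WGS84_F)

#: Error-magnitude categories. "accurate" covers [0, 10] m; the remaining
#: bins are half-open on the left: (10, 20], (20, 30], (30, inf). A fix is
#: "inaccurate" when its error strictly exceeds 10 m.
ERROR_CATEGORIES = ("accurate", "11-20", "21-30", ">30")
_CATEGORY_EDGES = (10.0, 20.0, 30.0)


def _validate_latlon(lat: np.ndarray, lon: np.ndarray) -> None:
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("coordinates must be finite")
    if np.any((lat < -90.0) | (lat > 90.0)):
        raise ValueError("latitude outside [-90, 90]")
    if np.any((lon < -180.0) | (lon >= 180.0)):
        raise ValueError("longitude outside [-180, 180)")


def geodesic_inverse(
    lat1, lon1, lat2, lon2, *, tol: float = 1e-15, max_iter: int = 200
):
    """Solve the inverse geodesic problem on the WGS-84 ellipsoid.

    Parameters are decimal degrees (scalars or broadcastable arrays).

    Returns
    -------
    (distance, azimuth)
        Geodesic distance in metres and forward azimuth at the first
        point in degrees clockwise from north. Scalars in, scalars out.
    """
    scalar = np.isscalar(lat1) and np.isscalar(lat2)
    lat1, lon1, lat2, lon2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    )
    _validate_latlon(lat1, lon1)
    _validate_latlon(lat2, lon2)

    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    L = np.radians(lon2 - lon1)
    U1 = np.arctan((1.0 - WGS84_F) * np.tan(phi1))
    U2 = np.arctan((1.0 - WGS84_F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)

    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.hypot(
            cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        )
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(
                sin_sigma > 0.0, cosU1 * cosU2 * sin_lam / sin_sigma, 0.0
            )
        cos_sq_alpha = 1.0 - sin_alpha**2
        with np.errstate(divide="ignore", invalid="ignore"):
            cos2sm = np.where(
                cos_sq_alpha > 0.0,
                cos_sigma - 2.0 * sinU1 * sinU2 / np.where(
                    cos_sq_alpha > 0.0, cos_sq_alpha, 1.0
                ),
                0.0,  # equatorial line
            )
        C = WGS84_F / 16.0 * cos_sq_alpha * (
            4.0 + WGS84_F * (4.0 - 3.0 * cos_sq_alpha)
        )
        lam_new = L + (1.0 - C) * WGS84_F * sin_alpha * (
            sigma
            + C * sin_sigma * (cos2sm + C * cos_sigma * (-1.0 + 2.0 * cos2sm**2))
        )
        if np.all(np.abs(lam_new - lam) < tol):
            lam = lam_new
            break
        lam = lam_new

    u_sq = cos_sq_alpha * (WGS84_A**2 - _B**2) / _B**2
    A = 1.0 + u_sq / 16384.0 * (
        4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq))
    )
    Bc = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = Bc * sin_sigma * (
        cos2sm
        + Bc / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos2sm**2)
            - Bc / 6.0 * cos2sm * (-3.0 + 4.0 * sin_sigma**2)
            * (-3.0 + 4.0 * cos2sm**2)
        )
    )
    s = _B * A * (sigma - delta_sigma)

    sin_lam, cos_lam = np.sin(lam), np.cos(lam)
    az = np.degrees(
        np.arctan2(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
    ) % 360.0

    if scalar:
        return float(s), float(az)
    return s, az


def geodesic_distance(lat1, lon1, lat2, lon2):
    """Geodesic distance in metres between WGS-84 points (degrees).

    Symmetric, non-negative, and zero iff the coordinates coincide.
    """
    return geodesic_inverse(lat1, lon1, lat2, lon2)[0]


def geodesic_direct(lat1, lon1, azimuth, distance, *, tol: float = 1e-15):
    """Solve the direct geodesic problem: start point + azimuth + distance.

    ``azimuth`` in degrees clockwise from north, ``distance`` in metres.
    Returns ``(lat2, lon2)`` in degrees, with lon2 wrapped to [-180, 180).
    """
    scalar = np.isscalar(distance) and np.isscalar(azimuth) and np.isscalar(lat1)
    lat1, lon1, azimuth, distance = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (lat1, lon1, azimuth, distance))
    )
    _validate_latlon(lat1, lon1)
    if np.any(distance < 0.0):
        raise ValueError("distance must be non-negative")

    phi1 = np.radians(lat1)
    alpha1 = np.radians(azimuth)
    U1 = np.arctan((1.0 - WGS84_F) * np.tan(phi1))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sin_a1, cos_a1 = np.sin(alpha1), np.cos(alpha1)

    sigma1 = np.arctan2(np.tan(U1), cos_a1)
    sin_alpha = cosU1 * sin_a1
    cos_sq_alpha = 1.0 - sin_alpha**2
    u_sq = cos_sq_alpha * (WGS84_A**2 - _B**2) / _B**2
    A = 1.0 + u_sq / 16384.0 * (
        4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq))
    )
    Bc = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))

    sigma = distance / (_B * A)
    for _ in range(200):
        cos2sm = np.cos(2.0 * sigma1 + sigma)
        sin_sigma, cos_sigma = np.sin(sigma), np.cos(sigma)
        delta_sigma = Bc * sin_sigma * (
            cos2sm
            + Bc / 4.0 * (
                cos_sigma * (-1.0 + 2.0 * cos2sm**2)
                - Bc / 6.0 * cos2sm * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos2sm**2)
            )
        )
        sigma_new = distance / (_B * A) + delta_sigma
        if np.all(np.abs(sigma_new - sigma) < tol):
            sigma = sigma_new
            break
        sigma = sigma_new

    sin_sigma, cos_sigma = np.sin(sigma), np.cos(sigma)
    cos2sm = np.cos(2.0 * sigma1 + sigma)
    phi2 = np.arctan2(
        sinU1 * cos_sigma + cosU1 * sin_sigma * cos_a1,
        (1.0 - WGS84_F)
        * np.hypot(sin_alpha, sinU1 * sin_sigma - cosU1 * cos_sigma * cos_a1),
    )
    lam = np.arctan2(
        sin_sigma * sin_a1, cosU1 * cos_sigma - sinU1 * sin_sigma * cos_a1
    )
    C = WGS84_F / 16.0 * cos_sq_alpha * (
        4.0 + WGS84_F * (4.0 - 3.0 * cos_sq_alpha)
    )
    L = lam - (1.0 - C) * WGS84_F * sin_alpha * (
        sigma
        + C * sin_sigma * (cos2sm + C * cos_sigma * (-1.0 + 2.0 * cos2sm**2))
    )
    lat2 = np.degrees(phi2)
    lon2 = (np.degrees(np.radians(lon1) + L) + 180.0) % 360.0 - 180.0

    if scalar:
        return float(lat2), float(lon2)
    return lat2, lon2


def vertical_error(ref_alt: float, fix_alt: float) -> float:
    """Signed vertical error ``ref_alt - fix_alt`` in metres.

    Positive when the device reads an altitude *below* the true one
    (underestimation), negative when the device reads too high.
    """
    if not (np.isfinite(ref_alt) and np.isfinite(fix_alt)):
        raise ValueError("both altitudes must be finite")
    return float(ref_alt) - float(fix_alt)


def error_category(error_m: float) -> str:
    """Bin an error magnitude into accurate / 11-20 / 21-30 / >30 m.

    Bins are (10, 20], (20, 30], (30, inf); magnitudes up to and
    including 10 m count as accurate.
    """
    e = abs(float(error_m))
    for edge, name in zip(_CATEGORY_EDGES, ERROR_CATEGORIES[:3]):
        if e <= edge:
            return name
    return ERROR_CATEGORIES[3]


@dataclass(frozen=True, slots=True)
class ErrorRecord:
    """A fix annotated with its realised errors against a reference.

    ``v_err`` and ``v_category`` are ``None`` for fixes without altitude;
    such records contribute to horizontal statistics only.
    """

    fix: "GeoFix"
    h_err: float
    h_category: str
    v_err: Optional[float] = None
    v_category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.h_err < 0.0:
            raise ValueError("h_err must be non-negative")


def annotate_errors(
    fixes: Sequence["GeoFix"], ref: "ReferencePoint"
) -> list[ErrorRecord]:
    """Annotate each fix with horizontal/vertical error vs. a reference.

    Horizontal error is the WGS-84 geodesic distance to the reference;
    vertical error follows the underestimation-positive sign convention.
    Returns an empty list for empty input.
    """
    if len(fixes) == 0:
        return []
    lat = np.array([f.lat for f in fixes])
    lon = np.array([f.lon for f in fixes])
    h = np.atleast_1d(geodesic_distance(lat, lon, ref.lat, ref.lon))
    out = []
    for f, he in zip(fixes, h):
        if f.alt is not None and ref.alt is not None:
            ve = vertical_error(ref.alt, f.alt)
            out.append(
                ErrorRecord(
                    fix=f,
                    h_err=float(he),
                    h_category=error_category(he),
                    v_err=ve,
                    v_category=error_category(ve),
                )
            )
        else:
            out.append(
                ErrorRecord(fix=f, h_err=float(he), h_category=error_category(he))
            )
    return out
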