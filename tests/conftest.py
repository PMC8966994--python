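"""Shared fixtures: reference points and fix factories.

Test fixes are constructed with the package's direct geodesic (place a
point at a given distance/azimuth from the reference), so displacements
are specified in metres, never in degrees.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import settings

from gpscal import GeoFix, ReferencePoint, geodesic_direct

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

T0 = datetime(2021, 6, 1, tzinfo=timezone.utc)


@pytest.fixture
def reference() -> ReferencePoint:
    return ReferencePoint(lat=38.5306, lon=-8.0128, alt=212.0)


@pytest.fixture
def make_fix(reference):
    """Factory: a fix displaced a given distance/azimuth from the reference."""

    counter = {"k": 0}

    def _make(
        distance_m: float = 0.0,
        azimuth_deg: float = 0.0,
        *,
        alt_err: float | None = 0.0,
        gps_error: float | None = None,
        device: str = "dev01",
        minutes: int | None = None,
        schedule: str = "custom",
        phase: str = "stationary",
    ) -> GeoFix:
        lat, lon = geodesic_direct(
            reference.lat, reference.lon, azimuth_deg, distance_m
        )
        if minutes is None:
            minutes = counter["k"]
            counter["k"] += 1
        return GeoFix(
            device_id=device,
            timestamp=T0 + timedelta(minutes=minutes),
            lat=lat,
            lon=lon,
            alt=None if alt_err is None else reference.alt - alt_err,
            gps_error=gps_error,
            schedule=schedule,
            phase=phase,
        )

    return _make
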