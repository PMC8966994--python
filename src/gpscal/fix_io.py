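"""Reading, validating and writing GPS fix tables and reference points.

Fix tables are delimited text (Movebank-style or plain headers) or XLSX
workbooks. Every record is validated against coordinate ranges and, per
device, sorted by timestamp (stable, so file order breaks exact ties).
Result tables are written as delimited text with ``#``-prefixed metadata
header lines and round-trip to the written precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import geodesy

__all__ = [
    "GeoFix",
    "ReferencePoint",
    "SCHEDULES",
    "PHASES",
    "DIALECTS",
    "read_fix_table",
    "fixes_to_frame",
    "read_reference",
    "average_reference",
    "write_results",
    "read_result_table",
]

logger = logging.getLogger(__name__)

SCHEDULES = ("1min", "20min", "60min", "custom")
PHASES = ("stationary", "before_deployment", "after_deployment")

#: Built-in column dialects mapping GeoFix fields -> file column names.
DIALECTS: dict[str, dict[str, str]] = {
    "plain": {
        "device_id": "device_id",
        "timestamp": "timestamp",
        "lat": "lat",
        "lon": "lon",
        "alt": "alt",
        "gps_error": "gps_error",
        "schedule": "schedule",
        "phase": "phase",
    },
    "movebank": {
        "device_id": "tag-local-identifier",
        "timestamp": "timestamp",
        "lat": "location-lat",
        "lon": "location-long",
        "alt": "height-above-ellipsoid",
        "gps_error": "gps-error",
        "schedule": "schedule",
        "phase": "phase",
    },
}

_MANDATORY = ("device_id", "timestamp", "lat", "lon")


@dataclass(frozen=True, slots=True)
class GeoFix:
    """One GPS position solution.

    ``gps_error`` is the device's self-reported positional error estimate
    in metres — the maximum lat/lon displacement at 67% probability
    (about one standard deviation). ``alt`` is metres above the WGS-84
    ellipsoid; both are optional because not every device or schedule
    emits them.
    """

    device_id: str
    timestamp: datetime
    lat: float
    lon: float
    alt: Optional[float] = None
    gps_error: Optional[float] = None
    schedule: str = "custom"
    phase: str = "stationary"

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon < 180.0):
            raise ValueError(f"lon {self.lon} outside [-180, 180)")
        if self.gps_error is not None and not (
            math.isfinite(self.gps_error) and self.gps_error >= 0.0
        ):
            raise ValueError(f"gps_error {self.gps_error} must be finite and >= 0")
        if self.alt is not None and not math.isfinite(self.alt):
            raise ValueError("alt must be finite when present")
        if self.schedule not in SCHEDULES:
            raise ValueError(f"schedule {self.schedule!r} not in {SCHEDULES}")
        if self.phase not in PHASES:
            raise ValueError(f"phase {self.phase!r} not in {PHASES}")
        if self.timestamp.tzinfo is None:
            # bare timestamps are taken as UTC
            object.__setattr__(
                self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc)
            )


@dataclass(frozen=True, slots=True)
class ReferencePoint:
    """A surveyed true location (e.g. a triangulation station or nest).

    May be the average of several differential-GPS readings;
    ``h_uncertainty``/``v_uncertainty`` are then the sample SDs of the
    readings' horizontal distances / altitude offsets to the mean.
    """

    lat: float
    lon: float
    alt: Optional[float] = None
    n_readings: int = 1
    h_uncertainty: Optional[float] = None
    v_uncertainty: Optional[float] = None

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon < 180.0):
            raise ValueError(f"lon {self.lon} outside [-180, 180)")
        if self.n_readings < 1:
            raise ValueError("n_readings must be >= 1")


def _resolve_dialect(dialect: Union[str, Mapping[str, str]]) -> dict[str, str]:
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise ValueError(
                f"unknown dialect {dialect!r}; built-ins: {sorted(DIALECTS)}"
            ) from None
    return dict(dialect)


def _load_frame(path: Union[str, Path], sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path, sep=sep, comment="#")


def read_fix_table(
    path: Union[str, Path],
    dialect: Union[str, Mapping[str, str]] = "plain",
    *,
    strict: bool = True,
    sep: str = ",",
    schedule: Optional[str] = None,
    phase: Optional[str] = None,
) -> list[GeoFix]:
    """Read a fix table (delimited text or XLSX) into validated GeoFix records.

    ``dialect`` names a built-in column mapping or provides one directly.
    Under ``strict=True`` any invalid row aborts with its row number; under
    lenient mode invalid rows are logged and dropped. ``schedule``/``phase``
    override or supply those fields when the file lacks the columns.
    Records are returned sorted by (device, timestamp), ties kept in file
    order.
    """
    cols = _resolve_dialect(dialect)
    df = _load_frame(path, sep)

    missing = [cols[f] for f in _MANDATORY if cols[f] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    def col(fld: str) -> Optional[pd.Series]:
        name = cols.get(fld)
        return df[name] if name is not None and name in df.columns else None

    ts = pd.to_datetime(col("timestamp"), utc=True, errors="coerce")
    fixes: list[GeoFix] = []
    problems: list[str] = []
    alt_s, err_s, sch_s, ph_s = col("alt"), col("gps_error"), col("schedule"), col("phase")
    for i in range(len(df)):
        row_no = i + 2  # 1-based plus header line
        try:
            t = ts.iloc[i]
            if pd.isna(t):
                raise ValueError(f"unparseable timestamp {df[cols['timestamp']].iloc[i]!r}")
            fixes.append(
                GeoFix(
                    device_id=str(df[cols["device_id"]].iloc[i]),
                    timestamp=t.to_pydatetime(),
                    lat=float(df[cols["lat"]].iloc[i]),
                    lon=float(df[cols["lon"]].iloc[i]),
                    alt=_opt_float(alt_s, i),
                    gps_error=_opt_float(err_s, i),
                    schedule=schedule or _opt_str(sch_s, i) or "custom",
                    phase=phase or _opt_str(ph_s, i) or "stationary",
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {row_no}: {exc}")
    if problems:
        msg = f"{path}: {len(problems)} invalid row(s): " + "; ".join(problems[:10])
        if strict:
            raise ValueError(msg)
        logger.warning("%s (rows dropped)", msg)
    fixes.sort(key=lambda f: (f.device_id, f.timestamp))  # stable: ties keep file order
    return fixes


def _opt_float(series: Optional[pd.Series], i: int) -> Optional[float]:
    if series is None:
        return None
    v = series.iloc[i]
    if pd.isna(v):
        return None
    return float(v)


def _opt_str(series: Optional[pd.Series], i: int) -> Optional[str]:
    if series is None:
        return None
    v = series.iloc[i]
    if pd.isna(v):
        return None
    return str(v)


def fixes_to_frame(fixes: Sequence[GeoFix]) -> pd.DataFrame:
    """Tabular (plain-dialect) view of a fix collection."""
    return pd.DataFrame(
        {
            "device_id": [f.device_id for f in fixes],
            "timestamp": [f.timestamp.isoformat() for f in fixes],
            "lat": [f.lat for f in fixes],
            "lon": [f.lon for f in fixes],
            "alt": [f.alt for f in fixes],
            "gps_error": [f.gps_error for f in fixes],
            "schedule": [f.schedule for f in fixes],
            "phase": [f.phase for f in fixes],
        }
    )


def read_reference(path: Union[str, Path], *, sep: str = ",") -> ReferencePoint:
    """Read a single reference point from a small delimited table.

    Expects columns ``lat, lon`` and optionally ``alt``. Multiple rows are
    treated as repeated raw readings and averaged (see
    :func:`average_reference`), mirroring field practice of taking a few
    differential-GPS readings at the surveyed point.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    for c in ("lat", "lon"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    readings = [
        ReferencePoint(
            lat=float(r.lat),
            lon=float(r.lon),
            alt=float(r.alt) if "alt" in df.columns and pd.notna(r.alt) else None,
        )
        for r in df.itertuples()
    ]
    if len(readings) == 1:
        return readings[0]
    return average_reference(readings)


def average_reference(readings: Sequence[ReferencePoint]) -> ReferencePoint:
    """Average repeated reference readings into one ReferencePoint.

    Coordinates are averaged arithmetically in degrees — valid because the
    spread of repeated differential-GPS readings is a few metres, far below
    the ~1 km scale where degree-space averaging would distort. Horizontal
    uncertainty is the sample SD of each reading's geodesic distance to
    the mean point; vertical uncertainty the sample SD of altitudes.
    """
    if len(readings) == 0:
        raise ValueError("cannot average zero readings")
    if len(readings) == 1:
        return replace(readings[0], n_readings=1)
    lat = float(np.mean([r.lat for r in readings]))
    lon = float(np.mean([r.lon for r in readings]))
    alts = [r.alt for r in readings if r.alt is not None]
    alt = float(np.mean(alts)) if alts else None
    d = [geodesy.geodesic_distance(r.lat, r.lon, lat, lon) for r in readings]
    h_unc = float(np.std(d, ddof=1))
    v_unc = float(np.std(alts, ddof=1)) if len(alts) >= 2 else None
    return ReferencePoint(
        lat=lat,
        lon=lon,
        alt=alt,
        n_readings=len(readings),
        h_uncertainty=h_unc,
        v_uncertainty=v_unc,
    )


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: Union[str, Path],
    *,
    metadata: Optional[Mapping[str, str]] = None,
    sep: str = ",",
) -> list[Path]:
    """Write named result tables as delimited text, one file per table.

    Each file starts with ``#``-prefixed metadata lines (tool version plus
    caller-supplied key/value pairs) so that runs are self-describing;
    re-reading with :func:`read_result_table` reproduces the values.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"gpscal_version": __version__, **(metadata or {})}
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        with open(p, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            df.to_csv(fh, sep=sep, index=False)
        written.append(p)
    return written


def read_result_table(path: Union[str, Path], *, sep: str = ",") -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, sep=sep, comment="#")
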