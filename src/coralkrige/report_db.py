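"""Parse, validate, QC and grid the observational bleaching-report table.

A bleaching report is one survey record: who reported it, where, when, and
how severe the bleaching was.  Severity uses the ReefBase ordinal code:

    -1  unknown severity
     0  no bleaching      (<1% of living coral bleached)
     1  mild bleaching    (1-10%)
     2  moderate          (10-50%)
     3  severe            (>50%)

To enter the database a report must at minimum carry latitude, longitude,
year, a severity code and a source.  Reports whose coordinates fall off the
reef raster are snapped to the nearest reef cell by great-circle distance,
up to a configurable cap; reports farther than the cap from any reef are
rejected as unlocatable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .grid import CellIndex, ReefMask, latlon_to_cell

VALID_SEVERITIES = (-1, 0, 1, 2, 3)

#: canonical CSV column order for the report table
REPORT_COLUMNS = [
    "SOURCE", "COUNTRY", "SITE", "LAT", "LON", "YEAR", "MONTH",
    "PERCENT_BLEACHED", "SEVERITY", "PERCENT_MORTALITY", "MORTALITY_CODE",
    "DEPTH_M", "METHOD",
]

MANDATORY_FIELDS = ("lat", "lon", "year", "severity", "source")

FIRST_REPORT_YEAR = 1963


@dataclass
class BleachingReport:
    """One observational record, after validation."""

    source: str
    lat: float
    lon: float
    year: int
    severity: int
    country: Optional[str] = None
    site: Optional[str] = None
    month: Optional[int] = None
    percent_bleached: Optional[float] = None
    percent_mortality: Optional[float] = None
    mortality_code: Optional[int] = None
    depth_m: Optional[float] = None
    method: Optional[str] = None


@dataclass
class QCLogEntry:
    row: int                    # 0-based input row number
    action: str                 # "rejected" | "infilled" | "conflict" | "snapped"
    reason: str


@dataclass
class ParseResult:
    reports: list[BleachingReport] = field(default_factory=list)
    log: list[QCLogEntry] = field(default_factory=list)
    n_input_rows: int = 0

    @property
    def n_rejected(self) -> int:
        return sum(1 for e in self.log if e.action == "rejected")


def percent_to_severity(percent: float) -> int:
    """Map a percent-bleached value to its ordinal severity code.

    Boundary convention (the published ranges overlap at their edges):
    exactly 1% and exactly 10% are mild, exactly 50% is moderate.
    """
    if not (0.0 <= percent <= 100.0) or not math.isfinite(percent):
        raise ValueError(f"percent bleached outside [0, 100]: {percent}")
    if percent < 1.0:
        return 0
    if percent <= 10.0:
        return 1
    if percent <= 50.0:
        return 2
    return 3


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_int(value) -> Optional[int]:
    v = _opt_float(value)
    return None if v is None else int(v)


def parse_reports(path_or_df, last_year: Optional[int] = None) -> ParseResult:
    """Read the report table and apply the minimum-field rule.

    Parameters
    ----------
    path_or_df : str | Path | pandas.DataFrame
        CSV with the documented header (case-insensitive), or an
        already-loaded frame with those columns.
    last_year : int, optional
        Upper bound on plausible report years; rows beyond it are rejected.

    Returns
    -------
    ParseResult
        Accepted records in input order plus a per-row QC log.  A row is
        rejected (never fatal) when it misses a mandatory field or its
        coordinates are out of range.  A missing severity is infilled from
        percent bleached where possible; a conflict between an explicit
        severity code and the percent value resolves in favor of the code
        and is logged.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)
    df.columns = [str(c).strip().upper() for c in df.columns]
    missing_cols = {"SOURCE", "LAT", "LON", "YEAR", "SEVERITY"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"report table missing required columns: {sorted(missing_cols)}")

    result = ParseResult(n_input_rows=len(df))
    for row_no, row in enumerate(df.to_dict("records")):
        entry = _parse_row(row_no, row, last_year)
        if isinstance(entry, QCLogEntry):
            result.log.append(entry)
        else:
            report, row_log = entry
            result.reports.append(report)
            result.log.extend(row_log)
    return result


def _parse_row(row_no: int, row: dict, last_year: Optional[int]):
    def reject(reason: str) -> QCLogEntry:
        return QCLogEntry(row=row_no, action="rejected", reason=reason)

    values = {
        "source": row.get("SOURCE"),
        "lat": _opt_float(row.get("LAT")),
        "lon": _opt_float(row.get("LON")),
        "year": _opt_int(row.get("YEAR")),
        "severity": _opt_int(row.get("SEVERITY")),
    }
    percent = _opt_float(row.get("PERCENT_BLEACHED"))
    log: list[QCLogEntry] = []

    if values["severity"] is None and percent is not None:
        values["severity"] = percent_to_severity(percent)
        log.append(QCLogEntry(row_no, "infilled", f"severity infilled from percent_bleached={percent:g}"))

    source = values["source"]
    if source is None or (isinstance(source, float) and math.isnan(source)) or str(source).strip() == "":
        values["source"] = None
    for name in MANDATORY_FIELDS:
        if values[name] is None:
            return reject(f"missing mandatory field: {name}")

    lat, lon = values["lat"], values["lon"]
    if not (-90.0 <= lat <= 90.0):
        return reject(f"latitude out of range: {lat}")
    if not (-180.0 <= lon < 180.0):
        return reject(f"longitude out of range: {lon}")
    year = values["year"]
    if year < FIRST_REPORT_YEAR or (last_year is not None and year > last_year):
        return reject(f"year out of range: {year}")
    severity = values["severity"]
    if severity not in VALID_SEVERITIES:
        return reject(f"invalid severity code: {severity}")
    if percent is not None and not (0.0 <= percent <= 100.0):
        return reject(f"percent bleached out of range: {percent}")

    if percent is not None and severity != -1 and percent_to_severity(percent) != severity:
        log.append(QCLogEntry(
            row_no, "conflict",
            f"severity code {severity} kept over percent_bleached={percent:g} "
            f"(implies {percent_to_severity(percent)})",
        ))

    report = BleachingReport(
        source=str(values["source"]),
        lat=lat, lon=lon, year=year, severity=severity,
        country=row.get("COUNTRY") if isinstance(row.get("COUNTRY"), str) else None,
        site=row.get("SITE") if isinstance(row.get("SITE"), str) else None,
        month=_opt_int(row.get("MONTH")),
        percent_bleached=percent,
        percent_mortality=_opt_float(row.get("PERCENT_MORTALITY")),
        mortality_code=_opt_int(row.get("MORTALITY_CODE")),
        depth_m=_opt_float(row.get("DEPTH_M")),
        method=row.get("METHOD") if isinstance(row.get("METHOD"), str) else None,
    )
    return report, log


def snap_to_reef(report: BleachingReport, mask: ReefMask) -> tuple[CellIndex, bool, float]:
    """Locate a report on the reef raster.

    Returns ``(cell, moved, distance_km)``.  If the report's own cell is a
    reef cell it is kept unmoved; otherwise the report snaps to the reef
    cell whose center is nearest by great-circle distance (ties to the
    lowest (j, i)).
    """
    own = latlon_to_cell(report.lat, report.lon)
    if own in mask:
        return own, False, 0.0
    cell, dist = mask.nearest_cell(report.lat, report.lon)
    return cell, True, dist


def snap_reports(
    reports: Sequence[BleachingReport],
    mask: ReefMask,
    max_snap_km: float = 50.0,
) -> tuple[list[tuple[BleachingReport, CellIndex]], list[QCLogEntry]]:
    """Snap every report onto the reef raster, rejecting gross outliers.

    Reports farther than ``max_snap_km`` from any reef cell are dropped as
    unlocatable; that cap guards against wildly wrong coordinates that
    unconditional snapping would silently relocate.
    """
    located: list[tuple[BleachingReport, CellIndex]] = []
    log: list[QCLogEntry] = []
    for row_no, report in enumerate(reports):
        cell, moved, dist = snap_to_reef(report, mask)
        if dist > max_snap_km:
            log.append(QCLogEntry(row_no, "rejected", f"nearest reef {dist:.1f} km away exceeds {max_snap_km:g} km cap"))
            continue
        if moved:
            log.append(QCLogEntry(row_no, "snapped", f"moved {dist:.2f} km to reef cell ({cell.i}, {cell.j})"))
        located.append((report, cell))
    return located, log


def presence_cells(
    located_reports: Iterable[tuple[BleachingReport, CellIndex]],
    year: int,
) -> set[CellIndex]:
    """Cells with at least one moderate-or-severe report that year.

    Presence means severity code > 1; mild (1), no-bleaching (0) and
    unknown (-1) reports never create a presence cell.
    """
    return {cell for report, cell in located_reports if report.year == year and report.severity > 1}


def reports_to_frame(reports: Sequence[BleachingReport]) -> pd.DataFrame:
    """Serialize reports back to the canonical CSV schema."""
    rows = []
    for r in reports:
        rows.append({
            "SOURCE": r.source, "COUNTRY": r.country, "SITE": r.site,
            "LAT": r.lat, "LON": r.lon, "YEAR": r.year, "MONTH": r.month,
            "PERCENT_BLEACHED": r.percent_bleached, "SEVERITY": r.severity,
            "PERCENT_MORTALITY": r.percent_mortality, "MORTALITY_CODE": r.mortality_code,
            "DEPTH_M": r.depth_m, "METHOD": r.method,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
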