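"""Flat-file I/O: monitoring-record CSV with validation, scored-result
CSV, spatial sample CSV, and grid export (long CSV, ESRI ASCII grid,
GeoJSON points).

Readers reject rather than guess: every unparseable or out-of-range cell
is recorded in a :class:`ValidationReport` with row, field, and reason;
rows that cannot form a valid record are dropped from the output but
never silently.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import WqimapError
from .geostat import KrigingGrid, SpatialSample
from .standards import (
    SEASONS,
    SOURCES,
    SUPPLIES,
    MonitoringRecord,
    StandardsTable,
)
from .wqi import WQIResult

META_COLUMNS = ["point_id", "lon", "lat", "year", "season", "source", "supply"]
MISSING_TOKENS = {"", "na", "nan", "null", "none"}
LOD_POLICIES = ("half", "zero", "lod")
_LOD_RE = re.compile(r"^<\s*([0-9.eE+-]+)$")


@dataclass
class Issue:
    row: int
    field: str
    message: str
    severity: str = "error"  # error | warning


@dataclass
class ValidationReport:
    n_rows_read: int = 0
    n_rows_accepted: int = 0
    issues: list[Issue] = field(default_factory=list)

    def add(self, row: int, field_: str, message: str, severity: str = "error") -> None:
        self.issues.append(Issue(row, field_, message, severity))

    def to_dict(self) -> dict:
        return {
            "n_rows_read": self.n_rows_read,
            "n_rows_accepted": self.n_rows_accepted,
            "issues": [
                {"row": i.row, "field": i.field, "message": i.message,
                 "severity": i.severity}
                for i in self.issues
            ],
        }


def _parse_measurement(token: str, lod_policy: str) -> tuple[float | None, str | None]:
    """Parse one indicator cell.  Returns (value, note); value None means
    missing; note is set when a below-LOD token was substituted."""
    s = str(token).strip()
    if s.lower() in MISSING_TOKENS:
        return None, None
    m = _LOD_RE.match(s)
    if m:
        lod = float(m.group(1))
        value = {"half": lod / 2.0, "zero": 0.0, "lod": lod}[lod_policy]
        return value, f"below-LOD token {s!r} parsed as {value} ({lod_policy} policy)"
    return float(s), None


def read_records(
    path: str | Path,
    standards: StandardsTable | None = None,
    lod_policy: str = "half",
    bbox: tuple[float, float, float, float] | None = None,
) -> tuple[list[MonitoringRecord], ValidationReport]:
    """Read a monitoring-record CSV.

    Required columns: point_id, lon, lat, year, season, source, supply,
    then one column per indicator code.  Empty cells and "NA" are
    missing; ``<x`` cells are substituted per ``lod_policy``
    (``half`` -> LOD/2, ``zero``, or ``lod``).  Range violations
    (negative concentrations, pH outside (0, 14), coordinates outside
    ``bbox`` if given) flag the row; flagged rows are excluded from the
    returned records but fully described in the report.
    """
    if lod_policy not in LOD_POLICIES:
        raise ValueError(f"lod_policy must be one of {LOD_POLICIES}")
    standards = standards or StandardsTable.default()
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise WqimapError(f"cannot read records file {path}: {exc}") from exc
    missing_cols = [c for c in META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise WqimapError(
            f"records file {path} lacks required columns {missing_cols}"
        )
    indicator_cols = [c for c in df.columns if c not in META_COLUMNS]
    unknown = [c for c in indicator_cols if c not in standards]
    if unknown:
        raise WqimapError(
            f"records file {path} has indicator columns with no standards "
            f"entry: {unknown}"
        )

    report = ValidationReport(n_rows_read=len(df))
    records: list[MonitoringRecord] = []
    for idx, row in df.iterrows():
        ok = True
        meas: dict[str, float] = {}
        try:
            lon, lat = float(row["lon"]), float(row["lat"])
            year = int(row["year"])
        except ValueError as exc:
            report.add(idx, "lon/lat/year", f"unparseable: {exc}")
            continue
        for name, allowed in (("season", SEASONS), ("source", SOURCES),
                              ("supply", SUPPLIES)):
            if row[name] not in allowed:
                report.add(idx, name, f"{row[name]!r} not in {allowed}")
                ok = False
        if bbox is not None:
            x0, x1, y0, y1 = bbox
            if not (x0 <= lon <= x1 and y0 <= lat <= y1):
                report.add(idx, "lon/lat",
                           f"({lon}, {lat}) outside declared bounding box",
                           severity="warning")
        for code in indicator_cols:
            try:
                value, note = _parse_measurement(row[code], lod_policy)
            except ValueError:
                report.add(idx, code, f"unparseable value {row[code]!r}")
                ok = False
                continue
            if note:
                report.add(idx, code, note, severity="warning")
            if value is None:
                continue
            if code == "ph":
                if not (0.0 < value < 14.0):
                    report.add(idx, code, f"pH {value} outside (0, 14)")
                    ok = False
                    continue
            elif value < 0:
                report.add(idx, code, f"negative concentration {value}")
                ok = False
                continue
            meas[code] = value
        if not ok:
            continue
        records.append(
            MonitoringRecord(
                point_id=str(row["point_id"]),
                longitude=lon,
                latitude=lat,
                year=year,
                season=str(row["season"]),
                source=str(row["source"]),
                supply=str(row["supply"]),
                measurements=meas,
            )
        )
    report.n_rows_accepted = len(records)
    return records, report


def write_records_csv(
    records: Sequence[MonitoringRecord],
    path: str | Path,
    standards: StandardsTable | None = None,
) -> None:
    """Write records in the schema :func:`read_records` consumes."""
    standards = standards or StandardsTable.default()
    codes = standards.codes
    rows = []
    for r in records:
        row = {
            "point_id": r.point_id,
            "lon": repr(r.longitude),
            "lat": repr(r.latitude),
            "year": r.year,
            "season": r.season,
            "source": r.source,
            "supply": r.supply,
        }
        for c in codes:
            v = r.measurements.get(c)
            row[c] = "" if v is None else repr(v)
        rows.append(row)
    pd.DataFrame(rows, columns=META_COLUMNS + codes).to_csv(path, index=False)


def results_to_frame(results: Sequence[WQIResult]) -> pd.DataFrame:
    """Scored results as a DataFrame: point_id, each sub-index, total."""
    codes = sorted({c for r in results for c in r.subindices})
    rows = []
    for r in results:
        row = {"point_id": r.point_id}
        row.update({c: r.subindices.get(c) for c in codes})
        row["wqi"] = r.total
        row["n_indicators_used"] = r.n_indicators_used
        rows.append(row)
    return pd.DataFrame(rows)


def read_samples_csv(path: str | Path) -> list[SpatialSample]:
    """Read (x, y, value[, point_id]) spatial samples."""
    df = pd.read_csv(path)
    for col in ("x", "y", "value"):
        if col not in df.columns:
            raise WqimapError(f"samples file {path} lacks column {col!r}")
    has_id = "point_id" in df.columns
    return [
        SpatialSample(
            float(r.x), float(r.y), float(r.value),
            point_id=str(r.point_id) if has_id else "",
        )
        for r in df.itertuples(index=False)
    ]


def write_samples_csv(samples: Sequence[SpatialSample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "point_id": [s.point_id for s in samples],
            "x": [s.x for s in samples],
            "y": [s.y for s in samples],
            "value": [s.value for s in samples],
        }
    ).to_csv(path, index=False)


GRID_FORMATS = ("csv", "asc", "geojson")


def write_grid(grid: KrigingGrid, fmt: str, path: str | Path) -> None:
    """Export a kriged grid.

    ``csv``: long format (x, y, predicted, variance), one row per cell,
    row-major.  ``asc``: ESRI ASCII grid of the prediction layer (cell
    centers; first data row is the *northernmost*, per the format).
    ``geojson``: a FeatureCollection of cell-center points.
    """
    if fmt not in GRID_FORMATS:
        raise ValueError(f"fmt must be one of {GRID_FORMATS}")
    spec = grid.spec
    xs, ys = spec.centers()
    path = Path(path)
    if fmt == "csv":
        xx, yy = np.meshgrid(xs, ys)
        pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "predicted": grid.predicted.ravel(),
                "variance": grid.variance.ravel(),
            }
        ).to_csv(path, index=False, float_format="%.12g")
    elif fmt == "asc":
        dx, dy = spec.cell_size
        if abs(dx - dy) > 1e-9 * max(abs(dx), abs(dy)):
            raise WqimapError(
                "ESRI ASCII grids need square cells; use csv or geojson"
            )
        header = (
            f"ncols {spec.n_x}\n"
            f"nrows {spec.n_y}\n"
            f"xllcorner {spec.x_min!r}\n"
            f"yllcorner {spec.y_min!r}\n"
            f"cellsize {dx!r}\n"
            f"NODATA_value -9999\n"
        )
        body = "\n".join(
            " ".join(f"{v:.10g}" for v in row) for row in grid.predicted[::-1]
        )
        path.write_text(header + body + "\n")
    else:
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [float(xs[i]), float(ys[j])]},
                "properties": {
                    "predicted": float(grid.predicted[j, i]),
                    "variance": float(grid.variance[j, i]),
                },
            }
            for j in range(spec.n_y)
            for i in range(spec.n_x)
        ]
        doc = {"type": "FeatureCollection", "features": features}
        path.write_text(json.dumps(doc) + "\n")


def samples_to_geojson(samples: Sequence[SpatialSample], path: str | Path) -> None:
    """Sample points as a GeoJSON FeatureCollection (map overlays)."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [s.x, s.y]},
            "properties": {"point_id": s.point_id, "value": s.value},
        }
        for s in samples
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}) + "\n"
    )
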