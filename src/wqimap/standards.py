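"""Regulatory standards tables and monitoring-record containers.

A :class:`StandardsTable` maps each indicator code to its category
(``general``, ``ph``, or ``microbial``) and, for general constituents,
the regulatory limit :math:`S_i` in the indicator's native units.  A
default table for the 16 routine drinking-water indicators, populated
from China's national drinking-water standard, ships with the package
as editable JSON; all limits are treated as configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import InvalidStandardError, InvalidMeasurementError

CATEGORIES = ("general", "ph", "microbial")
SEASONS = ("dry", "wet")
SOURCES = ("groundwater", "surface")
SUPPLIES = ("centralized", "decentralized")


@dataclass(frozen=True)
class StandardEntry:
    """One indicator's standards row: code, category, limit Si, units."""

    code: str
    category: str
    limit: float | None
    units: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidStandardError(
                f"indicator {self.code!r}: unknown category {self.category!r}"
            )
        if self.category == "general":
            if self.limit is None or not self.limit > 0:
                raise InvalidStandardError(
                    f"indicator {self.code!r}: general entries need a limit Si > 0, "
                    f"got {self.limit!r}"
                )
        elif self.limit is not None:
            raise InvalidStandardError(
                f"indicator {self.code!r}: {self.category} entries carry no limit, "
                f"got {self.limit!r}"
            )


class StandardsTable:
    """Collection of :class:`StandardEntry` rows, keyed by indicator code.

    Invariants enforced on construction: codes unique, every ``general``
    entry has Si > 0, exactly one ``ph`` entry, ``microbial`` entries
    have no Si.
    """

    def __init__(self, entries: Iterable[StandardEntry]):
        self._entries: dict[str, StandardEntry] = {}
        for e in entries:
            if e.code in self._entries:
                raise InvalidStandardError(f"duplicate indicator code {e.code!r}")
            self._entries[e.code] = e
        n_ph = sum(1 for e in self._entries.values() if e.category == "ph")
        if n_ph != 1:
            raise InvalidStandardError(f"expected exactly one ph entry, found {n_ph}")

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __getitem__(self, code: str) -> StandardEntry:
        return self._entries[code]

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def codes(self) -> list[str]:
        return list(self._entries)

    def codes_by_category(self, category: str) -> list[str]:
        return [c for c, e in self._entries.items() if e.category == category]

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardsTable":
        with open(path) as fh:
            doc = json.load(fh)
        rows = doc["entries"] if isinstance(doc, dict) else doc
        return cls(
            StandardEntry(
                code=r["code"],
                category=r["category"],
                limit=r.get("limit"),
                units=r.get("units", ""),
            )
            for r in rows
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "StandardsTable":
        df = pd.read_csv(path)
        entries = []
        for r in df.itertuples(index=False):
            limit = getattr(r, "limit", None)
            if limit is not None and pd.isna(limit):
                limit = None
            entries.append(
                StandardEntry(
                    code=str(r.code),
                    category=str(r.category),
                    limit=None if limit is None else float(limit),
                    units=str(getattr(r, "units", "") or ""),
                )
            )
        return cls(entries)

    @classmethod
    def load(cls, path: str | Path) -> "StandardsTable":
        path = Path(path)
        if path.suffix.lower() == ".json":
            return cls.from_json(path)
        return cls.from_csv(path)

    @classmethod
    def default(cls) -> "StandardsTable":
        """The bundled 16-indicator table (national drinking-water limits)."""
        ref = resources.files("wqimap.data").joinpath("standards_cn.json")
        with resources.as_file(ref) as p:
            return cls.from_json(p)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "entries": [
                {
                    "code": e.code,
                    "category": e.category,
                    "limit": e.limit,
                    "units": e.units,
                }
                for e in self._entries.values()
            ]
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")


@dataclass
class MonitoringRecord:
    """One water sample: identity, location, stratum metadata, and the
    measured concentrations Ci keyed by indicator code.

    Measurements may be missing (absent key).  pH is constrained to
    (0, 14); all other measurements must be nonnegative.
    """

    point_id: str
    longitude: float
    latitude: float
    year: int
    season: str
    source: str
    supply: str
    measurements: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise InvalidMeasurementError(
                f"{self.point_id}: season must be one of {SEASONS}, got {self.season!r}"
            )
        if self.source not in SOURCES:
            raise InvalidMeasurementError(
                f"{self.point_id}: source must be one of {SOURCES}, got {self.source!r}"
            )
        if self.supply not in SUPPLIES:
            raise InvalidMeasurementError(
                f"{self.point_id}: supply must be one of {SUPPLIES}, got {self.supply!r}"
            )
        for code, value in self.measurements.items():
            if code == "ph":
                if not (0.0 < value < 14.0):
                    raise InvalidMeasurementError(
                        f"{self.point_id}: pH must lie in (0, 14), got {value}"
                    )
            elif value < 0:
                raise InvalidMeasurementError(
                    f"{self.point_id}: {code} must be >= 0, got {value}"
                )
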