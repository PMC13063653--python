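"""Data model, file formats and validation for landmark rating tables.

A *rating* is one complete placement of all landmarks on one subject's
combined face-jaw scan by one rater in one repeat session.  Ratings are
interchanged as long-format CSV with header
``subject,rater,repeat,group,landmark,x,y,z`` — coordinates in mm,
``.`` decimal mark, UTF-8.  Landmark names are case-sensitive.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Point3",
    "RatingRecord",
    "LandmarkCatalog",
    "DEFAULT_CATALOG",
    "ValidationReport",
    "RatingsParseError",
    "read_ratings",
    "validate_complete",
    "write_table",
]

VALID_GROUPS = ("A", "B", "unassigned")


class RatingsParseError(ValueError):
    """Raised for malformed, duplicate or unknown-landmark rows."""


@dataclass(frozen=True)
class Point3:
    """A 3D point in mm: x transverse, y sagittal, z vertical."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for axis in (self.x, self.y, self.z):
            if not math.isfinite(axis):
                raise ValueError(f"non-finite coordinate in {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a: Sequence[float]) -> "Point3":
        return Point3(float(a[0]), float(a[1]), float(a[2]))

    @staticmethod
    def midpoint(p: "Point3", q: "Point3") -> "Point3":
        return Point3((p.x + q.x) / 2.0, (p.y + q.y) / 2.0, (p.z + q.z) / 2.0)


@dataclass
class RatingRecord:
    """One landmark set for one subject x rater x repeat."""

    subject_id: str
    rater_id: str
    repeat_index: int
    group: str
    landmarks: dict[str, Point3] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.repeat_index < 1:
            raise ValueError("repeat_index must be >= 1")
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"group must be one of {VALID_GROUPS}, got {self.group!r}"
            )

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.rater_id, self.repeat_index)

    def coords(self, names: Iterable[str]) -> np.ndarray:
        """Stack the named landmarks into an (n, 3) array, erroring on absences."""
        rows = []
        for name in names:
            if name not in self.landmarks:
                raise KeyError(f"landmark {name!r} missing from record {self.key}")
            rows.append(self.landmarks[name].as_array())
        return np.array(rows)


#: Landmark roster. Paired facial landmarks carry R/L suffixes (patient's
#: right/left); RPM_1..RPM_6 run anteroposteriorly along the median
#: palatine raphe; mes11/mes21 are the mesial crown points of the upper
#: central incisors.
REQUIRED_LANDMARKS: tuple[str, ...] = (
    "N",
    "OR",
    "OL",
    "EXR",
    "EXL",
    "ENR",
    "ENL",
    "PR",
    "PL",
    "LS",
    "PRN",
    "SN",
    "POG",
    "GN",
    "mes11",
    "mes21",
    "RPM_1",
    "RPM_2",
    "RPM_3",
    "RPM_4",
    "RPM_5",
    "RPM_6",
)
# 22 names: 14 facial + 2 dental + 6 raphe.


@dataclass(frozen=True)
class LandmarkCatalog:
    """Which landmark names a dataset must / may contain."""

    required_names: tuple[str, ...] = REQUIRED_LANDMARKS
    optional_names: tuple[str, ...] = ()

    def known(self, name: str) -> bool:
        return name in self.required_names or name in self.optional_names


DEFAULT_CATALOG = LandmarkCatalog()


@dataclass(frozen=True)
class ValidationReport:
    record_key: tuple[str, str, int]
    missing: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.missing


def read_ratings(
    path: str | Path, catalog: LandmarkCatalog = DEFAULT_CATALOG
) -> list[RatingRecord]:
    """Read a long-format ratings CSV into one record per (subject, rater, repeat).

    Records are returned sorted by (subject, rater, repeat) regardless of
    row order in the file.  Raises :class:`RatingsParseError` naming the
    offending line for malformed rows, duplicate landmark placements, or
    landmark names not in *catalog*.
    """
    path = Path(path)
    expected = ["subject", "rater", "repeat", "group", "landmark", "x", "y", "z"]
    records: dict[tuple[str, str, int], RatingRecord] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RatingsParseError(f"{path}: empty file") from None
        if [h.strip() for h in header] != expected:
            raise RatingsParseError(
                f"{path}: line 1: expected header {','.join(expected)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 8:
                raise RatingsParseError(
                    f"{path}: line {lineno}: expected 8 fields, got {len(row)}"
                )
            subject, rater, repeat_s, group, name = (f.strip() for f in row[:5])
            try:
                repeat = int(repeat_s)
                point = Point3(float(row[5]), float(row[6]), float(row[7]))
            except ValueError as exc:
                raise RatingsParseError(f"{path}: line {lineno}: {exc}") from None
            if not catalog.known(name):
                raise RatingsParseError(
                    f"{path}: line {lineno}: unknown landmark {name!r}"
                )
            key = (subject, rater, repeat)
            record = records.get(key)
            if record is None:
                try:
                    record = RatingRecord(subject, rater, repeat, group)
                except ValueError as exc:
                    raise RatingsParseError(
                        f"{path}: line {lineno}: {exc}"
                    ) from None
                records[key] = record
            elif record.group != group:
                raise RatingsParseError(
                    f"{path}: line {lineno}: conflicting group label for {key}"
                )
            if name in record.landmarks:
                raise RatingsParseError(
                    f"{path}: line {lineno}: duplicate landmark {name!r} for {key}"
                )
            record.landmarks[name] = point
    return [records[k] for k in sorted(records)]


def validate_complete(
    record: RatingRecord, catalog: LandmarkCatalog = DEFAULT_CATALOG
) -> ValidationReport:
    """Report which required landmarks are missing from *record*."""
    missing = tuple(n for n in catalog.required_names if n not in record.landmarks)
    return ValidationReport(record_key=record.key, missing=missing)


def write_ratings(records: Iterable[RatingRecord], path: str | Path) -> None:
    """Write records back to the long-format ratings CSV (4-decimal mm)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "rater", "repeat", "group", "landmark", "x", "y", "z"])
        for rec in sorted(records, key=lambda r: r.key):
            for name, p in rec.landmarks.items():
                writer.writerow(
                    [
                        rec.subject_id,
                        rec.rater_id,
                        rec.repeat_index,
                        rec.group,
                        name,
                        f"{p.x:.4f}",
                        f"{p.y:.4f}",
                        f"{p.z:.4f}",
                    ]
                )


def write_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    fieldnames: Sequence[str] | None = None,
) -> None:
    """Write homogeneous keyed rows as CSV, floats formatted to 4 decimals.

    All rows must share one key set (column order from *fieldnames* if
    given, else from the first row).  An empty row list with *fieldnames*
    yields a header-only file.  Heterogeneous key sets raise ValueError.
    """
    path = Path(path)
    rows = list(rows)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if not rows and fieldnames is None:
            return
        keys = list(fieldnames) if fieldnames is not None else list(rows[0].keys())
        keyset = set(keys)
        writer.writerow(keys)
        for i, row in enumerate(rows):
            if set(row.keys()) != keyset:
                raise ValueError(f"row {i} key set differs from header {keys}")
            writer.writerow(
                [
                    f"{v:.4f}" if isinstance(v, (float, np.floating)) else v
                    for v in (row[k] for k in keys)
                ]
            )
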