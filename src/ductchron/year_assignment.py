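"""Assigning calendar years to the sentinel-delimited duct stream.

One core's measurements form a single ordered stream in which each ring's
ducts are followed by one zero-area sentinel. Splitting the stream on
sentinels therefore recovers the rings in order; anchoring the first
group at the innermost measured year dates every duct. Two adjacent
sentinels produce an empty group — either a ring with no ducts or a
missing (locally absent) ring; the stream alone cannot tell them apart,
so :func:`verify_alignment` cross-checks against the dated ring widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MeasurementFormatError, ValidationError
from .imagej import MeasurementFile
from .rwl_io import RingWidthSeries


@dataclass
class DatedDuctTable:
    """Per-year duct areas for one core.

    ``rows[k]`` holds the duct areas (mm², all > 0) of year
    ``first_year + k``; empty lists are years with zero ducts. One row
    exists per sentinel in the source measurement stream.
    """

    sample_id: str
    first_year: int
    rows: list[list[float]]

    def __post_init__(self) -> None:
        for k, areas in enumerate(self.rows):
            if any(a <= 0 for a in areas):
                raise ValidationError(
                    f"{self.sample_id}: non-positive duct area in year "
                    f"{self.first_year + k}"
                )

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.rows) - 1

    @property
    def years(self) -> list[int]:
        return list(range(self.first_year, self.first_year + len(self.rows)))

    @property
    def n_ducts(self) -> int:
        return sum(len(r) for r in self.rows)


def assign_years(measurements: MeasurementFile, first_year: int) -> DatedDuctTable:
    """Group the measurement stream into dated rings.

    Entries are split into maximal runs of non-sentinel areas, each
    terminated by one sentinel; run *k* (0-based) gets year
    ``first_year + k``. A leading sentinel is allowed (ductless first
    ring); zero sentinels is a structural error.
    """
    flags = np.fromiter(
        (e.is_sentinel for e in measurements.entries), dtype=bool,
        count=len(measurements.entries),
    )
    if not flags.any():
        raise MeasurementFormatError(
            f"{measurements.sample_id}: no sentinel measurements — cannot "
            "delimit rings"
        )
    if not flags[-1]:
        raise MeasurementFormatError(
            f"{measurements.sample_id}: unterminated final ring"
        )
    areas = np.array([e.area_mm2 for e in measurements.entries])
    bounds = np.flatnonzero(flags)
    starts = np.concatenate(([0], bounds[:-1] + 1))
    rows = [list(areas[s:e]) for s, e in zip(starts, bounds)]
    return DatedDuctTable(
        sample_id=measurements.sample_id, first_year=first_year, rows=rows
    )


@dataclass
class AlignmentReport:
    """Cross-check result between a dated duct table and its ring widths.

    An empty ``violations`` list means the table is consistent with the
    ring-width record. Violations are reported, not raised, so the user
    can fix the source TXT file and re-run.
    """

    sample_id: str
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_alignment(
    table: DatedDuctTable, series: RingWidthSeries, last_year: int
) -> AlignmentReport:
    """Check a dated duct table against the core's ring-width series.

    Three rules: (a) the table must end at ``last_year`` (ring count check
    — a dropped or doubled sentinel shifts every later year); (b) every
    table year must lie within the series' span; (c) a year whose ring
    width is zero (missing ring) must have zero ducts.
    """
    report = AlignmentReport(sample_id=table.sample_id)
    expected = last_year - table.first_year + 1
    if table.last_year != last_year:
        report.violations.append(
            f"year count mismatch: expected {expected} rings "
            f"({table.first_year}-{last_year}), found {len(table.rows)}"
        )
    for year in table.years:
        if not series.first_year <= year <= series.last_year:
            report.violations.append(
                f"year {year} outside ring-width series span "
                f"{series.first_year}-{series.last_year}"
            )
    for year, areas in zip(table.years, table.rows):
        if series.first_year <= year <= series.last_year:
            width = series.widths[year - series.first_year]
            if width == 0 and areas:
                report.violations.append(
                    f"duct recorded in missing ring {year} "
                    f"({len(areas)} duct(s), ring width 0)"
                )
    return report


# ---------------------------------------------------------------------------
# Per-core dated-duct CSV persistence (one row per duct; empty years get a
# single row with a blank area so no year is lost).

_CSV_COLUMNS = ["sample_id", "year", "duct_area_mm2"]


def to_frame(table: DatedDuctTable) -> pd.DataFrame:
    records = []
    for year, areas in zip(table.years, table.rows):
        if areas:
            records.extend(
                {"sample_id": table.sample_id, "year": year, "duct_area_mm2": a}
                for a in areas
            )
        else:
            records.append(
                {"sample_id": table.sample_id, "year": year, "duct_area_mm2": np.nan}
            )
    return pd.DataFrame.from_records(records, columns=_CSV_COLUMNS)


def write_dated_csv(table: DatedDuctTable, path: str | Path) -> None:
    """Write one core's dated ducts as CSV (empty years -> blank area)."""
    to_frame(table).to_csv(path, index=False)


def read_dated_csv(path: str | Path) -> DatedDuctTable:
    """Read a per-core dated-duct CSV back into a :class:`DatedDuctTable`.

    The filename stem is authoritative for the sample ID; years must be
    consecutive.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise MeasurementFormatError(f"{path.name}: missing columns {missing}")
    if frame.empty:
        raise MeasurementFormatError(f"{path.name}: empty dated-duct file")
    years = frame["year"].astype(int)
    first_year = int(years.min())
    n_years = int(years.max()) - first_year + 1
    if set(years) != set(range(first_year, first_year + n_years)):
        raise MeasurementFormatError(
            f"{path.name}: years are not consecutive"
        )
    rows: list[list[float]] = [[] for _ in range(n_years)]
    for year, area in zip(years, frame["duct_area_mm2"]):
        if pd.notna(area):
            rows[year - first_year].append(float(area))
    return DatedDuctTable(sample_id=path.stem, first_year=first_year, rows=rows)
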