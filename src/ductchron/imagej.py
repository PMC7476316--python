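"""Parsing ImageJ "Results" exports of per-duct ellipse areas.

Resin ducts are measured one ellipse at a time in ImageJ, which records
areas in square inches (the scale is set from the scan DPI). Ring
boundaries are encoded in the measurement stream itself: after the last
duct of a ring the operator clicks a zero-area "fake" measurement at the
ring boundary, and a missing ring gets a second consecutive fake. This
module reads those exports, flags the sentinel rows, and converts areas
to mm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import MeasurementFormatError

#: Exact square-inch to square-millimetre factor (25.4 mm per inch, squared).
IN2_TO_MM2 = 25.4**2  # 645.16

#: Non-sentinel areas below this (in in²) trigger an "is this a fake?" warning.
AMBIGUITY_FLOOR_IN2 = 1e-5


@dataclass(frozen=True)
class DuctEntry:
    """One measurement row: a duct ellipse or a sentinel boundary click."""

    order_index: int
    raw_area_in2: float
    area_mm2: float
    is_sentinel: bool


@dataclass
class MeasurementFile:
    """All measurement rows of one core, oldest ring first.

    The final entry must be a sentinel: every ring, including the last,
    is terminated by a fake measurement.
    """

    sample_id: str
    entries: list[DuctEntry]

    @property
    def n_sentinels(self) -> int:
        return sum(e.is_sentinel for e in self.entries)

    @property
    def n_ducts(self) -> int:
        return len(self.entries) - self.n_sentinels


def detect_delimiter(path: str | Path) -> str:
    """Return the delimiter ('\\t' or ',') whose split exposes an Area column.

    ImageJ saves tab-separated ``.txt`` by default but falls back to CSV;
    tab wins a tie. Raises :class:`MeasurementFormatError` if neither
    delimiter yields an Area header (case-insensitive).
    """
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
    for delim in ("\t", ","):
        cols = [c.strip().lower() for c in header.rstrip("\n").split(delim)]
        if "area" in cols:
            return delim
    raise MeasurementFormatError(
        f"{Path(path).name}: no 'Area' column found with tab or comma delimiter"
    )


def read_measurements(
    path: str | Path, sentinel_threshold: float = 0.0
) -> MeasurementFile:
    """Read one core's ImageJ Results export.

    The sample ID is the filename stem (which by convention matches the
    core's RWL series ID). Rows are kept in file order — oldest ring
    toward the pith first. Areas at or below ``sentinel_threshold``
    (in in², default exactly 0) are flagged as sentinels; all areas are
    converted to mm². Extra ImageJ columns (Label, Mean, ...) are ignored.

    Raises
    ------
    MeasurementFormatError
        If there is no Area column, an area is negative, or the final
        row is not a sentinel (an unterminated final ring would silently
        drop the newest ring downstream).
    """
    path = Path(path)
    delim = detect_delimiter(path)
    frame = pd.read_csv(path, sep=delim)
    area_col = next((c for c in frame.columns if c.strip().lower() == "area"), None)
    if area_col is None:  # pragma: no cover - detect_delimiter already checks
        raise MeasurementFormatError(f"{path.name}: no 'Area' column")
    areas = pd.to_numeric(frame[area_col], errors="coerce")
    if areas.isna().any():
        row = int(areas.index[areas.isna()][0]) + 2  # +header +1-based
        raise MeasurementFormatError(f"{path.name}: non-numeric Area at line {row}")
    if (areas < 0).any():
        row = int(areas.index[areas < 0][0]) + 2
        raise MeasurementFormatError(f"{path.name}: negative Area at line {row}")
    if len(areas) == 0:
        raise MeasurementFormatError(f"{path.name}: file contains no measurements")

    entries = []
    for i, raw in enumerate(areas.to_numpy(dtype=float), start=1):
        sentinel = raw <= sentinel_threshold
        if not sentinel and raw < AMBIGUITY_FLOOR_IN2:
            warnings.warn(
                f"{path.name}: row {i} area {raw:g} in² is implausibly small "
                "for a duct — verify it is not a mis-recorded fake measurement",
                stacklevel=2,
            )
        entries.append(
            DuctEntry(
                order_index=i,
                raw_area_in2=float(raw),
                area_mm2=float(raw) * IN2_TO_MM2,
                is_sentinel=bool(sentinel),
            )
        )
    if not entries[-1].is_sentinel:
        raise MeasurementFormatError(
            f"{path.name}: unterminated final ring — the last measurement "
            "must be a sentinel (fake) boundary click"
        )
    return MeasurementFile(sample_id=path.stem, entries=entries)


def write_measurements(measurements: MeasurementFile, path: str | Path) -> None:
    """Serialize entries back to an ImageJ-style tab-separated table.

    Used for fixtures and idempotence checks; the layout mirrors an
    ImageJ Results export (row index, Label, Area in in²).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(" \tLabel\tArea\n")
        for e in measurements.entries:
            fh.write(f"{e.order_index}\t{measurements.sample_id}.tif\t{e.raw_area_in2!r}\n")
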