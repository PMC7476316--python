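"""Reading and writing Tucson ("decadal") RWL ring-width files.

The Tucson format stores one ring-width series per sample ID (at most 8
characters). Each data line carries the ID in the first 8 columns, the
calendar year of the first value on the line, and up to ten integer width
values. A terminal stop marker both ends the series and encodes the
measurement precision:

* ``999``   -- values are hundredths of a millimetre (0.01 mm),
* ``-9999`` -- values are thousandths of a millimetre (0.001 mm).

A width of exactly zero denotes a missing (locally absent) ring and is
preserved as 0.0 mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterator

from .errors import CoverageError, RWLParseError, ValidationError

#: Stop marker -> precision in mm per raw integer unit.
STOP_MARKERS = {999: 0.01, -9999: 0.001}

_MAX_ID_LEN = 8
_VALUES_PER_LINE = 10
_MAX_HEADER_LINES = 3


@dataclass
class RingWidthSeries:
    """One core's dated ring widths in millimetres.

    Parameters
    ----------
    sample_id : str
        Series identifier, non-empty, at most 8 characters (Tucson limit).
    first_year : int
        Calendar year of the innermost (first) ring in ``widths``.
    widths : list of float
        Ring widths in mm, one per consecutive year starting at
        ``first_year``. A value of exactly 0 marks a missing ring.
    precision : float
        Measurement precision in mm (0.01 or 0.001).
    """

    sample_id: str
    first_year: int
    widths: list[float]
    precision: float = 0.01

    def __post_init__(self) -> None:
        if not self.sample_id or len(self.sample_id) > _MAX_ID_LEN:
            raise ValidationError(
                f"sample_id must be 1-{_MAX_ID_LEN} characters, got "
                f"{self.sample_id!r}"
            )
        if self.precision not in (0.01, 0.001):
            raise ValidationError(f"precision must be 0.01 or 0.001 mm, got {self.precision}")
        if any(w < 0 for w in self.widths):
            raise ValidationError(f"negative ring width in series {self.sample_id!r}")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    def __len__(self) -> int:
        return len(self.widths)


@dataclass
class RingWidthCollection:
    """Mapping of sample_id -> :class:`RingWidthSeries` for one site file."""

    series: dict[str, RingWidthSeries] = field(default_factory=dict)

    def add(self, s: RingWidthSeries) -> None:
        if s.sample_id in self.series:
            raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
        self.series[s.sample_id] = s

    def __getitem__(self, sample_id: str) -> RingWidthSeries:
        return self.series[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.series

    def __iter__(self) -> Iterator[RingWidthSeries]:
        return iter(self.series.values())

    def __len__(self) -> int:
        return len(self.series)


def _parse_data_line(line: str) -> tuple[str, int, list[int]]:
    """Split one Tucson data line into (sample_id, year, raw integer values).

    The ID occupies the first 8 columns; the remainder is whitespace-token
    parsed, which tolerates the spacing variants different measurement
    programs emit.
    """
    sample_id = line[:_MAX_ID_LEN].strip()
    tokens = line[_MAX_ID_LEN:].split()
    if not sample_id or not tokens:
        raise ValueError("missing id or year")
    year = int(tokens[0])
    values = [int(t) for t in tokens[1:]]
    return sample_id, year, values


def read_rwl(path: str | Path) -> RingWidthCollection:
    """Read a Tucson RWL file into a :class:`RingWidthCollection`.

    Precision is detected per series from the terminal stop marker
    (999 -> 0.01 mm, -9999 -> 0.001 mm); the marker is stripped and raw
    integers converted to mm. A series that ends without a stop marker
    triggers a warning and is assumed to be in the 0.01 mm dialect.

    Up to three leading lines that do not parse as data are skipped as
    optional Tucson headers.

    Raises
    ------
    RWLParseError
        On a malformed data line (naming its line number), a duplicate
        (series, decade) row, or a gap in the year sequence.
    """
    path = Path(path)
    raw: dict[str, list[int]] = {}
    first_years: dict[str, int] = {}
    next_year: dict[str, int] = {}
    seen_lines: set[tuple[str, int]] = set()
    order: list[str] = []

    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                sample_id, year, values = _parse_data_line(line)
            except ValueError as exc:
                if lineno <= _MAX_HEADER_LINES and not raw:
                    continue  # optional header line
                raise RWLParseError(f"{path.name}:{lineno}: malformed data line ({exc})") from exc
            if len(sample_id) > _MAX_ID_LEN:
                raise RWLParseError(f"{path.name}:{lineno}: sample id longer than 8 characters")
            if (sample_id, year) in seen_lines:
                raise RWLParseError(
                    f"{path.name}:{lineno}: duplicate row for series "
                    f"{sample_id!r} decade {year}"
                )
            seen_lines.add((sample_id, year))
            if sample_id not in raw:
                raw[sample_id] = []
                first_years[sample_id] = year
                order.append(sample_id)
            elif year != next_year[sample_id]:
                raise RWLParseError(
                    f"{path.name}:{lineno}: series {sample_id!r} expected "
                    f"decade year {next_year[sample_id]}, found {year}"
                )
            raw[sample_id].extend(values)
            next_year[sample_id] = first_years[sample_id] + len(raw[sample_id])

    collection = RingWidthCollection()
    for sample_id in order:
        values = raw[sample_id]
        precision = None
        for marker, prec in STOP_MARKERS.items():
            if values and values[-1] == marker:
                precision = prec
                values = values[:-1]
                break
        if precision is None:
            warnings.warn(
                f"series {sample_id!r} in {path.name} has no stop marker; "
                "assuming 0.01 mm precision",
                stacklevel=2,
            )
            precision = 0.01
        bad = [v for v in values if v < 0]
        if bad:
            raise RWLParseError(
                f"{path.name}: series {sample_id!r} contains negative value {bad[0]}"
            )
        widths = [v * precision for v in values]
        collection.add(
            RingWidthSeries(
                sample_id=sample_id,
                first_year=first_years[sample_id],
                widths=widths,
                precision=precision,
            )
        )
    return collection


def _quantize(width_mm: float, precision: float) -> int:
    """Round a width to integer units of ``precision``, half away from zero."""
    q = Decimal(str(precision))
    return int(Decimal(str(width_mm)).quantize(q, rounding=ROUND_HALF_UP) / q)


def write_rwl(
    collection: RingWidthCollection,
    path: str | Path,
    precision: float = 0.01,
) -> None:
    """Write a collection in standard Tucson layout at the given precision.

    Values are emitted as integers in units of ``precision``; the matching
    stop marker (999 for 0.01 mm, -9999 for 0.001 mm) terminates each
    series. Widths that are not exactly representable are rounded half-up
    with a warning.
    """
    if precision not in (0.01, 0.001):
        raise ValidationError(f"precision must be 0.01 or 0.001 mm, got {precision}")
    marker = {v: k for k, v in STOP_MARKERS.items()}[precision]
    path = Path(path)
    lines: list[str] = []
    for series in collection:
        if len(series.sample_id) > _MAX_ID_LEN:
            raise ValidationError(
                f"sample_id {series.sample_id!r} exceeds the Tucson 8-character limit"
            )
        raw = [_quantize(w, precision) for w in series.widths]
        lost = [
            (y, w)
            for y, (w, r) in enumerate(zip(series.widths, raw), start=series.first_year)
            if abs(r * precision - w) > 1e-9
        ]
        if lost:
            warnings.warn(
                f"series {series.sample_id!r}: {len(lost)} width(s) rounded to "
                f"{precision} mm precision (first at year {lost[0][0]})",
                stacklevel=2,
            )
        fields = raw + [marker]
        year = series.first_year
        pos = 0
        while pos < len(fields):
            # first line runs to the end of the calendar decade
            room = _VALUES_PER_LINE - year % 10 if pos == 0 else _VALUES_PER_LINE
            chunk = fields[pos : pos + room]
            lines.append(
                f"{series.sample_id:<8}{year:>4}" + "".join(f"{v:>6d}" for v in chunk)
            )
            year += len(chunk)
            pos += len(chunk)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def series_slice(
    series: RingWidthSeries, first: int, last: int
) -> list[tuple[int, float]]:
    """Return ``[(year, width_mm), ...]`` for the inclusive year range.

    Raises
    ------
    CoverageError
        If any requested year falls outside the series' span; duct years
        must be covered by the ring-width record.
    """
    if first > last:
        raise ValidationError(f"first year {first} after last year {last}")
    missing = [y for y in (first, last) if not series.first_year <= y <= series.last_year]
    if missing:
        raise CoverageError(
            f"series {series.sample_id!r} spans {series.first_year}-"
            f"{series.last_year}; years {first}-{last} not fully covered "
            f"(missing {missing})"
        )
    off = first - series.first_year
    return [(first + i, series.widths[off + i]) for i in range(last - first + 1)]
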