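"""Shared fixtures: measurement-stream builders and an independent
brute-force splitter used as the oracle for year assignment."""

from __future__ import annotations

import pytest

from ductchron.imagej import IN2_TO_MM2, DuctEntry, MeasurementFile


def make_measurement_file(
    areas_mm2: list[float], sample_id: str = "TST01a"
) -> MeasurementFile:
    """Build a MeasurementFile from mm² areas; zeros are sentinels."""
    entries = [
        DuctEntry(
            order_index=i,
            raw_area_in2=a / IN2_TO_MM2,
            area_mm2=a,
            is_sentinel=(a == 0),
        )
        for i, a in enumerate(areas_mm2, start=1)
    ]
    return MeasurementFile(sample_id=sample_id, entries=entries)


def brute_force_split(areas_mm2: list[float], first_year: int):
    """Independent reference splitter: walk the stream once, closing a
    ring at every zero. Returns [(year, [areas]), ...]."""
    rings: list[tuple[int, list[float]]] = []
    current: list[float] = []
    year = first_year
    for a in areas_mm2:
        if a == 0:
            rings.append((year, current))
            current = []
            year += 1
        else:
            current.append(a)
    return rings


@pytest.fixture
def measurement_factory():
    return make_measurement_file


@pytest.fixture
def oracle_split():
    return brute_force_split
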