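"""The five resin-duct defense metrics, per core-year.

Unstandardized metrics describe the ducts alone:

* duct size (mm²) — mean area of all ducts in the ring (NA if none),
* duct production (count · year⁻¹) — number of ducts in the ring,
* total duct area (mm² · year⁻¹) — summed duct area in the ring.

Standardized metrics adjust for growth rate by dividing by ring area,
where ring area = ring width × core width (the sampled strip of the ring
seen on an increment core of constant diameter):

* duct density (count · mm⁻² · year⁻¹) = production / ring area,
* relative duct area (% of annual ring) = 100 × total duct area / ring area.

A missing ring (width 0) has ring area 0; its standardized metrics are
undefined and stored as NA rather than 0 or infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GroupingError, ValidationError
from .rwl_io import RingWidthSeries, series_slice
from .year_assignment import DatedDuctTable

#: Master-chronology column order (also the output CSV contract).
METRIC_COLUMNS = [
    "sample_id",
    "year",
    "duct_size_mm2",
    "duct_production",
    "total_duct_area_mm2",
    "duct_density_per_mm2",
    "relative_duct_area_pct",
    "ring_width_mm",
    "ring_area_mm2",
]

#: The numeric metric fields (plottable / QC-checkable).
NUMERIC_METRICS = METRIC_COLUMNS[2:]


@dataclass(frozen=True)
class CoreGeometry:
    """Core geometry: the average width of the increment core in mm.

    The 5.15 mm increment borer is the common choice; the value enters
    every standardized metric through ring area = ring width × core width.
    """

    core_width: float = 5.15

    def __post_init__(self) -> None:
        if not self.core_width > 0:
            raise ValidationError(f"core_width must be positive, got {self.core_width}")


def unstandardized_metrics(table: DatedDuctTable) -> pd.DataFrame:
    """Per-year duct size, production and total duct area for one core.

    Returns a DataFrame with the first five :data:`METRIC_COLUMNS`;
    standardized columns are added later from ring widths.
    """
    records = []
    for year, areas in zip(table.years, table.rows):
        n = len(areas)
        total = float(np.sum(areas)) if n else 0.0
        records.append(
            {
                "sample_id": table.sample_id,
                "year": year,
                "duct_size_mm2": total / n if n else np.nan,
                "duct_production": n,
                "total_duct_area_mm2": total,
            }
        )
    return pd.DataFrame.from_records(records, columns=METRIC_COLUMNS[:5])


def standardized_metrics(
    rows: pd.DataFrame, series: RingWidthSeries, geometry: CoreGeometry
) -> pd.DataFrame:
    """Add ring width, ring area and the two standardized metrics.

    Every year in ``rows`` must be covered by ``series`` (a
    :class:`~ductchron.errors.CoverageError` propagates otherwise). For
    missing rings (width 0) density and relative area are NA while
    production and total duct area are retained.
    """
    out = rows.copy()
    first, last = int(out["year"].min()), int(out["year"].max())
    widths = dict(series_slice(series, first, last))
    out["ring_width_mm"] = out["year"].map(widths)
    out["ring_area_mm2"] = out["ring_width_mm"] * geometry.core_width
    area = out["ring_area_mm2"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        density = out["duct_production"].to_numpy(dtype=float) / area
        relative = 100.0 * out["total_duct_area_mm2"].to_numpy(dtype=float) / area
    density[area == 0] = np.nan
    relative[area == 0] = np.nan
    out["duct_density_per_mm2"] = density
    out["relative_duct_area_pct"] = relative
    return out[METRIC_COLUMNS]


def combine_cores(
    rows_by_core: dict[str, pd.DataFrame], geometry: CoreGeometry
) -> pd.DataFrame:
    """Add together the cores of one tree (e.g. its A and B cores).

    The core letter is assumed to be the final character of each sample
    ID; all IDs must agree once it is dropped, and the common prefix
    becomes the tree-level sample ID. Per year, duct production, total
    duct area, ring width and ring area are summed over the cores that
    cover that year, and duct size, density and relative area are
    recomputed from the summed quantities — which keeps the
    size × production = total identity exact and reduces zero-duct years,
    the point of taking two cores per tree.
    """
    if len(rows_by_core) < 2:
        raise GroupingError("need at least two cores to combine")
    prefixes = {sid[:-1] for sid in rows_by_core}
    if len(prefixes) != 1 or "" in prefixes:
        raise GroupingError(
            "cores do not share a tree prefix after dropping the final "
            f"(core-letter) character: {sorted(rows_by_core)}"
        )
    tree_id = prefixes.pop()
    stacked = pd.concat(rows_by_core.values(), ignore_index=True)
    grouped = (
        stacked.groupby("year", sort=True)[
            ["duct_production", "total_duct_area_mm2", "ring_width_mm", "ring_area_mm2"]
        ]
        .sum()
        .reset_index()
    )
    prod = grouped["duct_production"].to_numpy(dtype=float)
    total = grouped["total_duct_area_mm2"].to_numpy(dtype=float)
    area = grouped["ring_area_mm2"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        size = np.where(prod > 0, total / prod, np.nan)
        density = prod / area
        relative = 100.0 * total / area
    density[area == 0] = np.nan
    relative[area == 0] = np.nan
    grouped["duct_size_mm2"] = size
    grouped["duct_density_per_mm2"] = density
    grouped["relative_duct_area_pct"] = relative
    grouped["sample_id"] = tree_id
    return grouped[METRIC_COLUMNS]


def core_metrics(
    table: DatedDuctTable, series: RingWidthSeries, geometry: CoreGeometry
) -> pd.DataFrame:
    """Convenience: unstandardized then standardized metrics for one core."""
    return standardized_metrics(unstandardized_metrics(table), series, geometry)
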