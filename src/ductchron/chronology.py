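"""Building and checking the master resin-duct chronology.

Ties the pipeline together: a directory of per-core dated-duct CSVs plus
one Tucson RWL file become a single master table of the five duct metrics
(with ring width and ring area) for every core-year, optionally with A/B
cores of each tree added together. The sample-ID contract is enforced up
front: every duct file's stem must match an RWL series ID exactly
(case-sensitive — core letters are conventionally lowercase).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ContractError, DuctChronError, ValidationError
from .metrics import METRIC_COLUMNS, NUMERIC_METRICS, CoreGeometry, combine_cores, core_metrics
from .rwl_io import RingWidthCollection, read_rwl
from .year_assignment import DatedDuctTable, read_dated_csv, to_frame


@dataclass
class MasterChronology:
    """The compiled chronology: one row per (sample_id, year) plus metadata."""

    rows: pd.DataFrame
    metadata: dict

    def __post_init__(self) -> None:
        if self.rows.duplicated(subset=["sample_id", "year"]).any():
            raise ValidationError("duplicate (sample_id, year) pairs in chronology")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.rows["sample_id"].unique())


def compile_duct_tables(tables: Sequence[DatedDuctTable]) -> pd.DataFrame:
    """Stack per-core dated-duct tables into one long table of duct areas."""
    if not tables:
        raise ValidationError("no dated-duct tables to compile")
    return pd.concat([to_frame(t) for t in tables], ignore_index=True)


def build_master(
    duct_dir: str | Path,
    rwl_path: str | Path,
    geometry: CoreGeometry,
    first_year: int,
    last_year: int,
    combine: bool = False,
) -> MasterChronology:
    """Build the master chronology from dated-duct CSVs and an RWL file.

    Parameters
    ----------
    duct_dir : path
        Directory of per-core dated-duct CSVs (stem = sample ID).
    rwl_path : path
        Tucson RWL file whose series IDs match the CSV stems.
    geometry : CoreGeometry
        Average core width in mm.
    first_year, last_year : int
        Overall bounds of the measured period. Duct years outside the
        bounds are an error — they indicate misalignment to fix at
        source, not data to trim.
    combine : bool
        If True, add A/B cores of each tree together (tree ID = sample
        ID minus its final character).
    """
    duct_dir = Path(duct_dir)
    if first_year > last_year:
        raise ValidationError(f"first_year {first_year} after last_year {last_year}")
    paths = sorted(duct_dir.glob("*.csv"))
    if not paths:
        raise ContractError(f"no dated-duct CSV files found in {duct_dir}")
    stems = [p.stem for p in paths]
    if len(set(stems)) != len(stems):
        dupes = sorted({s for s in stems if stems.count(s) > 1})
        raise ContractError(f"duplicate core files for sample IDs {dupes}")

    collection: RingWidthCollection = read_rwl(rwl_path)
    unmatched = [s for s in stems if s not in collection]
    if unmatched:
        raise ContractError(
            f"duct files with no matching RWL series: {unmatched}; "
            f"available series: {sorted(collection.series)}"
        )

    per_core: dict[str, pd.DataFrame] = {}
    for path in paths:
        table = read_dated_csv(path)
        if table.first_year < first_year or table.last_year > last_year:
            raise ValidationError(
                f"{table.sample_id}: duct years {table.first_year}-"
                f"{table.last_year} fall outside the declared period "
                f"{first_year}-{last_year}"
            )
        per_core[table.sample_id] = core_metrics(
            table, collection[table.sample_id], geometry
        )

    stacked = pd.concat(
        [per_core[s] for s in sorted(per_core)], ignore_index=True
    )
    if combine:
        rows = combine_master(stacked, geometry)
    else:
        rows = (
            stacked.sort_values(["sample_id", "year"], kind="mergesort")
            .reset_index(drop=True)
        )
    metadata = {
        "core_width_mm": geometry.core_width,
        "first_year": first_year,
        "last_year": last_year,
        "combine": combine,
        "duct_dir": str(duct_dir),
        "rwl_path": str(rwl_path),
        "n_cores": len(per_core),
        "n_rows": len(rows),
    }
    return MasterChronology(rows=rows, metadata=metadata)


def combine_master(rows: pd.DataFrame, geometry: CoreGeometry) -> pd.DataFrame:
    """Combine an uncombined (core-level) master table to tree level.

    Cores are grouped by sample ID minus the final (core-letter)
    character; singleton groups keep their values but take the tree ID.
    """
    groups: dict[str, dict[str, pd.DataFrame]] = {}
    for sid, frame in rows.groupby("sample_id"):
        groups.setdefault(sid[:-1], {})[sid] = frame
    frames = [
        combine_cores(cores, geometry) if len(cores) > 1
        else next(iter(cores.values())).assign(sample_id=tree_id)
        for tree_id, cores in sorted(groups.items())
    ]
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["sample_id", "year"], kind="mergesort")
        .reset_index(drop=True)[METRIC_COLUMNS]
    )


def write_master_csv(chron: MasterChronology, path: str | Path) -> None:
    """Write the master chronology CSV (values at 6 significant digits).

    Output is deterministic: stable sort upstream plus fixed rounding
    here means identical inputs give byte-identical files.
    """
    chron.rows[METRIC_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def write_run_log(chron: MasterChronology, path: str | Path, warnings_seen: Sequence[str] = ()) -> None:
    """Write a plain-text audit log of a build (inputs, parameters, warnings)."""
    lines = [
        f"ductchron build log — {datetime.datetime.now().isoformat(timespec='seconds')}",
        "parameters:",
    ]
    lines += [f"  {k}: {v}" for k, v in chron.metadata.items()]
    lines.append(f"warnings: {len(warnings_seen)}")
    lines += [f"  {w}" for w in warnings_seen]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Quality control


@dataclass(frozen=True)
class QCRules:
    """Plausibility bands for QC flagging.

    The duct-size band brackets what a real duct can plausibly measure on
    a sanded core; relative duct area above 100% means the ducts would
    exceed the ring itself. Both point at measurement or alignment errors.
    """

    duct_size_min_mm2: float = 0.001
    duct_size_max_mm2: float = 0.5
    relative_area_max_pct: float = 100.0


@dataclass
class QCFlag:
    sample_id: str
    year: int
    field: str
    value: float
    rule: str


@dataclass
class QCReport:
    """Flags, missing-ring review list and per-core summary statistics."""

    flags: list[QCFlag] = field(default_factory=list)
    missing_rings: list[tuple[str, int]] = field(default_factory=list)
    summary: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.flags

    def to_text(self) -> str:
        lines = [f"QC flags: {len(self.flags)}"]
        lines += [
            f"  {f.sample_id} {f.year} {f.field}={f.value:g}: {f.rule}"
            for f in self.flags
        ]
        lines.append(f"missing rings (for review): {len(self.missing_rings)}")
        lines += [f"  {sid} {year}" for sid, year in self.missing_rings]
        if self.summary is not None:
            lines.append("per-core summary:")
            lines.append(self.summary.to_string())
        return "\n".join(lines)


def qc_checks(chron: MasterChronology, rules: QCRules | None = None) -> QCReport:
    """Flag implausibly large or small values in a master chronology.

    Rules are pure predicates: duct size outside the plausible band,
    relative duct area above 100%, any negative value. Missing rings
    (NA density) are listed for review, not flagged, since they are
    expected in real series. A per-core min/max/mean summary of every
    metric supports the plot-and-eyeball check.
    """
    rules = rules or QCRules()
    report = QCReport()
    for row in chron.rows.itertuples(index=False):
        sid, year = row.sample_id, int(row.year)
        size = row.duct_size_mm2
        if pd.notna(size) and not rules.duct_size_min_mm2 <= size <= rules.duct_size_max_mm2:
            report.flags.append(
                QCFlag(sid, year, "duct_size_mm2", float(size),
                       f"duct size outside plausible band "
                       f"[{rules.duct_size_min_mm2}, {rules.duct_size_max_mm2}] mm²")
            )
        rel = row.relative_duct_area_pct
        if pd.notna(rel) and rel > rules.relative_area_max_pct:
            report.flags.append(
                QCFlag(sid, year, "relative_duct_area_pct", float(rel),
                       f"relative area exceeds {rules.relative_area_max_pct:g}%")
            )
        for col in NUMERIC_METRICS:
            v = getattr(row, col)
            if pd.notna(v) and v < 0:
                report.flags.append(
                    QCFlag(sid, year, col, float(v), "negative value")
                )
        if pd.isna(row.duct_density_per_mm2) and row.ring_width_mm == 0:
            report.missing_rings.append((sid, year))
    report.summary = (
        chron.rows.groupby("sample_id")[NUMERIC_METRICS].agg(["min", "max", "mean"])
    )
    return report


def plot_chronology(
    chron: MasterChronology, metric: str, out: str | Path
) -> None:
    """Write a per-core line plot of one metric over years (NA gaps shown)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if metric not in NUMERIC_METRICS:
        raise DuctChronError(
            f"unknown metric {metric!r}; valid metrics: {NUMERIC_METRICS}"
        )
    if chron.rows.empty:
        raise DuctChronError("nothing to plot: chronology is empty")
    fig, ax = plt.subplots(figsize=(9, 4))
    for sid, grp in chron.rows.groupby("sample_id"):
        ax.plot(grp["year"], grp[metric], marker=".", lw=0.8, label=sid)
    ax.set_xlabel("year")
    ax.set_ylabel(metric)
    ax.legend(fontsize="small", ncol=2)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
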