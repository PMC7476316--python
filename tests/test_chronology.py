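"""Master chronology assembly, QC and plotting."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_measurement_file
from ductchron.chronology import (
    MasterChronology,
    QCRules,
    build_master,
    plot_chronology,
    qc_checks,
    write_master_csv,
)
from ductchron.errors import ContractError, DuctChronError, ValidationError
from ductchron.metrics import METRIC_COLUMNS, CoreGeometry
from ductchron.rwl_io import RingWidthCollection, RingWidthSeries, write_rwl
from ductchron.simulate import CoreParams, emit_site, simulate_core
from ductchron.year_assignment import assign_years, write_dated_csv


def make_site(tmp_path, cores, first_year=1950):
    """cores: {sample_id: (rows, widths)} -> (duct_dir, rwl_path)."""
    duct_dir = tmp_path / "dated"
    duct_dir.mkdir(exist_ok=True)
    coll = RingWidthCollection()
    for sid, (rows, widths) in cores.items():
        stream = []
        for areas in rows:
            stream.extend(areas)
            stream.append(0.0)
        table = assign_years(make_measurement_file(stream, sample_id=sid), first_year)
        write_dated_csv(table, duct_dir / f"{sid}.csv")
        coll.add(RingWidthSeries(sid, first_year, widths))
    rwl = tmp_path / "site.rwl"
    write_rwl(coll, rwl, 0.01)
    return duct_dir, rwl


TWO_CORES = {
    "TREE01Aa": ([[0.2], [], [0.3, 0.1]], [1.0, 2.0, 1.5]),
    "TREE01Ab": ([[0.4], [0.2], []], [1.2, 1.8, 1.1]),
}


class TestBuildMaster:
    def test_two_cores_three_years_gives_six_rows(self, tmp_path):
        duct_dir, rwl = make_site(tmp_path, TWO_CORES)
        chron = build_master(duct_dir, rwl, CoreGeometry(5.15), 1950, 1952)
        assert len(chron.rows) == 6
        assert list(chron.rows.columns) == METRIC_COLUMNS
        assert not chron.rows.duplicated(["sample_id", "year"]).any()

    def test_combine_collapses_to_tree_rows(self, tmp_path):
        duct_dir, rwl = make_site(tmp_path, TWO_CORES)
        chron = build_master(duct_dir, rwl, CoreGeometry(5.15), 1950, 1952, combine=True)
        assert len(chron.rows) == 3
        assert chron.sample_ids == ["TREE01A"]

    def test_unmatched_sample_id_fails_naming_it(self, tmp_path):
        duct_dir, rwl = make_site(tmp_path, TWO_CORES)
        (duct_dir / "XX.csv").write_text(
            "sample_id,year,duct_area_mm2\nXX,1950,0.2\n"
        )
        with pytest.raises(ContractError, match="XX"):
            build_master(duct_dir, rwl, CoreGeometry(5.15), 1950, 1952)

    def test_years_outside_declared_period_rejected(self, tmp_path):
        duct_dir, rwl = make_site(tmp_path, TWO_CORES)
        with pytest.raises(ValidationError, match="outside"):
            build_master(duct_dir, rwl, CoreGeometry(5.15), 1951, 1952)

    def test_end_to_end_duct_conservation(self, tmp_path):
        duct_dir, rwl = make_site(tmp_path, TWO_CORES)
        chron = build_master(duct_dir, rwl, CoreGeometry(5.15), 1950, 1952)
        n_input_ducts = sum(
            sum(len(r) for r in rows) for rows, _ in TWO_CORES.values()
        )
        assert chron.rows["duct_production"].sum() == n_input_ducts

    def test_master_csv_is_deterministic(self, tmp_path):
        duct_dir, rwl = make_site(tmp_path, TWO_CORES)
        outs = []
        for name in ("a.csv", "b.csv"):
            chron = build_master(duct_dir, rwl, CoreGeometry(5.15), 1950, 1952)
            write_master_csv(chron, tmp_path / name)
            outs.append((tmp_path / name).read_bytes())
        assert outs[0] == outs[1]

    def test_rebuild_from_emitted_csvs_is_idempotent(self, tmp_path):
        duct_dir, rwl = make_site(tmp_path, TWO_CORES)
        a = build_master(duct_dir, rwl, CoreGeometry(5.15), 1950, 1952)
        b = build_master(duct_dir, rwl, CoreGeometry(5.15), 1950, 1952)
        pd.testing.assert_frame_equal(a.rows, b.rows)


class TestQC:
    def chron_with(self, **overrides):
        base = {
            "sample_id": "TST01a", "year": 1950, "duct_size_mm2": 0.05,
            "duct_production": 2, "total_duct_area_mm2": 0.1,
            "duct_density_per_mm2": 0.2, "relative_duct_area_pct": 1.0,
            "ring_width_mm": 1.0, "ring_area_mm2": 5.15,
        }
        base.update(overrides)
        return MasterChronology(rows=pd.DataFrame([base]), metadata={})

    def test_relative_area_above_100_flagged(self):
        report = qc_checks(self.chron_with(relative_duct_area_pct=120.0))
        assert any("exceeds 100" in f.rule for f in report.flags)

    def test_duct_size_outside_band_flagged(self):
        report = qc_checks(self.chron_with(duct_size_mm2=0.9))
        assert any(f.field == "duct_size_mm2" for f in report.flags)

    def test_negative_value_flagged(self):
        report = qc_checks(self.chron_with(total_duct_area_mm2=-0.1))
        assert any(f.rule == "negative value" for f in report.flags)

    def test_missing_ring_listed_for_review_not_flagged(self):
        report = qc_checks(
            self.chron_with(
                ring_width_mm=0.0, ring_area_mm2=0.0,
                duct_density_per_mm2=np.nan, relative_duct_area_pct=np.nan,
                duct_size_mm2=np.nan, duct_production=0, total_duct_area_mm2=0.0,
            )
        )
        assert report.ok
        assert report.missing_rings == [("TST01a", 1950)]

    def test_clean_synthetic_chronology_has_no_flags(self, tmp_path):
        truths = [
            simulate_core(CoreParams(n_years=40), seed, sample_id=f"SYN00{seed}a")
            for seed in (1, 2)
        ]
        _, rwl = emit_site(truths, tmp_path)
        duct_dir = tmp_path / "dated"
        duct_dir.mkdir()
        from ductchron.imagej import read_measurements
        for t in truths:
            mf = read_measurements(tmp_path / f"{t.sample_id}.txt")
            write_dated_csv(assign_years(mf, t.first_year), duct_dir / f"{t.sample_id}.csv")
        chron = build_master(duct_dir, rwl, CoreGeometry(5.15), 1940, truths[0].last_year)
        assert qc_checks(chron).ok

    def test_configurable_band(self):
        report = qc_checks(
            self.chron_with(duct_size_mm2=0.05),
            QCRules(duct_size_min_mm2=0.1, duct_size_max_mm2=0.2),
        )
        assert not report.ok


class TestPlot:
    def chron(self, tmp_path):
        duct_dir, rwl = make_site(tmp_path, TWO_CORES)
        return build_master(duct_dir, rwl, CoreGeometry(5.15), 1950, 1952)

    def test_writes_png(self, tmp_path):
        out = tmp_path / "plot.png"
        plot_chronology(self.chron(tmp_path), "duct_density_per_mm2", out)
        assert out.exists() and out.stat().st_size > 0

    def test_unknown_metric_lists_valid_fields(self, tmp_path):
        with pytest.raises(DuctChronError, match="duct_density_per_mm2"):
            plot_chronology(self.chron(tmp_path), "colour", tmp_path / "x.png")

    def test_empty_chronology_rejected(self, tmp_path):
        empty = MasterChronology(rows=pd.DataFrame(columns=METRIC_COLUMNS), metadata={})
        with pytest.raises(DuctChronError, match="nothing to plot"):
            plot_chronology(empty, "duct_size_mm2", tmp_path / "x.png")
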