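"""Census data model, stem aggregation, and file round trips."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings, strategies as st

from forestdyn.census import CensusRegistry, Observation, Status, TreeRecord
from forestdyn.errors import (
    FormatError,
    IntegrityError,
    InvalidMeasurementError,
)
from forestdyn.io import read_census_csv, read_dwca, write_census_csv, write_dwca
from forestdyn.measures import aggregate_stem_dbh, basal_area_m2
from forestdyn.simulate import SimulationParams, simulate_stand


class TestStemAggregation:
    @pytest.mark.parametrize(
        "stems, expected",
        [
            ([3, 4], 5.0),            # 3-4-5 right triangle
            ([7.2], 7.2),             # single stem unchanged
            ([5, 5, 5], math.sqrt(75)),
        ],
    )
    def test_examples(self, stems, expected):
        assert aggregate_stem_dbh(stems) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("bad", [[], [0.0], [5, -1], [float("nan")]])
    def test_invalid(self, bad):
        with pytest.raises(InvalidMeasurementError):
            aggregate_stem_dbh(bad)

    @given(st.lists(st.floats(0.1, 200.0), min_size=1, max_size=8))
    @settings(deadline=None)
    def test_permutation_invariant_and_dominates_max(self, stems):
        agg = aggregate_stem_dbh(stems)
        assert agg == pytest.approx(aggregate_stem_dbh(sorted(stems)), rel=1e-12)
        assert agg >= max(stems) - 1e-12

    def test_aggregate_preserves_total_basal_area(self):
        stems = [6.0, 9.0, 4.0]
        assert basal_area_m2(aggregate_stem_dbh(stems)) == pytest.approx(
            sum(basal_area_m2(d) for d in stems), rel=1e-12
        )


class TestBasalArea:
    def test_known_values(self):
        assert basal_area_m2(10) == pytest.approx(math.pi * 0.05**2, rel=1e-9)
        assert basal_area_m2(200 / math.sqrt(math.pi)) == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("bad", [0, -3.0, float("inf")])
    def test_invalid(self, bad):
        with pytest.raises(InvalidMeasurementError):
            basal_area_m2(bad)


class TestLifeCourse:
    def test_dead_cannot_revive(self):
        rec = TreeRecord("X", "Sp", "P1", "S")
        rec.observations["a"] = Observation(Status.ALIVE, 6.0)
        rec.observations["b"] = Observation(Status.DEAD)
        rec.observations["c"] = Observation(Status.ALIVE, 6.0)
        with pytest.raises(IntegrityError):
            rec.validate(["a", "b", "c"], 4.99)

    def test_alive_requires_dbh(self):
        rec = TreeRecord("X", "Sp", "P1", "S")
        rec.observations["a"] = Observation(Status.ALIVE, None)
        with pytest.raises(InvalidMeasurementError):
            rec.validate(["a"], 4.99)

    def test_stems_must_match_aggregate(self):
        from forestdyn.census import StemMeasurement

        rec = TreeRecord("X", "Sp", "P1", "S")
        stems = (StemMeasurement("X", 3.0), StemMeasurement("X", 4.0))
        rec.observations["a"] = Observation(Status.ALIVE, 6.0, stems)  # aggregate is 5
        with pytest.raises(InvalidMeasurementError):
            rec.validate(["a"], 4.99)

    def test_snapshot_filters_below_threshold(self, caplog):
        registry = CensusRegistry("S", {"a": 2000}, n_plots=1, plot_area_m2=300)
        ok = TreeRecord("T1", "Sp", "P1", "S")
        ok.observations["a"] = Observation(Status.ALIVE, 6.0)
        small = TreeRecord("T2", "Sp", "P1", "S")
        small.observations["a"] = Observation(Status.ALIVE, 3.0)
        registry.add(ok)
        registry.add(small)
        snap = registry.snapshot("a")
        assert snap.n_trees == 1
        assert snap.trees[0].tree_id == "T1"


class TestCsvRoundTrip:
    def test_round_trip_identity(self, sim_registry, tmp_path):
        path = tmp_path / "census.csv"
        write_census_csv(sim_registry, path)
        back = read_census_csv(path, plot_area_m2=sim_registry.plot_area_m2,
                               n_plots=sim_registry.n_plots)
        assert back.censuses == sim_registry.censuses
        assert set(back.trees) == set(sim_registry.trees)
        for tid, rec in sim_registry.trees.items():
            rb = back.trees[tid]
            assert rb.species == rec.species and rb.plot_id == rec.plot_id
            for label in sim_registry.censuses:
                assert rb.status_at(label) == rec.status_at(label)
                a, b = rec.dbh_at(label), rb.dbh_at(label)
                if a is None:
                    assert b is None
                else:  # >= 6 significant digits preserved
                    assert b == pytest.approx(a, rel=1e-6)

    def test_empty_table(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "stand_id,plot_id,tree_id,species,census_label,census_year,status,dbh_cm\n"
        )
        registry = read_census_csv(path)
        assert registry.trees == {}

    def test_unknown_status_token(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "stand_id,plot_id,tree_id,species,census_label,census_year,status,dbh_cm\n"
            "S,P1,T1,Sp,c0,2000,zombie,6.0\n"
        )
        with pytest.raises(FormatError):
            read_census_csv(path)

    def test_duplicate_tree_census_row(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "stand_id,plot_id,tree_id,species,census_label,census_year,status,dbh_cm\n"
            "S,P1,T1,Sp,c0,2000,alive,6.0\n"
            "S,P1,T1,Sp,c0,2000,alive,7.0\n"
        )
        with pytest.raises(IntegrityError):
            read_census_csv(path)

    def test_alive_without_dbh(self, tmp_path):
        path = tmp_path / "nodbh.csv"
        path.write_text(
            "stand_id,plot_id,tree_id,species,census_label,census_year,status,dbh_cm\n"
            "S,P1,T1,Sp,c0,2000,alive,\n"
        )
        with pytest.raises(IntegrityError):
            read_census_csv(path)


@pytest.fixture(scope="module")
def archive(tmp_path_factory):
    registry = simulate_stand(
        SimulationParams(n_initial_trees=80, n_plots=4, census_years=(0, 5), seed=11)
    )
    directory = tmp_path_factory.mktemp("dwca") / "archive"
    write_dwca(registry, directory)
    return registry, directory


class TestDwca:
    def test_round_trip_counts_and_dbh(self, archive):
        registry, directory = archive
        back = read_dwca(directory, n_plots=registry.n_plots, stand_id=registry.stand_id)
        assert len(back.trees) == len(registry.trees)
        assert list(back.censuses.values()) == list(registry.censuses.values())
        # census labels differ (years vs c-labels); align by order
        orig_labels = registry.census_order
        back_labels = back.census_order
        for tid, rec in registry.trees.items():
            rb = back.trees[tid]
            assert rb.species == rec.species
            for la, lb in zip(orig_labels, back_labels):
                assert rb.status_at(lb) == rec.status_at(la)
                a, b = rec.dbh_at(la), rb.dbh_at(lb)
                if a is not None and rec.status_at(la) == "alive":
                    assert b == pytest.approx(a, rel=1e-6)

    def test_csv_after_dwca_round_trips(self, archive, tmp_path):
        _, directory = archive
        back = read_dwca(directory)
        path = tmp_path / "via_dwca.csv"
        write_census_csv(back, path)
        again = read_census_csv(path, n_plots=back.n_plots)
        assert set(again.trees) == set(back.trees)

    def test_small_archive_shape(self, tmp_path):
        """3 occurrences over 2 censuses -> 2 trees tracked, 2 censuses."""
        specs = [
            ("A1", "Sp one", [6.0, 6.5]),
            ("A2", "Sp two", [7.0, "dead"]),
        ]
        from tests.conftest import build_registry

        registry = build_registry(specs, {"c0": 2000, "c1": 2005})
        directory = tmp_path / "tiny"
        write_dwca(registry, directory)
        back = read_dwca(directory)
        assert len(back.trees) == 2
        assert len(back.censuses) == 2

    def test_missing_measurement_file_is_format_error(self, archive, tmp_path):
        _, directory = archive
        import shutil

        broken = tmp_path / "broken"
        shutil.copytree(directory, broken)
        (broken / "measurementorfact.txt").unlink()
        with pytest.raises(FormatError):
            read_dwca(broken)

    def test_missing_meta_is_format_error(self, tmp_path):
        empty = tmp_path / "nothing"
        empty.mkdir()
        with pytest.raises(FormatError):
            read_dwca(empty)

    def test_duplicate_occurrence_is_integrity_error(self, tmp_path):
        from tests.conftest import build_registry

        registry = build_registry([("A1", "Sp", [6.0])], {"c0": 2000})
        directory = tmp_path / "dup"
        write_dwca(registry, directory)
        occ = directory / "occurrence.txt"
        lines = occ.read_text().splitlines()
        occ.write_text("\n".join(lines + [lines[-1]]) + "\n")
        mof = directory / "measurementorfact.txt"
        mof_lines = mof.read_text().splitlines()
        mof.write_text("\n".join(mof_lines + [mof_lines[-1]]) + "\n")
        with pytest.raises(IntegrityError):
            read_dwca(directory)

    def test_bad_event_date_skipped_with_warning(self, tmp_path, caplog):
        from tests.conftest import build_registry

        registry = build_registry(
            [("A1", "Sp", [6.0, 6.5]), ("A2", "Sp", [7.0, 7.5])], {"c0": 2000, "c1": 2005}
        )
        directory = tmp_path / "baddate"
        write_dwca(registry, directory)
        occ = directory / "occurrence.txt"
        text = occ.read_text().replace("2005", "????", 1)
        occ.write_text(text)
        with caplog.at_level("WARNING"):
            back = read_dwca(directory, validate=False)
        assert "eventDate" in caplog.text
        # the corrupted row is dropped, others survive
        total_obs = sum(len(r.observations) for r in back.trees.values())
        assert total_obs == 3
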