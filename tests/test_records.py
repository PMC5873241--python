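"""Record model, CSV round-trip, and the inclusion/exclusion filters."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dietspec import (
    CellSelection,
    PreyRecord,
    build_diet_matrix,
    extract_sizes,
    filter_cells,
    read_records,
    write_records,
)
from conftest import rec


class TestCsvRoundTrip:
    def test_full_records_round_trip(self, tmp_path):
        records = [
            rec("F01", "C1", fam="Araneidae", gen="Neoscona",
                guild="orb-weaver", bl=5.2, cw=1.4),
            rec("F01", "C2", fam="Salticidae", gen="Phidippus",
                guild="stalker", bl=4.0, cw=1.1, damaged=True),
            rec("F02", "C1", fam=None, unident=True),
        ]
        path = tmp_path / "records.csv"
        write_records(records, path)
        assert read_records(path) == records

    def test_blank_genus_with_unidentifiable_flag_reads_as_missing(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "individual_id,cell_id,family,genus,genus_unidentifiable\n"
            "F01,C1,Araneidae,,true\n"
        )
        (record,) = read_records(path)
        assert record.genus is None and record.genus_unidentifiable

    def test_negative_size_raises_with_row_number(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "individual_id,cell_id,family,body_length_mm\n"
            "F01,C1,Araneidae,5.0\nF01,C1,Araneidae,-1\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_records(path)

    def test_custom_dialect_maps_headers(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("wasp,chamber,fam\nF01,C1,Araneidae\n")
        (record,) = read_records(
            path,
            dialect={"individual_id": "wasp", "cell_id": "chamber",
                     "family": "fam"},
        )
        assert record.individual_id == "F01" and record.family == "Araneidae"


class TestRecordInvariants:
    def test_unidentifiable_flag_forces_genus_missing(self):
        r = PreyRecord("F01", "C1", family="Araneidae", genus="Neoscona",
                       genus_unidentifiable=True)
        assert r.genus is None

    def test_missing_family_without_flag_rejected(self):
        with pytest.raises(ValueError, match="family"):
            PreyRecord("F01", "C1", family=None)

    @pytest.mark.parametrize("attr", ["body_length_mm", "carapace_width_mm"])
    def test_nonpositive_sizes_rejected(self, attr):
        with pytest.raises(ValueError, match="positive"):
            PreyRecord("F01", "C1", family="Araneidae", **{attr: 0.0})


def _cells(sizes_by_cell, ind="F01"):
    return [
        rec(ind, cell)
        for cell, n in sizes_by_cell.items()
        for _ in range(n)
    ]


class TestFilterCells:
    def test_small_cells_dropped(self):
        records = _cells({"C1": 4, "C2": 6, "C3": 7})
        kept = filter_cells(records, CellSelection(seed=0))
        assert {r.cell_id for r in kept} == {"C2", "C3"}

    def test_random_subsample_is_deterministic_given_seed(self):
        records = _cells({f"C{i}": 6 for i in range(1, 6)})
        selection = CellSelection(max_cells_per_individual=3, seed=11)
        first = filter_cells(records, selection)
        second = filter_cells(records, selection)
        assert len({r.cell_id for r in first}) == 3
        assert first == second

    def test_all_cells_below_threshold_removes_individual(self):
        records = _cells({"C1": 2, "C2": 3})
        assert filter_cells(records, CellSelection(seed=0)) == []

    def test_idempotent(self):
        records = _cells({f"C{i}": 6 for i in range(1, 6)}) + _cells(
            {"C1": 4, "C2": 9}, ind="F02"
        )
        selection = CellSelection(seed=3)
        once = filter_cells(records, selection)
        assert filter_cells(once, selection) == once

    def test_provenance_records_drops(self):
        records = _cells({f"C{i}": 6 for i in range(1, 6)}) + _cells(
            {"C9": 2}, ind="F02"
        )
        kept, prov = filter_cells(
            records, CellSelection(seed=0), with_provenance=True
        )
        assert prov["cells_dropped_below_min_items"] == {"F02": ["C9"]}
        assert len(prov["cells_dropped_by_random_subsample"]["F01"]) == 2


class TestBuildDietMatrix:
    def test_direct_tabulation(self):
        records = [rec("F01", fam="A")] * 3 + [rec("F02", fam="A"),
                                               rec("F02", fam="B")]
        diet = build_diet_matrix(records, "family")
        assert diet.resource_labels == ("A", "B")
        assert diet.counts.tolist() == [[3, 0], [1, 1]]

    def test_unidentifiable_excluded_at_genus_level_only(self):
        records = [
            rec("F01", gen="Neoscona"),
            rec("F01", fam="Araneidae", unident=True),
            rec("F02", gen="Leucauge"),
        ]
        genus = build_diet_matrix(records, "genus")
        family = build_diet_matrix(records, "family")
        assert genus.counts.sum() == 2
        assert family.counts.sum() == 3

    def test_single_shared_taxon_gives_one_column(self):
        records = [rec("F01", fam="A"), rec("F02", fam="A")]
        diet = build_diet_matrix(records, "family")
        assert diet.n_resources == 1

    def test_missing_guild_records_dropped_with_warning(self, caplog):
        records = [rec("F01", guild="orb-weaver"), rec("F01"), rec("F02", guild="orb-weaver")]
        with caplog.at_level("WARNING"):
            diet = build_diet_matrix(records, "guild")
        assert diet.counts.sum() == 2
        assert "dropped 1" in caplog.text

    def test_no_usable_records_raises(self):
        with pytest.raises(ValueError, match="no usable records"):
            build_diet_matrix([rec("F01", fam="A")], "guild")

    @given(
        st.lists(
            st.tuples(st.integers(0, 3), st.sampled_from("ABCD")),
            min_size=1,
            max_size=30,
        )
    )
    def test_count_conservation_and_column_bound(self, items):
        records = [rec(f"F{i:02d}", fam=fam) for i, fam in items]
        diet = build_diet_matrix(records, "family")
        assert diet.counts.sum() == len(records)
        assert diet.n_resources <= len({fam for _, fam in items})
        assert (diet.row_totals() >= 1).all()


class TestExtractSizes:
    def test_damaged_specimens_excluded(self):
        records = [
            rec("F01", bl=3.0),
            rec("F01", bl=4.0),
            rec("F01", bl=5.0, damaged=True),
        ]
        assert extract_sizes(records, "body_length") == {"F01": [3.0, 4.0]}

    def test_all_damaged_yields_empty_with_warning(self, caplog):
        records = [rec("F01", bl=3.0, damaged=True)]
        with caplog.at_level("WARNING"):
            out = extract_sizes(records, "body_length")
        assert out == {}
        assert "no usable sizes" in caplog.text

    def test_filtering_is_per_measure(self):
        records = [rec("F01", bl=None, cw=1.2), rec("F02", bl=3.3, cw=None)]
        assert extract_sizes(records, "carapace_width") == {"F01": [1.2]}
        assert extract_sizes(records, "body_length") == {"F02": [3.3]}
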