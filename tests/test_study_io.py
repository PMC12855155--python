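import numpy as np
import pandas as pd
import pytest

from rumencm import study_io
from rumencm.study_io import (CountMatrix, EmptySliceError, FormatError,
                              InsufficientReplicationError, SampleMetadata,
                              SliceSpec, TaxonomyTable, ValidationError,
                              normalize_timepoint, read_count_matrix,
                              read_sample_metadata, read_taxonomy,
                              slice_group_timepoint, write_count_matrix,
                              write_sample_metadata, write_taxonomy)


class TestCountMatrixIO:
    def test_read_small_matrix_sums(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("sgb_id\tS1\tS2\nsgb1\t2\t3\nsgb2\t0\t5\n")
        cm = read_count_matrix(path)
        assert cm.counts.sum(axis=1).tolist() == [5, 5]
        assert cm.counts.sum(axis=0).tolist() == [2, 8]
        assert cm.sgb_ids == ["sgb1", "sgb2"]

    def test_header_only_gives_zero_sgbs(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("sgb_id\tS1\tS2\n")
        cm = read_count_matrix(path)
        assert cm.n_sgb == 0 and cm.sample_ids == ["S1", "S2"]

    def test_non_integer_cell_names_position(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("sgb_id\tS1\tS2\nsgb1\t1\t3.7\n")
        with pytest.raises(FormatError, match=r"row 1, col 2"):
            read_count_matrix(path)

    def test_negative_cell_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("sgb_id\tS1\nsgb1\t-2\n")
        with pytest.raises(FormatError, match="negative"):
            read_count_matrix(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate SGB"):
            CountMatrix(["a", "a"], ["S1"], np.zeros((2, 1), dtype=int))
        with pytest.raises(ValidationError, match="duplicate sample"):
            CountMatrix(["a"], ["S1", "S1"], np.zeros((1, 2), dtype=int))

    def test_round_trip_preserves_counts_and_order(self, tmp_path):
        rng = np.random.default_rng(3)
        cm = CountMatrix([f"g{i}" for i in range(5)],
                         [f"s{j}" for j in range(4)],
                         rng.integers(0, 100, (5, 4)))
        path = tmp_path / "rt.tsv"
        write_count_matrix(cm, path)
        back = read_count_matrix(path)
        assert back.sgb_ids == cm.sgb_ids
        assert back.sample_ids == cm.sample_ids
        np.testing.assert_array_equal(back.counts, cm.counts)


class TestMetadata:
    def test_read_single_record(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("sample_id,animal_id,diet,fe_group,timepoint\nS1,A1,F,HFE,D1\n")
        md = read_sample_metadata(path)
        assert md.table.loc["S1", "diet"] == "F"
        assert md.table.loc["S1", "timepoint"] == "D1"

    def test_unknown_diet_level_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("sample_id,animal_id,diet,fe_group,timepoint\nS1,A1,silage,HFE,D1\n")
        with pytest.raises(ValidationError, match="diet"):
            read_sample_metadata(path)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "sample_id,animal_id,diet,fe_group,timepoint\n"
            "S1,A1,F,HFE,D1\nS1,A2,F,HFE,D80\n")
        with pytest.raises(ValidationError, match="duplicate sample_id"):
            read_sample_metadata(path)

    def test_duplicate_animal_timepoint_rejected(self):
        df = pd.DataFrame({
            "animal_id": ["A1", "A1"], "diet": ["F", "F"],
            "fe_group": ["HFE", "HFE"], "timepoint": ["D1", "D1"],
        }, index=["S1", "S2"])
        with pytest.raises(ValidationError, match="animal_id, timepoint"):
            SampleMetadata(df)

    @pytest.mark.parametrize("token,expected", [
        ("D80", "D80"), ("Day 80", "D80"), ("day1", "D1"), ("180", "D180")])
    def test_timepoint_normalization(self, token, expected):
        assert normalize_timepoint(token) == expected

    def test_unknown_timepoint_rejected(self):
        with pytest.raises(ValidationError):
            normalize_timepoint("D42")

    def test_metadata_round_trip(self, tmp_path, design_metadata):
        path = tmp_path / "m.csv"
        write_sample_metadata(design_metadata, path)
        back = read_sample_metadata(path)
        pd.testing.assert_frame_equal(back.table, design_metadata.table)


class TestTaxonomy:
    def test_genus_extraction(self):
        tax = TaxonomyTable({
            "s1": "d__Bacteria;p__X;c__Y;o__Z;f__W;g__Fibrobacter;s__F sp",
            "s2": "d__Bacteria;p__X",  # missing tail ranks allowed
        })
        assert tax.genus["s1"] == "Fibrobacter"
        assert tax.genus["s2"] == ""
        assert tax.sgbs_in_genus("g__Fibrobacter") == ["s1"]
        assert tax.sgbs_in_genus("Fibrobacter") == ["s1"]

    def test_too_many_ranks_rejected(self):
        with pytest.raises(ValidationError, match="ranks"):
            TaxonomyTable({"s1": ";".join("x" * 8)})

    def test_taxonomy_round_trip(self, tmp_path):
        tax = TaxonomyTable({"s1": "d__B;p__P;c__C;o__O;f__F;g__G;s__S"})
        path = tmp_path / "t.tsv"
        write_taxonomy(tax, path)
        assert read_taxonomy(path).lineages == tax.lineages


class TestSlicing:
    @pytest.fixture
    def full_matrix(self, design_metadata):
        rng = np.random.default_rng(0)
        samples = design_metadata.sample_ids
        return CountMatrix([f"g{i}" for i in range(6)], samples,
                           rng.integers(0, 50, (6, len(samples))))

    def test_slice_returns_ten_columns(self, full_matrix, design_metadata):
        sl = slice_group_timepoint(full_matrix, design_metadata,
                                   SliceSpec("HFE", "D80"))
        assert sl.n_samples == 10
        assert all(s.startswith("HFE") and s.endswith("D80")
                   for s in sl.sample_ids)

    def test_slice_column_sums_match_parent(self, full_matrix, design_metadata):
        sl = slice_group_timepoint(full_matrix, design_metadata,
                                   SliceSpec("LFE", "D100"))
        parent = full_matrix.to_frame()
        for s in sl.sample_ids:
            assert sl.to_frame()[s].sum() == parent[s].sum()

    def test_slice_idempotent(self, full_matrix, design_metadata):
        spec = SliceSpec("HFE", "D1")
        once = slice_group_timepoint(full_matrix, design_metadata, spec)
        twice = slice_group_timepoint(once, design_metadata, spec)
        assert once.sample_ids == twice.sample_ids
        np.testing.assert_array_equal(once.counts, twice.counts)

    def test_canonical_slices_partition_samples(self, full_matrix,
                                                design_metadata):
        seen: list[str] = []
        for spec in study_io.canonical_slices(design_metadata):
            seen += slice_group_timepoint(full_matrix, design_metadata,
                                          spec).sample_ids
        assert sorted(seen) == sorted(design_metadata.sample_ids)

    def test_empty_slice_raises(self, design_metadata):
        cm = CountMatrix(["g0"], ["orphan"], np.array([[1]]))
        with pytest.raises(EmptySliceError):
            slice_group_timepoint(cm, design_metadata, SliceSpec("HFE", "D1"))

    def test_single_sample_raises(self, design_metadata):
        cm = CountMatrix(["g0"], ["HFE_A00_D1"], np.array([[1]]))
        with pytest.raises(InsufficientReplicationError):
            slice_group_timepoint(cm, design_metadata, SliceSpec("HFE", "D1"))

    def test_all_zero_rows_kept_at_slice_time(self, full_matrix,
                                              design_metadata):
        counts = full_matrix.counts.copy()
        counts[2, :] = 0
        cm = CountMatrix(full_matrix.sgb_ids, full_matrix.sample_ids, counts)
        sl = slice_group_timepoint(cm, design_metadata, SliceSpec("HFE", "D1"))
        assert sl.n_sgb == cm.n_sgb
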