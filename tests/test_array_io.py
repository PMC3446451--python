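import numpy as np
import pandas as pd
import pytest

from seroarray import array_io
from seroarray.array_io import (
    ArrayDesign,
    ArrayIOError,
    load_table1_fixture,
    load_table2_fixture,
    read_design,
    read_spot_table,
    read_spot_table_mapped,
    write_design,
    write_spot_table,
)
from seroarray.synthetic import make_design


def design_df(rows):
    return pd.DataFrame(
        rows, columns=["feature_id", "feature_class", "replicate_index", "block", "row", "col"]
    )


class TestArrayDesign:
    def test_default_synthetic_design_has_768_duplicated_antigens(self, tmp_path):
        design = make_design(768)
        write_design(design, tmp_path / "design.tsv")
        loaded = read_design(tmp_path / "design.tsv")
        assert loaded.n_antigens == 768
        ant = loaded.features[loaded.features["feature_class"] == "antigen"]
        assert (ant["feature_id"].value_counts() == 2).all()
        assert loaded.qc_warnings == []

    def test_minimal_design_warns_on_single_replicate(self):
        with pytest.warns(UserWarning, match="expected 2"):
            design = ArrayDesign(
                design_df([("A", "antigen", 0, 0, 0, 0), ("NS", "nonspot", 0, 0, 0, 1)])
            )
        assert len(design.qc_warnings) == 1

    def test_duplicate_position_rejected(self):
        with pytest.raises(ArrayIOError, match="duplicate grid positions"):
            ArrayDesign(
                design_df(
                    [
                        ("A", "antigen", 0, 0, 0, 0),
                        ("B", "antigen", 0, 0, 0, 0),
                        ("NS", "nonspot", 0, 0, 0, 1),
                    ]
                )
            )

    def test_design_without_nonspots_rejected(self):
        with pytest.raises(ArrayIOError, match="nonspot"):
            ArrayDesign(
                design_df([("A", "antigen", 0, 0, 0, 0), ("A", "antigen", 1, 0, 0, 1)])
            )


class TestSpotTable:
    def test_round_trip_is_identity(self, small_sim, tmp_path):
        table = small_sim.arrays[0]
        path = tmp_path / f"{table.sample_id}.tsv"
        write_spot_table(table, path)
        loaded = read_spot_table(path, small_sim.design)
        assert loaded.sample_id == table.sample_id
        a = table.data.sort_values(["block", "row", "col"]).reset_index(drop=True)
        b = loaded.data.sort_values(["block", "row", "col"]).reset_index(drop=True)
        assert np.array_equal(a["raw_volume"].to_numpy(), b["raw_volume"].to_numpy())
        assert (a[["block", "row", "col"]].to_numpy() == b[["block", "row", "col"]].to_numpy()).all()

    def test_orphan_row_names_position(self, small_sim, tmp_path):
        table = small_sim.arrays[0]
        path = tmp_path / "spots.tsv"
        write_spot_table(table, path)
        extra = table.data.iloc[[0]].assign(block=99)
        df = pd.concat([table.data, extra])
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ArrayIOError, match=r"not in design.*\(99,"):
            read_spot_table(path, small_sim.design)

    def test_missing_positions_reported(self, small_sim, tmp_path):
        table = small_sim.arrays[0]
        path = tmp_path / "spots.tsv"
        table.data.iloc[1:].to_csv(path, sep="\t", index=False)
        with pytest.raises(ArrayIOError, match="missing from spot table"):
            read_spot_table(path, small_sim.design)

    def test_negative_volume_rejected(self, small_sim, tmp_path):
        table = small_sim.arrays[0]
        df = table.data.copy()
        df.loc[df.index[0], "raw_volume"] = -1.0
        path = tmp_path / "spots.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ArrayIOError, match="negative raw volume"):
            read_spot_table(path, small_sim.design)

    def test_quantification_export_adapter_maps_columns(self, small_sim, tmp_path):
        table = small_sim.arrays[0]
        export = table.data.rename(
            columns={"block": "Block", "row": "Row", "col": "Column", "raw_volume": "Volume"}
        )[["Block", "Row", "Column", "Volume"]]
        path = tmp_path / "export.tsv"
        export.to_csv(path, sep="\t", index=False)
        loaded = read_spot_table_mapped(
            path,
            small_sim.design,
            {"Block": "block", "Row": "row", "Column": "col", "Volume": "raw_volume"},
            sample_id="X",
        )
        assert len(loaded.data) == len(table.data)


class TestFixtures:
    def test_differential_list_has_36_entries(self):
        df = load_table1_fixture()
        assert len(df) == 36

    def test_category_tallies(self):
        df = load_table1_fixture()
        counts = df["category"].value_counts()
        assert counts["pl_higher"] == 29
        assert counts["similar"] == 6
        assert df.loc[df["category"] == "sf_higher", "gene"].tolist() == ["ACTN1"]

    def test_demographics_values(self):
        meta = load_table2_fixture()
        assert len(meta) == 10
        assert [m.patient_id for m in meta] == [
            "O1", "O2", "O3", "E1", "E2", "E3", "P1", "P2", "P3", "P4",
        ]
        p2 = {m.patient_id: m for m in meta}["P2"]
        assert (p2.esr_mm_hr, p2.crp_mg_l, p2.rf) == (110.0, 72.0, 231.0)
        ana_pos = {m.patient_id for m in meta if m.ana_titer != "Negative"}
        assert ana_pos == {"O1", "O2", "E1", "P4"}

    def test_loaders_pure_and_checksums_pinned(self):
        assert (
            array_io.fixture_sha256("table1_differential_antibodies.tsv")
            == "1912908869ba7f7d03aff48d1a71b0caf2015446ae65a3b8ffadd59950b83ce1"
        )
        assert (
            array_io.fixture_sha256("table2_patient_demographics.tsv")
            == "6478c08ba297febe45837b32eef75a8c1d5658df08c77ed5041c2df4f58070ed"
        )
        pd.testing.assert_frame_equal(load_table1_fixture(), load_table1_fixture())
        assert load_table2_fixture() == load_table2_fixture()
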