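import numpy as np
import pytest

from pfbs import FeatureTable, load_feature_table, save_feature_table, subset_features
from pfbs.errors import ConfigurationError, DataError


class TestLoadRoundTrip:
    def test_write_read_round_trip(self, tiny_table, tmp_path):
        path = tmp_path / "t.csv"
        save_feature_table(tiny_table, path)
        back = load_feature_table(path, label_column="label")
        assert back.feature_names == tiny_table.feature_names
        assert back.labels == tiny_table.labels
        np.testing.assert_array_equal(back.values, tiny_table.values)

    def test_round_trip_preserves_full_precision(self, tmp_path):
        values = np.array([[1 / 3, np.pi], [np.e, 1e-17]])
        t = FeatureTable(values=values, feature_names=("a", "b"),
                         labels=("x", "y"), sample_ids=("s0", "s1"))
        path = tmp_path / "t.csv"
        save_feature_table(t, path)
        back = load_feature_table(path, label_column="label")
        np.testing.assert_array_equal(back.values, values)

    def test_tsv_delimiter(self, tiny_table, tmp_path):
        path = tmp_path / "t.tsv"
        save_feature_table(tiny_table, path, delimiter="\t")
        back = load_feature_table(path, label_column="label", delimiter="\t")
        assert back == FeatureTable(tiny_table.values, tiny_table.feature_names,
                                    tiny_table.labels, back.sample_ids)

    def test_missing_label_column_is_config_error(self, tiny_table, tmp_path):
        path = tmp_path / "t.csv"
        save_feature_table(tiny_table, path)
        with pytest.raises(ConfigurationError, match="nope"):
            load_feature_table(path, label_column="nope")

    def test_empty_cell_reports_coordinates(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("x,y,label\n1,2,a\n3,,b\n")
        with pytest.raises(DataError, match=r"'s1'.*'y'"):
            load_feature_table(path, label_column="label")

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("x,y,label\n1,2,a\nfoo,4,b\n")
        with pytest.raises(DataError, match="non-numeric"):
            load_feature_table(path, label_column="label")

    def test_single_class_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("x,label\n1,a\n2,a\n")
        with pytest.raises(DataError, match="2 label classes"):
            load_feature_table(path, label_column="label")

    def test_sample_id_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("id,x,label\nr1,1,a\nr2,2,b\n")
        t = load_feature_table(path, label_column="label", sample_id_column="id")
        assert t.sample_ids == ("r1", "r2")
        assert t.feature_names == ("x",)


class TestInvariants:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            FeatureTable(values=np.zeros((2, 2)), feature_names=("a", "b"),
                         labels=("x",), sample_ids=("s0", "s1"))

    def test_duplicate_feature_names_rejected(self):
        with pytest.raises(DataError, match="unique"):
            FeatureTable(values=np.zeros((1, 2)), feature_names=("a", "a"),
                         labels=("x",), sample_ids=("s0",))

    def test_nan_rejected_with_coordinates(self):
        with pytest.raises(DataError, match="'s0'.*'b'"):
            FeatureTable(values=np.array([[0.0, np.nan]]),
                         feature_names=("a", "b"), labels=("x",),
                         sample_ids=("s0",))

    def test_label_encoding_first_appearance_order(self, tiny_table):
        assert tiny_table.classes == ("a", "b")
        t = FeatureTable(tiny_table.values, tiny_table.feature_names,
                         ("b", "b", "a", "a"), tiny_table.sample_ids)
        assert t.classes == ("b", "a")
        np.testing.assert_array_equal(t.encoded_labels(), [0, 0, 1, 1])


class TestSubsetFeatures:
    def test_identity(self, tiny_table):
        assert subset_features(tiny_table, list(tiny_table.feature_names)) == tiny_table

    def test_empty_keep(self, tiny_table):
        sub = subset_features(tiny_table, [])
        assert sub.n_features == 0
        assert sub.n_samples == tiny_table.n_samples

    def test_reversed_matches_per_cell_copy(self, tiny_table):
        keep = list(reversed(tiny_table.feature_names))
        sub = subset_features(tiny_table, keep)
        # naive per-cell oracle
        for i in range(tiny_table.n_samples):
            for j, name in enumerate(keep):
                src = tiny_table.feature_names.index(name)
                assert sub.values[i, j] == tiny_table.values[i, src]

    def test_unknown_name_is_key_error(self, tiny_table):
        with pytest.raises(KeyError):
            subset_features(tiny_table, ["ghost"])

    def test_subset_composition(self, tiny_table):
        ab = subset_features(tiny_table, ["z", "x"])
        b_direct = subset_features(tiny_table, ["x"])
        b_via_a = subset_features(ab, ["x"])
        assert b_via_a == b_direct
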