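"""Dataset container validation, delimited I/O round-trips, feature subsetting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pocclass import (
    ExpressionDataset,
    load_dataset,
    save_dataset,
    subset_features,
)
from pocclass.simulate import SyntheticConfig, generate

from conftest import random_dataset


class TestValidation:
    def test_shape_and_id_consistency(self, rng):
        ds = random_dataset(rng)
        assert ds.n_samples == 9 and ds.n_features == 7 and ds.n_classes == 2

    @pytest.mark.parametrize(
        "mutation, match",
        [
            (dict(sample_ids=("a", "a", "b", "c")), "duplicate sample ids"),
            (dict(feature_ids=("f", "f", "g")), "duplicate feature ids"),
            (dict(labels=("x", "x", "x", "x")), "2 distinct subclass"),
            (dict(sample_ids=("a", "", "c", "d")), "empty-string sample id"),
            (dict(labels=("x", "y")), "labels for"),
        ],
    )
    def test_invalid_construction(self, mutation, match):
        base = dict(
            values=np.ones((4, 3)),
            sample_ids=("a", "b", "c", "d"),
            feature_ids=("f", "g", "h"),
            labels=("x", "x", "y", "y"),
        )
        base.update(mutation)
        with pytest.raises(ValueError, match=match):
            ExpressionDataset(**base)

    def test_missing_values_rejected(self):
        vals = np.ones((4, 3))
        vals[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ExpressionDataset(
                values=vals,
                sample_ids=("a", "b", "c", "d"),
                feature_ids=("f", "g", "h"),
                labels=("x", "x", "y", "y"),
            )

    def test_class_index_is_lexicographic(self):
        ds = ExpressionDataset(
            values=np.ones((4, 2)) * np.arange(4)[:, None],
            sample_ids=("a", "b", "c", "d"),
            feature_ids=("f", "g"),
            labels=("zeta", "alpha", "zeta", "alpha"),
        )
        assert ds.classes == ("alpha", "zeta")
        assert ds.class_index == {"alpha": 0, "zeta": 1}


class TestIO:
    def test_basic_read_back(self, tmp_path):
        mat = tmp_path / "m.tsv"
        lab = tmp_path / "l.tsv"
        mat.write_text(
            "\tg1\tg2\tg3\n"
            "s1\t1.5\t2\t3\n"
            "s2\t4\t5\t6\n"
            "s3\t7\t8\t9\n"
            "s4\t10\t11\t12\n"
        )
        lab.write_text("s1\tA\ns2\tA\ns3\tB\ns4\tB\n")
        ds = load_dataset(mat, lab)
        assert ds.n_samples == 4 and ds.n_features == 3 and ds.n_classes == 2
        assert ds.values[0, 0] == 1.5
        assert ds.labels == ("A", "A", "B", "B")

    def test_features_in_rows_orientation(self, tmp_path):
        mat = tmp_path / "m.csv"
        lab = tmp_path / "l.csv"
        mat.write_text(",s1,s2,s3,s4\ng1,1,2,3,4\ng2,5,6,7,8\n")
        lab.write_text("s1,A\ns2,A\ns3,B\ns4,B\n")
        ds = load_dataset(mat, lab, orientation="features_in_rows")
        assert ds.sample_ids == ("s1", "s2", "s3", "s4")
        assert ds.feature_ids == ("g1", "g2")
        np.testing.assert_array_equal(ds.values[:, 0], [1, 2, 3, 4])

    def test_unlabeled_sample_is_named(self, tmp_path):
        mat = tmp_path / "m.tsv"
        lab = tmp_path / "l.tsv"
        mat.write_text("\tg1\ns1\t1\ns2\t2\ns3\t3\n")
        lab.write_text("s1\tA\ns3\tB\n")
        with pytest.raises(ValueError, match="s2"):
            load_dataset(mat, lab)

    def test_missing_cell_rejected(self, tmp_path):
        mat = tmp_path / "m.tsv"
        lab = tmp_path / "l.tsv"
        mat.write_text("\tg1\tg2\ns1\t1\t\ns2\t2\t3\n")
        lab.write_text("s1\tA\ns2\tB\n")
        with pytest.raises(ValueError, match="missing"):
            load_dataset(mat, lab)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n_features=st.integers(1, 6),
        m_a=st.integers(1, 4),
        m_b=st.integers(1, 4),
        ext=st.sampled_from(["tsv", "csv"]),
    )
    def test_round_trip_property(self, seed, n_features, m_a, m_b, ext, tmp_path_factory):
        """load(save(ds)) == ds bitwise, for random datasets, both dialects."""
        tmp = tmp_path_factory.mktemp("rt")
        ds = random_dataset(
            np.random.default_rng(seed), (m_a, m_b), n_features
        )
        save_dataset(ds, tmp / f"m.{ext}", tmp / f"l.{ext}")
        back = load_dataset(tmp / f"m.{ext}", tmp / f"l.{ext}")
        assert back == ds

    def test_srbct_shaped_round_trip(self, tmp_path):
        """A benchmark-shaped dataset (83 samples, 2308 features, 4 classes)
        survives save/load with bitwise-equal values."""
        ds, _ = generate(
            SyntheticConfig(4, (29, 11, 18, 25), 2308, n_informative=100, seed=7)
        )
        save_dataset(ds, tmp_path / "m.tsv", tmp_path / "l.tsv")
        back = load_dataset(tmp_path / "m.tsv", tmp_path / "l.tsv")
        assert back == ds
        assert back.n_samples == 83 and back.n_features == 2308 and back.n_classes == 4


class TestSubsetFeatures:
    def test_identity_and_reorder(self, small_dataset):
        same = subset_features(small_dataset, range(small_dataset.n_features))
        assert same == small_dataset
        swapped = subset_features(small_dataset, [2, 0])
        assert swapped.feature_ids == ("g2", "g0")
        np.testing.assert_array_equal(
            swapped.values, small_dataset.values[:, [2, 0]]
        )
        assert swapped.labels == small_dataset.labels

    def test_errors(self, small_dataset):
        with pytest.raises(IndexError):
            subset_features(small_dataset, [0, 5])
        with pytest.raises(ValueError, match="duplicates"):
            subset_features(small_dataset, [1, 1])

    def test_select_225_of_2308(self):
        ds, _ = generate(
            SyntheticConfig(2, (5, 5), 2308, n_informative=50, seed=3)
        )
        sub = subset_features(ds, range(225))
        assert sub.n_features == 225 and sub.n_samples == ds.n_samples
        np.testing.assert_array_equal(sub.values, ds.values[:, :225])
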