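"""Template construction, POC classification, KNN variants, correlation distance."""

import numpy as np
import pytest

from pocclass import (
    ExpressionDataset,
    build_templates,
    classify_corr_knn,
    classify_dataset,
    classify_poc,
    classify_poc_knn,
    correlation_distance,
    peak_table,
)
from pocclass.simulate import SyntheticConfig, generate

from conftest import pearson_direct, random_dataset


def _dataset(values, labels):
    values = np.asarray(values, dtype=float)
    return ExpressionDataset(
        values=values,
        sample_ids=tuple(f"s{i}" for i in range(values.shape[0])),
        feature_ids=tuple(f"g{j}" for j in range(values.shape[1])),
        labels=tuple(labels),
    )


class TestTemplates:
    def test_singleton_class_template_is_the_sample(self):
        ds = _dataset([[1, 2, 3], [3, 4, 5], [9, 9, 9]], ["a", "a", "b"])
        templates = build_templates(ds)
        np.testing.assert_array_equal(templates[0].mu, [2, 3, 4])  # mean of two
        np.testing.assert_array_equal(templates[1].mu, [9, 9, 9])  # mean of one
        assert [t.n_members for t in templates] == [2, 1]
        assert [t.label for t in templates] == ["a", "b"]

    def test_matches_direct_mean_oracle(self, rng):
        ds = random_dataset(rng, (5, 7, 3), n_features=11)
        for tmpl in build_templates(ds):
            rows = ds.class_members(tmpl.label)
            direct = np.array(
                [sum(ds.values[i, j] for i in rows) / len(rows)
                 for j in range(ds.n_features)]
            )
            np.testing.assert_allclose(tmpl.mu, direct, atol=1e-12)


class TestClassifyPoc:
    def test_exact_template_match_wins_with_peak_one(self, rng):
        ds = random_dataset(rng, (4, 4, 4), n_features=16)
        templates = build_templates(ds)
        for tmpl in templates:
            scores = classify_poc(tmpl.mu, templates)
            assert scores.predicted_label == tmpl.label
            k = templates.index(tmpl)
            assert abs(scores.peaks[k] - 1.0) < 1e-9
            assert scores.margin > 0

    @pytest.mark.parametrize("mode", ["one_d", "two_d"])
    def test_templates_as_test_set_score_perfectly(self, mode, rng):
        ds = random_dataset(rng, (3, 3, 3), n_features=25)
        templates = build_templates(ds)
        as_test = _dataset(
            np.stack([t.mu for t in templates]), [t.label for t in templates]
        )
        _, acc = classify_dataset(as_test, templates, mode=mode)
        assert acc == 1.0

    def test_positive_rescaling_never_flips_prediction(self, rng):
        ds, _ = generate(SyntheticConfig(3, (5, 5, 5), 64, n_informative=12, seed=4))
        templates = build_templates(ds)
        for i in range(ds.n_samples):
            base = classify_poc(ds.values[i], templates)
            scaled = classify_poc(1e3 * ds.values[i], templates)
            assert scaled.predicted_label == base.predicted_label
            np.testing.assert_allclose(scaled.peaks, base.peaks, atol=1e-9)

    def test_label_permutation_equivariance(self, rng):
        """Relabeling subclasses permutes the peak vector accordingly."""
        ds = random_dataset(rng, (4, 4), n_features=9)
        templates = build_templates(ds)
        swapped = [templates[1], templates[0]]
        x = rng.normal(size=9)
        a = classify_poc(x, templates)
        b = classify_poc(x, swapped)
        np.testing.assert_allclose(a.peaks, b.peaks[::-1], atol=1e-12)
        assert a.predicted_label == b.predicted_label

    def test_two_d_requires_square_length(self, rng):
        ds = random_dataset(rng, (3, 3), n_features=10)
        templates = build_templates(ds)
        with pytest.raises(ValueError, match="square"):
            classify_poc(rng.normal(size=10), templates, mode="two_d")

    def test_single_sample_test_set(self, rng):
        ds = random_dataset(rng, (3, 3), n_features=8)
        templates = build_templates(ds)
        scores, acc = classify_dataset(
            _dataset(np.vstack([ds.values[0], ds.values[-1]]), [ds.labels[0], ds.labels[-1]]),
            templates,
        )
        assert acc in (0.0, 0.5, 1.0)
        assert len(scores) == 2


class TestKnn:
    def test_poc_knn_identical_sample_k1(self, rng):
        ds = random_dataset(rng, (4, 4), n_features=12)
        assert classify_poc_knn(ds.values[5], ds, k=1) == ds.labels[5]

    def test_poc_knn_k_bounds(self, rng):
        ds = random_dataset(rng, (2, 2), n_features=6)
        with pytest.raises(ValueError):
            classify_poc_knn(ds.values[0], ds, k=0)
        with pytest.raises(ValueError):
            classify_poc_knn(ds.values[0], ds, k=5)

    def test_corr_knn_duplicate_and_scaled_copy(self, rng):
        ds = random_dataset(rng, (4, 4), n_features=10)
        x = ds.values[2]
        assert classify_corr_knn(x, ds, k=1) == ds.labels[2]
        # correlation distance is invariant to positive scaling
        assert classify_corr_knn(5.0 * x, ds, k=1) == ds.labels[2]

    def test_corr_knn_agrees_with_exhaustive_oracle(self, rng):
        ds = random_dataset(rng, (3, 3, 3), n_features=8)
        x = rng.normal(size=8)
        k = 3
        d = [1 - pearson_direct(list(x), list(row)) for row in ds.values]
        order = sorted(range(len(d)), key=lambda i: d[i])[:k]
        votes = [ds.labels[i] for i in order]
        expected = max(set(votes), key=votes.count)
        counts = sorted((votes.count(v) for v in set(votes)), reverse=True)
        if len(counts) > 1 and counts[0] == counts[1]:
            expected = votes[0]  # tie -> nearest neighbour
        assert classify_corr_knn(x, ds, k=k) == expected


class TestCorrelationDistance:
    def test_identical_and_anticorrelated(self, rng):
        x = rng.normal(size=20)
        assert correlation_distance(x, x) == pytest.approx(0.0, abs=1e-12)
        assert correlation_distance(x, -x + 4.2) == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_pearson_oracle(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        expected = 1.0 - pearson_direct(list(x), list(y))
        assert correlation_distance(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_distance(np.ones(5), np.arange(5.0))


class TestPeakTable:
    def test_table_shape_and_columns(self, rng):
        ds = random_dataset(rng, (3, 3), n_features=9)
        templates = build_templates(ds)
        scores, _ = classify_dataset(ds, templates)
        table = peak_table(scores, ds.sample_ids)
        assert list(table.columns) == [
            "sample_id", "peak_k0", "peak_k1", "predicted_label", "margin",
        ]
        assert len(table) == ds.n_samples
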