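import numpy as np
import pytest

from gsabench.expression import (
    ExpressionDataset,
    center_genes,
    preprocess,
    quantile_normalize,
    read_expression,
    read_labels,
    write_expression,
    write_labels,
)


class TestMatrixIO:
    def test_tsv_round_trip(self, tiny_ds, tmp_path):
        path = tmp_path / "m.tsv"
        write_expression(tiny_ds, path)
        back = read_expression(path)
        assert back.gene_ids == tiny_ds.gene_ids
        assert back.sample_ids == tiny_ds.sample_ids
        np.testing.assert_allclose(back.values, tiny_ds.values)

    def test_gct_round_trip(self, tiny_ds, tmp_path):
        path = tmp_path / "m.gct"
        write_expression(tiny_ds, path, format="gct")
        back = read_expression(path)
        np.testing.assert_allclose(back.values, tiny_ds.values)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene\tS1\tS2\nG1\t1\t2\nG1\t3\t4\n")
        with pytest.raises(ValueError, match="duplicate gene ids"):
            read_expression(path)

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\tS1\tS2\nG1\t1\toops\n")
        with pytest.raises(ValueError, match="G1"):
            read_expression(path)

    def test_missing_value_rejected(self, tmp_path):
        path = tmp_path / "na.tsv"
        path.write_text("gene\tS1\tS2\nG1\t1\t\nG2\t3\t4\n")
        with pytest.raises(ValueError, match="missing"):
            read_expression(path)

    def test_gct_dim_mismatch_rejected(self, tmp_path):
        path = tmp_path / "m.gct"
        path.write_text("#1.2\n5\t2\nNAME\tDescription\tS1\tS2\nG1\tna\t1\t2\n")
        with pytest.raises(ValueError, match="disagree"):
            read_expression(path)


class TestLabelIO:
    def test_cls_positional(self, tmp_path):
        path = tmp_path / "l.cls"
        path.write_text("4 2 1\n# ctrl case\n0 0 1 1\n")
        np.testing.assert_array_equal(read_labels(path), [0, 0, 1, 1])

    def test_cls_named_tokens(self, tmp_path):
        path = tmp_path / "l.cls"
        path.write_text("4 2 1\n# ctrl case\nctrl ctrl case case\n")
        np.testing.assert_array_equal(read_labels(path), [0, 0, 1, 1])

    def test_two_column_aligned_by_sample(self, tmp_path):
        path = tmp_path / "l.txt"
        path.write_text("S2\t1\nS1\t0\n")
        np.testing.assert_array_equal(
            read_labels(path, format="two_column_tsv", sample_ids=["S1", "S2"]), [0, 1]
        )

    def test_unmatched_sample_rejected(self, tmp_path):
        path = tmp_path / "l.txt"
        path.write_text("S1\t0\nS2\t1\n")
        with pytest.raises(ValueError, match="without labels"):
            read_labels(path, format="two_column_tsv", sample_ids=["S1", "S3"])

    def test_single_class_rejected(self, tmp_path):
        path = tmp_path / "l.cls"
        path.write_text("3 2 1\n# a b\n0 0 0\n")
        with pytest.raises(ValueError):
            read_labels(path)

    def test_three_classes_rejected(self, tmp_path):
        path = tmp_path / "l.cls"
        path.write_text("3 3 1\n# a b c\n0 1 2\n")
        with pytest.raises(ValueError, match="2 classes"):
            read_labels(path)

    def test_cls_round_trip(self, tmp_path):
        path = tmp_path / "out.cls"
        write_labels([1, 0, 1, 0], path)
        np.testing.assert_array_equal(read_labels(path), [1, 0, 1, 0])


class TestQuantileNormalize:
    def test_hand_example(self):
        ds = ExpressionDataset(
            np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]), list("abc"), ["s1", "s2"]
        )
        out = quantile_normalize(ds)
        np.testing.assert_allclose(out.values[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.values[:, 1], [2.5, 3.5, 4.5])

    def test_all_columns_share_distribution(self, tiny_ds):
        out = quantile_normalize(tiny_ds)
        sorted_cols = np.sort(out.values, axis=0)
        for j in range(1, out.n_samples):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_rank_order_preserved_within_column(self, tiny_ds):
        out = quantile_normalize(tiny_ds)
        for j in range(tiny_ds.n_samples):
            np.testing.assert_array_equal(
                np.argsort(out.values[:, j]), np.argsort(tiny_ds.values[:, j])
            )

    def test_ties_get_averaged_reference(self):
        ds = ExpressionDataset(
            np.array([[1.0, 1.0], [1.0, 2.0], [3.0, 3.0]]), list("abc"), ["s1", "s2"]
        )
        out = quantile_normalize(ds)
        # column 1 has a tie at ranks 1,2: both get the mean reference value
        assert out.values[0, 0] == out.values[1, 0]

    def test_single_sample_rejected(self):
        ds = ExpressionDataset(np.array([[1.0], [2.0]]), ["a", "b"], ["s"])
        with pytest.raises(ValueError):
            quantile_normalize(ds)


class TestCenterGenes:
    def test_row_arithmetic(self):
        ds = ExpressionDataset(np.array([[1.0, 2.0, 3.0]]), ["g"], ["a", "b", "c"])
        np.testing.assert_allclose(center_genes(ds).values, [[-1.0, 0.0, 1.0]])

    def test_idempotent_and_sd_preserving(self, tiny_ds):
        once = center_genes(tiny_ds)
        twice = center_genes(once)
        np.testing.assert_allclose(once.values, twice.values)
        np.testing.assert_allclose(
            once.values.std(axis=1), tiny_ds.values.std(axis=1)
        )

    def test_correlations_unchanged(self, tiny_ds):
        before = np.corrcoef(tiny_ds.values)
        after = np.corrcoef(center_genes(tiny_ds).values)
        np.testing.assert_allclose(before, after, atol=1e-10)


def test_preprocess_components_idempotent(iid_ds):
    """Each preprocessing step is a fixed point of itself, and the pipeline
    ends with every gene exactly centered (the zero-signal invariant)."""
    qn = quantile_normalize(iid_ds)
    np.testing.assert_allclose(qn.values, quantile_normalize(qn).values, atol=1e-10)
    out = preprocess(iid_ds)
    np.testing.assert_allclose(out.values, center_genes(out).values, atol=1e-12)
    np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-12)


class TestDatasetInvariants:
    def test_shape_and_label_checks(self):
        with pytest.raises(ValueError, match="shape"):
            ExpressionDataset(np.zeros((2, 2)), ["a"], ["s1", "s2"])
        with pytest.raises(ValueError, match="binary"):
            ExpressionDataset(np.zeros((1, 2)), ["a"], ["s1", "s2"], [0, 2])
        with pytest.raises(ValueError, match="non-empty"):
            ExpressionDataset(np.zeros((1, 2)), ["a"], ["s1", "s2"], [1, 1])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ExpressionDataset(np.array([[np.nan, 1.0]]), ["a"], ["s1", "s2"])
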