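"""Log2 harmonization, quantile normalization, outlier removal, merged DE."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tp53mir import preprocess as pp
from tp53mir import synthetic_data as sd
from tp53mir.containers import MergedMatrix
from tp53mir.errors import DegenerateInputError, ParameterError


class TestEnsureLog2:
    def test_log2_scale_passes_through(self):
        m = pd.DataFrame([[8.1, 15.2], [3.3, 7.0]])
        out, flagged = pp.ensure_log2(m)
        assert not flagged
        pd.testing.assert_frame_equal(out, m)

    def test_raw_intensities_are_transformed(self):
        m = pd.DataFrame([[120.0, 44388.62], [950.0, 210.0]])
        out, flagged = pp.ensure_log2(m)
        assert flagged
        assert out.to_numpy().max() == pytest.approx(np.log2(44388.62 + 1))

    def test_zero_under_raw_signature_maps_to_zero(self):
        m = pd.DataFrame([[0.0, 60000.0]])
        out, flagged = pp.ensure_log2(m)
        assert flagged
        assert out.iloc[0, 0] == 0.0

    def test_negative_values_under_raw_signature_rejected(self):
        with pytest.raises(ParameterError):
            pp.ensure_log2(pd.DataFrame([[-1.0, 60000.0]]))


class TestQuantileNormalize:
    def test_hand_computed_two_by_two(self):
        # columns (1, 2) and (3, 4): sorted-row means are (2, 3)
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]})
        out = pp.quantile_normalize(m)
        assert out["s1"].tolist() == [2.0, 3.0]
        assert out["s2"].tolist() == [2.0, 3.0]

    def test_spec_of_columns_1_3_and_2_4(self):
        # columns (1, 3) and (2, 4): sorted-row means are (1.5, 3.5)
        m = pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 4.0]})
        out = pp.quantile_normalize(m)
        assert out["s1"].tolist() == [1.5, 3.5]
        assert out["s2"].tolist() == [1.5, 3.5]

    def test_permuted_columns_are_fixed_point(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=50)
        m = pd.DataFrame({f"s{i}": rng.permutation(col) for i in range(4)})
        out = pp.quantile_normalize(m)
        np.testing.assert_allclose(np.sort(out.to_numpy(), axis=0), np.sort(m.to_numpy(), axis=0), atol=1e-12)
        # each column's values unchanged up to reordering
        for c in m.columns:
            np.testing.assert_allclose(np.sort(out[c]), np.sort(col), atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=28,
            max_size=28,
            unique=True,
        )
    )
    def test_column_sorted_vectors_identical_and_idempotent(self, flat):
        # sorted-column equality is exact only without within-column ties
        # (tied entries receive the mean of their would-be quantile values)
        values = np.array(flat).reshape(7, 4)
        m = pd.DataFrame(values, columns=list("abcd"))
        out = pp.quantile_normalize(m)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 4):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-9)
        np.testing.assert_allclose(out.to_numpy().mean(axis=0),
                                   out.to_numpy().mean(axis=0)[0], atol=1e-9)
        twice = pp.quantile_normalize(out)
        np.testing.assert_allclose(twice.to_numpy(), out.to_numpy(), atol=1e-9)

    def test_missing_values_rejected(self):
        with pytest.raises(ParameterError):
            pp.quantile_normalize(pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]}))


class TestKmeansOutlierRemoval:
    def test_single_distant_sample_removed(self):
        rng = np.random.default_rng(1)
        tight = rng.normal(0, 1, size=(30, 20))
        outlier = rng.normal(0, 1, size=(30, 1)) + 10 * np.sqrt(30)
        m = pd.DataFrame(
            np.hstack([tight, outlier]), columns=[f"s{i}" for i in range(21)]
        )
        kept, removed, sizes = pp.kmeans_outlier_removal(m, seed=0)
        assert removed == ["s20"]
        assert len(kept) == 20

    def test_balanced_clusters_keep_everything(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(10, 15))
        b = rng.normal(8, 1, size=(10, 15))
        m = pd.DataFrame(np.hstack([a, b]), columns=[f"s{i}" for i in range(30)])
        kept, removed, _ = pp.kmeans_outlier_removal(m, seed=0)
        assert removed == []

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(25, 40)), columns=[f"s{i}" for i in range(40)])
        r1 = pp.kmeans_outlier_removal(m, seed=5)
        r2 = pp.kmeans_outlier_removal(m, seed=5)
        assert r1[0] == r2[0] and r1[1] == r2[1]

    def test_removal_emptying_a_class_rejected(self):
        rng = np.random.default_rng(4)
        tight = rng.normal(0, 0.1, size=(10, 20))
        outlier = rng.normal(50, 0.1, size=(10, 1))
        m = pd.DataFrame(np.hstack([tight, outlier]), columns=[f"s{i}" for i in range(21)])
        classes = pd.Series(["tumor"] * 20 + ["normal"], index=m.columns)
        with pytest.raises(DegenerateInputError):
            pp.kmeans_outlier_removal(m, seed=0, classes=classes)


class TestDifferentialExpression:
    def _merged(self, values, classes, genes=None):
        genes = genes or [f"g{i}" for i in range(values.shape[0])]
        return MergedMatrix(
            genes=genes,
            samples=[f"s{i}" for i in range(values.shape[1])],
            values=values,
            classes=np.asarray(classes, dtype=object),
        )

    def test_planted_gene_has_smallest_adjusted_p(self, cleaned_default):
        cleaned, de, _ = cleaned_default
        de = de.set_index("gene")
        best = de.p_adj.idxmin()
        assert best in sd.NOVEL_GENES

    def test_null_matrix_bh_significant_fraction_near_zero(self, null_collection, null_design):
        cleaned, de, _ = pp.preprocess_pipeline(null_collection, null_design.genes, seed=0)
        assert (de.p_adj < 0.05).mean() <= 0.05

    def test_single_gene_adjusted_p_equals_raw(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(1, 10))
        merged = self._merged(values, ["tumor"] * 5 + ["normal"] * 5)
        de = pp.differential_expression(merged)
        assert de.loc[0, "p_adj"] == pytest.approx(de.loc[0, "p"])

    def test_degenerate_gene_gets_na_row_with_reason(self):
        values = np.vstack([np.ones(8), np.random.default_rng(6).normal(size=8)])
        values[0, :4] = 2.0  # constant per class, different means
        merged = self._merged(values, ["tumor"] * 4 + ["normal"] * 4)
        de = pp.differential_expression(merged)
        assert np.isnan(de.loc[0, "p"])
        assert de.loc[0, "reason"] != ""
        assert np.isfinite(de.loc[1, "p_adj"])

    def test_bh_adjusted_p_monotone_in_raw_p(self, cleaned_default):
        _, de, _ = cleaned_default
        ok = de.dropna(subset=["p"]).sort_values("p")
        assert ok.p_adj.is_monotonic_increasing


class TestMerge:
    def test_merge_restricts_to_common_candidates(self, default_collection):
        merged = pp.merge_datasets(default_collection, ["MEIS1", "BAK1", "NOSUCH"])
        assert merged.genes == ["MEIS1", "BAK1"]
        assert len(merged.samples) == sum(len(d.samples) for d in default_collection)

    def test_outlier_removal_preserves_kept_values(self, default_collection, default_design):
        cleaned, _, removed = pp.preprocess_pipeline(
            default_collection, default_design.genes, seed=42
        )
        merged = pp.merge_datasets(default_collection, default_design.genes)
        normalized = pp.quantile_normalize(merged.to_frame())
        kept_cols = [s for s in merged.samples if s not in set(removed)]
        np.testing.assert_array_equal(
            cleaned.to_frame().to_numpy(), normalized[kept_cols].to_numpy()
        )
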