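import numpy as np
import pandas as pd
import pytest

from oleomics.feature_io import ValidationError
from oleomics.stats import bh_adjust, heatmap_order, kw_bh, pca_overview, preprocess


class TestPreprocess:
    def test_constant_column_maps_to_zero(self):
        df = pd.DataFrame({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 3.0]})
        out = preprocess(df)
        assert np.allclose(out["a"], 0.0)

    def test_hand_computed_pareto(self):
        # oracle computed by hand: log10(x+1), center, divide by sqrt(sd)
        df = pd.DataFrame({"a": [9.0, 99.0, 999.0]})
        logged = np.log10(df["a"] + 1.0)          # 1, 2, 3
        expected = (logged - 2.0) / np.sqrt(1.0)  # sd = 1 -> [-1, 0, 1]
        out = preprocess(df)
        assert np.allclose(out["a"], expected)

    def test_imputation_is_seeded(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [2.0, 2.5, np.nan]})
        out1 = preprocess(df, seed=13)
        out2 = preprocess(df, seed=13)
        assert np.allclose(out1.values, out2.values)

    def test_imputed_values_below_min_positive(self):
        df = pd.DataFrame({"a": [10.0, np.nan, 30.0]})
        x = df.copy()
        out = preprocess(x, seed=1)
        # imputed cell must stay below the smallest observed log value
        assert out["a"].iloc[1] < out["a"].iloc[0]

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            preprocess(pd.DataFrame({"a": [-1.0, 2.0, 3.0]}))

    def test_all_missing_column_rejected(self):
        with pytest.raises(ValidationError):
            preprocess(pd.DataFrame({"a": [np.nan, np.nan, np.nan]}))


class TestPca:
    def test_rank_one_matrix(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame(np.outer([1.0, 2.0, 3.0], base))
        res = pca_overview(df)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_orthogonal_toy_matches_analytic_eigenvalues(self):
        # two uncorrelated coordinates with variances 4 and 1
        x = np.array([[2.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        df = pd.DataFrame(x)
        res = pca_overview(df)
        # covariance eigenvalues: 8/3 and 2/3 -> ratios 0.8 / 0.2
        assert res.explained_variance_ratio == pytest.approx([0.8, 0.2])

    def test_variance_fractions_sum_to_at_most_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(10, 6)))
        res = pca_overview(df)
        assert res.explained_variance_ratio.sum() <= 1.0 + 1e-9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            pca_overview(pd.DataFrame(np.ones((2, 3))))

    def test_rank_zero_rejected(self):
        with pytest.raises(ValidationError):
            pca_overview(pd.DataFrame(np.ones((4, 3))))

    def test_replicate_clustering_on_synthetic_triplicates(self, synth_default):
        # build a samples x compounds matrix from the molecular-ion features
        feats = [f for f in synth_default.features_neg
                 if synth_default.truth[f.feature_id].role == "molecular_ion"]
        df = pd.DataFrame({f.feature_id: f.intensities for f in feats})
        scores = pca_overview(preprocess(df), n_components=2).scores
        products = [s.rsplit("_", 1)[0] for s in scores.index]
        ok = 0
        for product in set(products):
            own = scores.loc[[s for s, p in zip(scores.index, products)
                              if p == product]].values
            other = scores.loc[[s for s, p in zip(scores.index, products)
                                if p != product]].values
            within = max(np.linalg.norm(a - b) for a in own for b in own)
            between = min(np.linalg.norm(a - b) for a in own for b in other)
            ok += within < between
        assert ok / len(set(products)) >= 0.9


class TestKwBh:
    def test_bh_formula_frozen_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_class_rejected(self):
        df = pd.DataFrame(np.ones((4, 2)))
        with pytest.raises(ValidationError):
            kw_bh(df, ["a", "a", "a", "a"])

    def test_small_class_rejected(self):
        df = pd.DataFrame(np.ones((3, 2)))
        with pytest.raises(ValidationError):
            kw_bh(df, ["a", "a", "b"])

    def test_type_one_error_controlled(self):
        # null simulation: identical distributions in all classes
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        clean_runs = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(12, 10)))
            res = kw_bh(df, labels)
            clean_runs += not res["significant"].any()
        assert clean_runs / n_runs >= 0.95

    def test_planted_shift_detected(self):
        # with n=4/group rank tests saturate; a graded 3-sd step between
        # classes gives full separation and the smallest attainable p
        rng = np.random.default_rng(123)
        x = rng.normal(size=(12, 5))
        x[4:8, 0] += 3.0
        x[8:, 0] += 6.0
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = kw_bh(pd.DataFrame(x), labels)
        assert bool(res["significant"].iloc[0])

    def test_constant_feature_is_never_significant(self):
        df = pd.DataFrame({"flat": np.ones(8), "var": np.arange(8.0)})
        res = kw_bh(df, ["a"] * 4 + ["b"] * 4)
        assert res.loc["flat", "p"] == 1.0


class TestHeatmapOrder:
    def _matrix(self):
        data = {
            "up_in_F": [3.0, 3.1, 2.0, 2.1, 1.0, 1.1],
            "flat": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        }
        idx = ["F1", "F2", "L1", "L2", "B1", "B2"]
        classes = pd.Series(["F", "F", "L", "L", "B", "B"], index=idx)
        return pd.DataFrame(data, index=idx), classes

    def test_behavior_label(self):
        matrix, classes = self._matrix()
        _, _, labels = heatmap_order(matrix, classes)
        assert labels["up_in_F"] == "F > L > B"

    def test_tie_label(self):
        matrix, classes = self._matrix()
        _, _, labels = heatmap_order(matrix, classes)
        assert labels["flat"] == "B = F = L"

    def test_columns_ordered_by_class(self):
        matrix, classes = self._matrix()
        _, col_order, _ = heatmap_order(matrix, classes)
        assert [classes[c] for c in col_order] == sorted(classes)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            heatmap_order(pd.DataFrame(), pd.Series(dtype=object))

    def test_planted_orderings_recovered(self):
        rng = np.random.default_rng(42)
        idx = [f"{c}{i}" for c in "FLB" for i in range(3)]
        classes = pd.Series([s[0] for s in idx], index=idx)
        base = {"F": 10.0, "L": 5.0, "B": 1.0}
        cols = {}
        planted = {}
        for j, order in enumerate([("F", "L", "B"), ("B", "L", "F"), ("L", "F", "B")]):
            values = {cls: base[src] for cls, src in zip(order, ("F", "L", "B"))}
            cols[f"feat{j}"] = [values[s[0]] + rng.normal(0, 0.01) for s in idx]
            planted[f"feat{j}"] = " > ".join(order)
        _, _, labels = heatmap_order(pd.DataFrame(cols, index=idx), classes)
        assert labels == planted
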