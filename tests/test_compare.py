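import itertools

import numpy as np
import pandas as pd
import pytest

from lfqatlas import compare
from lfqatlas.io_formats import CategoricalAtlas


def atlas_from_rows(rows):
    return CategoricalAtlas(
        table=pd.DataFrame(rows, columns=["gene_id", "organ", "level", "reliability"])
    )


class TestMapCategoricalLevels:
    def test_quoted_mapping(self):
        atlas = atlas_from_rows(
            [
                ("g1", "brain", "low", "supported"),
                ("g2", "brain", "medium", "supported"),
                ("g3", "brain", "high", "supported"),
                ("g4", "brain", "not detected", "supported"),
                ("g5", "brain", "ascending", "supported"),
                ("g6", "brain", "descending", "supported"),
                ("g7", "brain", "not representative", "supported"),
            ]
        )
        out = compare.map_categorical_levels(atlas)["brain"]
        assert out.loc[["g1", "g2", "g3"]].tolist() == [1.0, 2.0, 3.0]
        assert np.isnan(out.loc["g4"])
        assert out.loc[["g5", "g6", "g7"]].tolist() == [1.0, 1.0, 1.0]

    def test_uncertain_rows_dropped(self):
        atlas = atlas_from_rows(
            [("g1", "brain", "high", "uncertain"), ("g2", "brain", "low", "enhanced")]
        )
        out = compare.map_categorical_levels(atlas)
        assert "g1" not in out.index and out.loc["g2", "brain"] == 1.0


class TestTrueEditDistance:
    def test_identical_vectors_zero(self):
        v = pd.Series([1.0, 2, 3], index=list("abc"))
        _, mean = compare.true_edit_distance(v, v)
        assert mean == 0.0

    def test_hand_example(self):
        v1 = pd.Series([1.0, 2, 3], index=list("abc"))
        v2 = pd.Series([3.0, 2, 1], index=list("abc"))
        d, mean = compare.true_edit_distance(v1, v2)
        assert d.tolist() == [2.0, 0.0, 2.0]
        assert mean == pytest.approx(4 / 3)

    def test_na_pairs_dropped(self):
        v1 = pd.Series([1.0, np.nan, 3], index=list("abc"))
        v2 = pd.Series([1.0, 2, 3], index=list("abc"))
        d, mean = compare.true_edit_distance(v1, v2)
        assert len(d) == 2 and mean == 0.0

    def test_no_shared_support_errors(self):
        v1 = pd.Series([1.0], index=["a"])
        v2 = pd.Series([1.0], index=["b"])
        with pytest.raises(compare.ComparisonError):
            compare.true_edit_distance(v1, v2)


class TestRandomizedEditDistance:
    def test_constant_reference_gives_zero_difference(self):
        v1 = pd.Series([2.0] * 5, index=list("abcde"))
        rep = compare.randomized_edit_distance_difference(v1, v1, n_perm=20, seed=0)
        assert rep.difference == 0.0

    def test_difference_bookkeeping_exact(self):
        rng = np.random.default_rng(0)
        v1 = pd.Series(rng.integers(1, 4, 30).astype(float))
        v2 = pd.Series(rng.integers(1, 4, 30).astype(float))
        rep = compare.randomized_edit_distance_difference(v1, v2, n_perm=10, seed=3)
        assert rep.difference == rep.randomized_distance_mean - rep.true_distance_mean

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        v1 = pd.Series(rng.integers(1, 4, 20).astype(float))
        v2 = pd.Series(rng.integers(1, 4, 20).astype(float))
        a = compare.randomized_edit_distance_difference(v1, v2, n_perm=10, seed=5)
        b = compare.randomized_edit_distance_difference(v1, v2, n_perm=10, seed=5)
        assert a == b

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """Permutation sampling converges to the average over all |v|!
        permutations of the reference vector."""
        v1 = pd.Series([1.0, 2, 3, 1, 3], index=list("abcde"))
        v2 = pd.Series([2.0, 3, 1, 1, 2], index=list("abcde"))
        exact = np.mean(
            [np.mean(np.abs(v1.to_numpy() - np.array(p))) for p in itertools.permutations(v2)]
        )
        rep = compare.randomized_edit_distance_difference(v1, v2, n_perm=4000, seed=11)
        assert rep.randomized_distance_mean == pytest.approx(exact, abs=0.02)

    def test_unrelated_uniform_reference_near_zero(self):
        rng = np.random.default_rng(21)
        v1 = pd.Series(rng.integers(1, 4, 600).astype(float))
        v2 = pd.Series(rng.integers(1, 4, 600).astype(float))
        rep = compare.randomized_edit_distance_difference(v1, v2, n_perm=200, seed=2)
        assert abs(rep.difference) < 0.05

    def test_na_support_shared_by_true_and_randomized(self):
        v1 = pd.Series([1.0, np.nan, 3, 2], index=list("abcd"))
        v2 = pd.Series([1.0, 2, np.nan, 2], index=list("abcd"))
        rep = compare.randomized_edit_distance_difference(v1, v2, n_perm=5, seed=0)
        assert rep.n_proteins == 2

    def test_with_replacement_mode_runs(self):
        v1 = pd.Series([1.0, 2, 3], index=list("abc"))
        rep = compare.randomized_edit_distance_difference(
            v1, v1, n_perm=50, seed=1, with_replacement=True
        )
        assert rep.randomized_distance_mean > 0


class TestOverlapSummary:
    def test_identical_sets(self):
        out = compare.overlap_summary({"a", "b"}, {"a", "b"})
        assert (out["common_pct"], out["a_only_pct"], out["b_only_pct"]) == (100.0, 0.0, 0.0)

    def test_disjoint_equal_sets(self):
        out = compare.overlap_summary({"a", "b"}, {"c", "d"})
        assert (out["common_pct"], out["a_only_pct"], out["b_only_pct"]) == (0.0, 50.0, 50.0)

    def test_hand_counted_example(self):
        out = compare.overlap_summary({"a", "b", "c"}, {"b", "c", "d"})
        assert out["common_pct"] == 50.0
        assert out["a_only_pct"] == 25.0 and out["b_only_pct"] == 25.0
        assert out["union_size"] == 4.0

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(50)]
        a = set(rng.choice(universe, 20, replace=False))
        b = set(rng.choice(universe, 25, replace=False))
        out = compare.overlap_summary(a, b)
        assert out["common_pct"] + out["a_only_pct"] + out["b_only_pct"] == pytest.approx(100.0)

    def test_empty_union_errors(self):
        with pytest.raises(compare.ComparisonError):
            compare.overlap_summary(set(), set())


class TestContinuousAtlasCorrelation:
    def organ_map(self, samples, organ="brain"):
        return pd.Series({s: organ for s in samples})

    def test_atlas_vs_itself_is_one(self):
        genes = [f"g{i}" for i in range(6)]
        vals = pd.DataFrame(
            {"s1": [1, 2, 4, 8, 16, 32], "s2": [1, 2, 4, 8, 16, 32]}, index=genes, dtype=float
        )
        atlas = pd.DataFrame({"brain": vals["s1"]})
        out = compare.continuous_atlas_correlation(vals, self.organ_map(["s1", "s2"]), atlas)
        assert out["brain"] == pytest.approx(1.0)

    def test_constant_fold_change_still_one(self):
        genes = [f"g{i}" for i in range(5)]
        a = pd.DataFrame({"s1": [1.0, 3, 9, 27, 81]}, index=genes)
        atlas = pd.DataFrame({"brain": 2.0 * a["s1"]})
        out = compare.continuous_atlas_correlation(a, self.organ_map(["s1"]), atlas)
        assert out["brain"] == pytest.approx(1.0)

    def test_median_then_log2_enters_correlation(self):
        # two samples (4,16) -> median 10 -> log2(10) ~ 3.3219 must be used
        a = pd.DataFrame(
            {"s1": [4.0, 1.0, 64.0], "s2": [16.0, 1.0, 64.0]}, index=["g1", "g2", "g3"]
        )
        atlas = pd.DataFrame({"brain": [10.0, 1.0, 64.0]}, index=["g1", "g2", "g3"])
        out = compare.continuous_atlas_correlation(a, self.organ_map(["s1", "s2"]), atlas)
        assert out["brain"] == pytest.approx(1.0)
        medians = a.median(axis=1)
        assert np.log2(medians["g1"]) == pytest.approx(3.321928, abs=1e-6)

    def test_too_few_shared_genes_skipped(self):
        a = pd.DataFrame({"s1": [1.0, 2.0]}, index=["g1", "g2"])
        atlas = pd.DataFrame({"brain": [1.0, 2.0]}, index=["g1", "g2"])
        out = compare.continuous_atlas_correlation(a, self.organ_map(["s1"]), atlas, min_shared=3)
        assert "brain" not in out.index
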