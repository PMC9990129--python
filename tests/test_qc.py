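import numpy as np
import pandas as pd
import pytest

from lfqatlas import binning, qc
from lfqatlas.io_formats import SampleMap


def binned(bins: pd.DataFrame, n_bins=5):
    batch = pd.Series(
        [("DS1", "t") for _ in bins.columns], index=bins.columns
    )
    return binning.BinnedMatrix(bins=bins, n_bins=n_bins, batch=batch)


class TestCrossDatasetFdr:
    def test_hand_counted_three_dataset_example(self):
        detections = {}
        is_decoy = {}
        # two decoys: one in datasets {1,2}, one in {1}
        detections["d1"], is_decoy["d1"] = {"DS1", "DS2"}, True
        detections["d2"], is_decoy["d2"] = {"DS1"}, True
        # targets: 100 in >=1, 60 in >=2, 30 in all 3
        for i in range(100):
            ds = {"DS1"}
            if i < 60:
                ds.add("DS2")
            if i < 30:
                ds.add("DS3")
            detections[f"t{i}"], is_decoy[f"t{i}"] = ds, False
        table = qc.cross_dataset_fdr(detections, is_decoy, n_datasets=3)
        assert table["targets"].tolist() == [100, 60, 30]
        assert table["decoys"].tolist() == [2, 1, 0]
        assert table["fdr"].tolist() == pytest.approx([0.02, 1 / 60, 0.0])

    def test_no_decoys_gives_zero_fdr(self):
        detections = {f"t{i}": {"DS1"} for i in range(5)}
        table = qc.cross_dataset_fdr(detections, {k: False for k in detections}, n_datasets=1)
        assert table["fdr"].tolist() == [0.0]

    def test_single_dataset_is_within_dataset_decoy_rate(self):
        detections = {"t1": {"DS1"}, "t2": {"DS1"}, "d1": {"DS1"}}
        table = qc.cross_dataset_fdr(
            detections, {"t1": False, "t2": False, "d1": True}, n_datasets=1
        )
        assert table.loc[1, "fdr"] == pytest.approx(0.5)

    def test_no_targets_at_k_reported_na(self):
        detections = {"t1": {"DS1"}, "d1": {"DS1", "DS2"}}
        table = qc.cross_dataset_fdr(detections, {"t1": False, "d1": True}, n_datasets=2)
        assert np.isnan(table.loc[2, "fdr"])

    def test_counts_non_increasing_in_k(self, default_study):
        from lfqatlas.pipeline import detections_across_datasets

        det, dec = detections_across_datasets(default_study["raw_tables"])
        table = qc.cross_dataset_fdr(det, dec, n_datasets=3)
        assert (table["targets"].diff().dropna() <= 0).all()
        assert (table["decoys"].diff().dropna() <= 0).all()
        assert len(table) == 3


class TestPairwiseBinCorrelation:
    def test_pairwise_complete_hand_example(self):
        bins = pd.DataFrame(
            {"s1": [1.0, 2, 3, np.nan], "s2": [2.0, 4, 6, 5]}, index=list("abcd")
        )
        corr = qc.pairwise_bin_correlation(binned(bins))
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)
        assert corr.loc["s1", "s1"] == 1.0

    def test_anti_ordered_is_minus_one(self):
        bins = pd.DataFrame({"s1": [1.0, 2, 3], "s2": [3.0, 2, 1]})
        corr = qc.pairwise_bin_correlation(binned(bins))
        assert corr.loc["s1", "s2"] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal(self, default_study):
        corr = qc.pairwise_bin_correlation(default_study["binned5"])
        assert np.allclose(corr.values, corr.values.T, equal_nan=True)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_constant_pair_is_na_with_warning(self):
        bins = pd.DataFrame({"s1": [2.0, 2, 2, 2], "s2": [1.0, 2, 3, 4]})
        with pytest.warns(UserWarning, match="undefined"):
            corr = qc.pairwise_bin_correlation(binned(bins))
        assert np.isnan(corr.loc["s1", "s2"])

    def test_within_tissue_correlation_exceeds_between(self, default_study):
        """Samples of the same organ correlate more strongly on bins than
        samples of different organs, despite per-dataset batch effects."""
        corr = qc.pairwise_bin_correlation(default_study["binned5"])
        organ = default_study["sample_map"].organ_of_sample().loc[corr.index]
        same = organ.values[:, None] == organ.values[None, :]
        off_diag = ~np.eye(len(corr), dtype=bool)
        within = corr.values[same & off_diag].mean()
        between = corr.values[~same].mean()
        assert within > between


class TestClusterOrder:
    def test_identical_pair_merges_first(self):
        corr = pd.DataFrame(
            [[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
            index=["a", "b", "c"],
            columns=["a", "b", "c"],
        )
        res = qc.cluster_order(corr)
        assert set(res.leaf_order[:2]) == {"a", "b"} or set(res.leaf_order[1:]) == {"a", "b"}
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)  # first merge at distance 0

    def test_duplicate_samples_adjacent(self, default_study):
        corr = qc.pairwise_bin_correlation(default_study["binned5"]).iloc[:20, :20]
        first_col = corr.iloc[:, 0].to_numpy().tolist()
        dup = corr.copy()
        dup.loc["dup_of_first"] = dup.iloc[0]
        dup["dup_of_first"] = first_col + [1.0]
        res = qc.cluster_order(dup)
        i = res.leaf_order.index(dup.index[0])
        j = res.leaf_order.index("dup_of_first")
        assert abs(i - j) == 1

    def test_order_invariant_to_row_permutation(self):
        rng = np.random.default_rng(4)
        x = rng.random((6, 6))
        corr = pd.DataFrame((x + x.T) / 2, index=list("abcdef"), columns=list("abcdef"))
        np.fill_diagonal(corr.values, 1.0)
        base = qc.cluster_order(corr).leaf_order
        perm = list(rng.permutation(list("abcdef")))
        shuffled = qc.cluster_order(corr.loc[perm, perm]).leaf_order
        assert shuffled in (base, base[::-1])

    def test_too_few_samples_errors(self):
        with pytest.raises(qc.QCError):
            qc.cluster_order(pd.DataFrame([[1.0]], index=["a"], columns=["a"]))


class TestPcaOnBins:
    def test_identical_samples_identical_coordinates(self):
        bins = pd.DataFrame(
            {"s1": [1.0, 2, 3, 4], "s2": [1.0, 2, 3, 4], "s3": [4.0, 3, 2, 1]}
        )
        res = qc.pca_on_bins(binned(bins), min_fraction=0.5)
        np.testing.assert_allclose(
            res.coordinates.loc["s1"].to_numpy(), res.coordinates.loc["s2"].to_numpy(), atol=1e-12
        )

    def test_gene_detected_below_threshold_excluded(self):
        bins = pd.DataFrame(
            np.ones((2, 6)), index=["g_ok", "g_sparse"], columns=[f"s{i}" for i in range(6)]
        )
        bins.iloc[1, 2:] = np.nan  # detected in 2 of 6 samples = 33%
        res = qc.pca_on_bins(binned(bins), min_fraction=0.5)
        assert res.n_genes_used == 1

    def test_variance_fractions_match_eigendecomposition(self):
        rng = np.random.default_rng(8)
        bins = pd.DataFrame(
            rng.integers(1, 6, (10, 6)).astype(float), columns=[f"s{i}" for i in range(6)]
        )
        res = qc.pca_on_bins(binned(bins), min_fraction=0.5)
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()
        x = bins.T - bins.T.mean(axis=0)
        eigvals = np.linalg.eigvalsh(x.to_numpy() @ x.to_numpy().T)[::-1]
        eigvals = np.clip(eigvals, 0, None)
        expected = eigvals / eigvals.sum()
        np.testing.assert_allclose(
            res.explained_variance_ratio, expected[: len(res.explained_variance_ratio)], atol=1e-9
        )

    def test_no_passing_gene_errors(self):
        bins = pd.DataFrame(np.full((3, 4), np.nan), columns=[f"s{i}" for i in range(4)])
        with pytest.raises(qc.QCError):
            qc.pca_on_bins(binned(bins), min_fraction=0.5)
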