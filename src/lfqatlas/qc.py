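"""Quality-control diagnostics: cross-dataset decoy FDR and sample structure.

Because every dataset is searched separately at its own 1% protein FDR, the
union list accumulates false positives.  Decoy protein groups detected in the
*unfiltered* tables give a direct estimate of the error among proteins seen
in at least k datasets:

    FDR(k) = D(k) / T(k)

with D(k) and T(k) the numbers of decoy and target groups detected in >= k
datasets.  A protein seen independently in many datasets is very unlikely to
be a random match in all of them, so FDR(k) falls rapidly with k.

Sample-structure diagnostics operate on the binned matrix: pairwise-complete
Pearson correlation between samples, hierarchical clustering (complete
linkage on Euclidean distances between correlation rows), and PCA on genes
quantified in at least half of the samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from lfqatlas.binning import BinnedMatrix


class QCError(ValueError):
    pass


def cross_dataset_fdr(
    detections: Mapping[str, set[str]],
    is_decoy: Mapping[str, bool],
    n_datasets: int | None = None,
) -> pd.DataFrame:
    """FDR as a function of the number of datasets a protein is detected in.

    ``detections`` maps a protein-group key to the set of dataset ids where it
    was detected (pre-filter, so decoys are present).  Returns one row per
    k = 1..n_datasets with columns ``targets``, ``decoys``, ``fdr`` (NA where
    no targets reach k).
    """
    if not detections:
        raise QCError("no detections supplied")
    counts = {p: len(ds) for p, ds in detections.items()}
    if n_datasets is None:
        n_datasets = max(counts.values())
    rows = []
    for k in range(1, n_datasets + 1):
        t = sum(1 for p, c in counts.items() if c >= k and not is_decoy[p])
        d = sum(1 for p, c in counts.items() if c >= k and is_decoy[p])
        rows.append(
            {"k": k, "targets": t, "decoys": d, "fdr": (d / t) if t > 0 else np.nan}
        )
    return pd.DataFrame(rows).set_index("k")


def pairwise_bin_correlation(binned: BinnedMatrix, min_periods: int = 3) -> pd.DataFrame:
    """Sample x sample Pearson r over pairwise-complete binned observations.

    Pairs with fewer than ``min_periods`` complete observations, and pairs
    where either vector is constant on the shared support, are NA.
    """
    if binned.bins.shape[1] < 2:
        raise QCError("need at least 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant vectors -> NaN
        corr = binned.bins.corr(method="pearson", min_periods=min_periods)
    np.fill_diagonal(corr.values, 1.0)
    n_na = int(corr.isna().sum().sum())
    if n_na:
        warnings.warn(
            f"{n_na} sample pair(s) have undefined correlation "
            "(constant or <min_periods complete observations)",
            stacklevel=2,
        )
    return corr


@dataclass
class ClusterResult:
    leaf_order: list[str]
    linkage_matrix: np.ndarray
    method: str
    metric: str


def cluster_order(corr: pd.DataFrame, method: str = "complete") -> ClusterResult:
    """Hierarchical clustering of samples on Euclidean distances between
    correlation-matrix rows; deterministic leaf order (rows are processed in
    lexicographic sample-id order before linkage)."""
    if corr.shape[0] < 2:
        raise QCError("need at least 2 samples to cluster")
    if corr.isna().any().any():
        warnings.warn("NA correlations imputed as 0 for clustering", stacklevel=2)
        corr = corr.fillna(0.0)
    ordered_ids = sorted(corr.index)
    rows = corr.loc[ordered_ids, ordered_ids].to_numpy(float)
    z = linkage(rows, method=method, metric="euclidean")
    leaves = [ordered_ids[i] for i in leaves_list(z)]
    return ClusterResult(leaf_order=leaves, linkage_matrix=z, method=method, metric="euclidean")


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    n_genes_used: int


def pca_on_bins(
    binned: BinnedMatrix,
    min_fraction: float = 0.5,
    n_components: int | None = None,
    impute: str = "zero",
) -> PCAResult:
    """PCA of samples on binned values of genes quantified in at least
    ``min_fraction`` of the samples.

    Remaining NA cells are imputed as 0 (undetected ~ lowest signal) or as the
    gene mean (``impute="mean"``); columns (genes) are centered and the
    coordinates come from the singular value decomposition.
    """
    bins = binned.bins
    if bins.shape[1] < 3:
        raise QCError("need at least 3 samples for PCA")
    keep = bins.notna().mean(axis=1) >= min_fraction
    if not keep.any():
        raise QCError(f"no gene quantified in >= {min_fraction:.0%} of samples")
    x = bins.loc[keep].T  # samples x genes
    if impute == "zero":
        x = x.fillna(0.0)
    elif impute == "mean":
        x = x.fillna(x.mean(axis=0))
    else:
        raise QCError(f"unknown imputation mode {impute!r}")
    centered = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(centered.to_numpy(float), full_matrices=False)
    k = n_components or min(centered.shape)
    coords = pd.DataFrame(
        (u * s)[:, :k],
        index=x.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    return PCAResult(
        coordinates=coords, explained_variance_ratio=ratio[:k], n_genes_used=int(keep.sum())
    )
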