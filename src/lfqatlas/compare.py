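"""Comparison statistics against categorical and continuous reference atlases.

The central statistic is the *randomized edit distance difference* between
two aligned bin vectors (pipeline organ profile vs a reference atlas organ):
the true edit distance of a protein is the absolute difference of its bins in
the two vectors; the randomized edit distance permutes the reference bins
across proteins and re-measures; the difference

    difference = mean_over_replicates(randomized mean) - true mean

is near zero when the two vectors are unrelated noise and positive when they
carry concordant signal (a random pairing is then worse than the real one).
The permutation null preserves the reference's bin composition; resampling
with replacement is available as an alternative null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

#: HPA-style level -> numeric mapping used for comparison with 3-level bins
LEVEL_TO_NUMERIC: Mapping[str, float] = {
    "low": 1.0,
    "medium": 2.0,
    "high": 3.0,
    "not detected": np.nan,
    "ascending": 1.0,
    "descending": 1.0,
    "not representative": 1.0,
}


class ComparisonError(ValueError):
    pass


def map_categorical_levels(atlas) -> pd.DataFrame:
    """Convert a categorical atlas to a genes x organs numeric matrix.

    Rows with reliability ``uncertain`` are dropped first; then low/medium/high
    map to 1/2/3, "not detected" to NA, and ascending / descending /
    "not representative" all to 1.
    """
    table = atlas.table
    table = table[table["reliability"] != "uncertain"]
    unknown = set(table["level"]) - set(LEVEL_TO_NUMERIC)
    if unknown:
        raise ComparisonError(f"unknown categorical level(s): {sorted(unknown)}")
    numeric = table.assign(value=table["level"].map(LEVEL_TO_NUMERIC))
    wide = numeric.pivot(index="gene_id", columns="organ", values="value")
    wide.index.name = "gene_id"
    wide.columns.name = None
    return wide.sort_index()


def _aligned_pairs(v1: pd.Series, v2: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    joined = pd.concat({"a": v1, "b": v2}, axis=1, join="inner").dropna()
    if joined.empty:
        raise ComparisonError("no shared genes with values in both vectors")
    return joined["a"].to_numpy(float), joined["b"].to_numpy(float)


def true_edit_distance(v1: pd.Series, v2: pd.Series) -> tuple[pd.Series, float]:
    """Per-protein |bin difference| over shared non-NA genes, and its mean."""
    joined = pd.concat({"a": v1, "b": v2}, axis=1, join="inner").dropna()
    if joined.empty:
        raise ComparisonError("no shared genes with values in both vectors")
    d = (joined["a"] - joined["b"]).abs()
    return d, float(d.mean())


@dataclass
class EditDistanceReport:
    true_distance_mean: float
    randomized_distance_mean: float
    difference: float  # always randomized - true, bit-exact
    n_proteins: int
    n_permutations: int
    seed: int | None


def randomized_edit_distance_difference(
    v1: pd.Series,
    v2: pd.Series,
    n_perm: int = 10,
    seed: int | None = None,
    with_replacement: bool = False,
) -> EditDistanceReport:
    """Randomized-vs-true edit distance between two aligned bin vectors.

    NA pairs are dropped before both the true and the randomized distances so
    both statistics use the same support.  Each replicate shuffles ``v2``
    across proteins (or resamples it with replacement); deterministic given
    ``seed``.
    """
    if n_perm < 1:
        raise ComparisonError("n_perm must be >= 1")
    a, b = _aligned_pairs(v1, v2)
    true_mean = float(np.abs(a - b).mean())
    rng = np.random.default_rng(seed)
    means = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = rng.choice(b, size=b.size, replace=True) if with_replacement else rng.permutation(b)
        means[i] = np.abs(a - shuffled).mean()
    randomized_mean = float(means.mean())
    return EditDistanceReport(
        true_distance_mean=true_mean,
        randomized_distance_mean=randomized_mean,
        difference=randomized_mean - true_mean,
        n_proteins=a.size,
        n_permutations=n_perm,
        seed=seed,
    )


def overlap_summary(genes_a: set[str], genes_b: set[str]) -> dict[str, float]:
    """Percentages of the union that are common / A-only / B-only."""
    union = genes_a | genes_b
    if not union:
        raise ComparisonError("empty union of gene sets")
    n = len(union)
    return {
        "common_pct": 100.0 * len(genes_a & genes_b) / n,
        "a_only_pct": 100.0 * len(genes_a - genes_b) / n,
        "b_only_pct": 100.0 * len(genes_b - genes_a) / n,
        "union_size": float(n),
    }


def continuous_atlas_correlation(
    matrix_a: pd.DataFrame,
    organ_of_sample: pd.Series,
    matrix_b: pd.DataFrame,
    min_shared: int = 3,
) -> pd.Series:
    """Per-organ Pearson r between pipeline abundances and a continuous atlas.

    ``matrix_a`` is genes x samples; its samples are collapsed to organ medians
    over detected values, then both sides are log2-transformed (non-positive
    and missing values dropped pairwise) and correlated over shared genes.
    Organs with fewer than ``min_shared`` shared genes are skipped.
    """
    organs = organ_of_sample.loc[matrix_a.columns]
    medians = matrix_a.T.groupby(organs.values).median().T
    out = {}
    for organ in medians.columns:
        if organ not in matrix_b.columns:
            continue
        joined = pd.concat(
            {"a": medians[organ], "b": matrix_b[organ]}, axis=1, join="inner"
        ).dropna()
        joined = joined[(joined > 0).all(axis=1)]
        if len(joined) < min_shared:
            continue
        la, lb = np.log2(joined["a"]), np.log2(joined["b"])
        out[organ] = float(np.corrcoef(la, lb)[0, 1])
    return pd.Series(out, name="pearson_r").sort_index()
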