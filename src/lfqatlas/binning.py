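"""Rank-bin transformation and batch-wise missing-value rules.

Continuous ppb abundances are not comparable across independently processed
datasets (multiplicative batch effects), but within-run ranks are.  Each MS
run's detected abundances are therefore ranked ascending and cut into
``n_bins`` equal-frequency bins (bin 1 = lowest, bin ``n_bins`` = highest):

    bin(r) = ceil(r * n_bins / m)      r = rank among the m detected entries

Tied values take their minimum rank, so ties always share the lower bin; the
arithmetic is exact integer arithmetic (no floating-point ceil).  Because the
transform depends only on ranks, any strictly increasing distortion of the
abundances — a dataset-wide batch factor, a run-depth factor — leaves the bins
unchanged, which is what makes the binned matrices integrable.

Missing values are resolved per *batch* (all samples of one tissue within one
dataset): a gene undetected in every sample of the batch stays NA (not
detected there); a gene detected in some samples gets bin 1 in the remaining
samples of the batch (present but below detection).

Re-binning to 3 levels (low/medium/high, for comparison with categorical
reference atlases) recomputes the bins from ppb with ``n_bins=3`` rather than
collapsing the 5-level bins, keeping the definition self-consistent; a
collapse mode ({1,2}->1, {3,4}->2, {5}->3) is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from lfqatlas.io_formats import SampleMap


class BinningError(ValueError):
    pass


@dataclass
class BinnedMatrix:
    """Genes x samples with values in {1..n_bins} or NA, plus batch labels."""

    bins: pd.DataFrame  # float dtype to carry NaN; integral values
    n_bins: int
    batch: pd.Series  # sample_id -> (dataset_id, tissue)


def rank_bin_run(ppb: pd.Series | np.ndarray, n_bins: int = 5) -> pd.Series | np.ndarray:
    """Rank-bin one run's ppb vector; missing entries stay missing here.

    Detected entries ranked ascending; rank r of m detected entries gets bin
    ``ceil(r * n_bins / m)``; ties share the bin of their minimum rank.
    """
    if n_bins < 2:
        raise BinningError("n_bins must be >= 2")
    values = np.asarray(ppb, dtype=float) if not isinstance(ppb, pd.Series) else ppb.to_numpy(float)
    out = np.full(values.shape, np.nan)
    detected = ~np.isnan(values)
    m = int(detected.sum())
    if m:
        ranks = rankdata(values[detected], method="min").astype(np.int64)
        out[detected] = -(-ranks * n_bins // m)  # exact ceil division
    if isinstance(ppb, pd.Series):
        return pd.Series(out, index=ppb.index, name=ppb.name)
    return out


def rank_bin_matrix(ppb: pd.DataFrame, n_bins: int = 5) -> pd.DataFrame:
    """Rank-bin every column (run) of a genes x runs ppb matrix independently."""
    return pd.DataFrame(
        {run: rank_bin_run(ppb[run], n_bins=n_bins) for run in ppb.columns},
        index=ppb.index,
    )


def aggregate_runs_to_samples(
    run_bins: pd.DataFrame, sample_map: SampleMap
) -> pd.DataFrame:
    """Collapse per-run bins to per-sample bins.

    A sample with several runs (fractions, replicates of the same sample) gets
    the median of its detected run bins, rounded half up; all runs missing ->
    missing.  With one run per sample this is the identity.
    """
    sample_of_run = sample_map.sample_of_run()
    missing_runs = [r for r in run_bins.columns if r not in sample_of_run.index]
    if missing_runs:
        raise BinningError(f"run(s) absent from the sample map: {missing_runs}")
    grouped = run_bins.T.groupby(sample_of_run.loc[run_bins.columns].values).median().T
    return np.floor(grouped + 0.5).where(grouped.notna())


def apply_batch_missing_rules(
    sample_bins: pd.DataFrame, sample_map: SampleMap, n_bins: int = 5
) -> BinnedMatrix:
    """Resolve missing values batch-wise: all-missing -> NA, partial -> bin 1."""
    batch_of_sample = sample_map.batch_of_sample()
    unassigned = [s for s in sample_bins.columns if s not in batch_of_sample.index]
    if unassigned:
        raise BinningError(f"sample(s) with no batch assignment: {unassigned}")
    bins = sample_bins.copy()
    batch_keys = batch_of_sample.loc[bins.columns]
    labels = pd.Series(["\x1f".join(key) for key in batch_keys], index=bins.columns)
    for label in labels.unique():
        samples = list(labels.index[labels == label])
        block = bins[samples]
        partially_detected = block.notna().any(axis=1)
        fill = block.isna() & partially_detected.to_numpy()[:, None]
        bins.loc[:, samples] = block.where(~fill, 1.0)
    return BinnedMatrix(bins=bins, n_bins=n_bins, batch=batch_keys)


def bin_pipeline(
    ppb: pd.DataFrame, sample_map: SampleMap, n_bins: int = 5
) -> BinnedMatrix:
    """Full path: per-run rank-bin -> sample aggregation -> batch rules."""
    run_bins = rank_bin_matrix(ppb, n_bins=n_bins)
    sample_bins = aggregate_runs_to_samples(run_bins, sample_map)
    return apply_batch_missing_rules(sample_bins, sample_map, n_bins=n_bins)


def rebin(ppb: pd.DataFrame, sample_map: SampleMap, n_bins: int = 3) -> BinnedMatrix:
    """Re-bin from ppb at a coarser resolution (default 3: low/medium/high)."""
    return bin_pipeline(ppb, sample_map, n_bins=n_bins)


def collapse_five_to_three(binned: BinnedMatrix) -> BinnedMatrix:
    """Alternative 3-level mapping by collapsing 5-level bins: {1,2}{3,4}{5}."""
    if binned.n_bins != 5:
        raise BinningError("collapse_five_to_three expects a 5-bin matrix")
    mapped = binned.bins.replace({2.0: 1.0, 3.0: 2.0, 4.0: 2.0, 5.0: 3.0})
    return BinnedMatrix(bins=mapped, n_bins=3, batch=binned.batch)
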