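#!/usr/bin/env python
"""Quality control: cross-dataset decoy FDR and sample-structure diagnostics.

Computes FDR(k) from decoy hits in the unfiltered tables, the pairwise-
complete Pearson correlation of binned abundances, the hierarchical
clustering order and the PCA of samples.  Verifies that samples group by
organ rather than by dataset once abundances are rank-binned.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lfqatlas import binning, io_formats, qc
from lfqatlas.pipeline import detections_across_datasets

ROOT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    out = ROOT / "qc"
    out.mkdir(exist_ok=True)
    sample_map = io_formats.read_sample_map(ROOT / "inputs" / "sdrf.tsv")

    raw = {
        p.stem.split("_", 1)[1]: io_formats.read_protein_groups(p)
        for p in sorted((ROOT / "inputs").glob("proteinGroups_*.txt"))
    }
    detections, decoy_flags = detections_across_datasets(raw)
    fdr = qc.cross_dataset_fdr(detections, decoy_flags, n_datasets=len(raw))
    fdr.to_csv(out / "cross_dataset_fdr.tsv", sep="\t")
    print("decoy-based FDR by minimum dataset count:")
    print((100 * fdr["fdr"]).round(2).rename("fdr_pct").to_string())

    bins = io_formats.read_matrix(ROOT / "bins5.tsv")
    binned = binning.BinnedMatrix(bins=bins, n_bins=5, batch=sample_map.batch_of_sample())
    corr = qc.pairwise_bin_correlation(binned)
    io_formats.write_matrix(corr, out / "sample_correlation.tsv")
    organ = sample_map.organ_of_sample().loc[corr.index]
    same = organ.values[:, None] == organ.values[None, :]
    off = ~np.eye(len(corr), dtype=bool)
    print(f"mean within-organ r = {corr.values[same & off].mean():.3f}, "
          f"between-organ r = {corr.values[~same].mean():.3f}")

    order = qc.cluster_order(corr)
    pd.DataFrame({"sample_id": order.leaf_order}).to_csv(
        out / "cluster_order.tsv", sep="\t", index=False
    )
    pca = qc.pca_on_bins(binned)
    coords = pca.coordinates.iloc[:, :5].copy()
    coords["organ"] = organ.loc[coords.index]
    coords.to_csv(out / "pca_coordinates.tsv", sep="\t")
    print(f"PCA on {pca.n_genes_used} genes quantified in >=50% of samples; "
          f"PC1/PC2 variance fractions "
          f"{pca.explained_variance_ratio[0]:.2f}/{pca.explained_variance_ratio[1]:.2f}")


if __name__ == "__main__":
    main()
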