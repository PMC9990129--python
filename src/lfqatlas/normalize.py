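"""Fraction-of-total (FOT) normalization and gene-level aggregation.

FOT scales every protein group's iBAQ intensity by the total iBAQ signal of
its MS run and expresses the result in parts per billion:

    ppb_i = ibaq_i / sum_j ibaq_j * 1e9        (sum over detected groups)

so each run's detected signal sums to 1e9 exactly (relative error < 1e-9),
removing per-run depth differences while preserving within-run ranks.

Gene aggregation maps each group's majority protein identifiers (isoform
suffixes allowed) to gene identifiers.  A group whose majority ids resolve to
a single gene is kept under that gene — isoform groups of one gene collapse
naturally.  Groups resolving to multiple genes, or containing unmapped
accessions, are excluded and reported in a side table rather than silently
dropped.  When several groups map to the same gene, the per-run gene value is
the median of their detected ppb values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lfqatlas.io_formats import GeneMap, ProteinGroupTable

PPB_TOTAL = 1e9


class NormalizationError(ValueError):
    pass


@dataclass
class GeneAbundanceMatrix:
    """Canonical genes x runs, in ppb, with the groups excluded on the way."""

    values: pd.DataFrame  # index gene_id, columns run names, NaN = not detected
    excluded_groups: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["group_id", "majority_ids", "genes", "reason"])
    )


def fot_normalize(intensities: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """FOT-normalize per-run iBAQ intensities to ppb.

    Accepts a Series (one run) or a DataFrame (rows = groups, columns = runs);
    missing values stay missing.  Scale-invariant: ``fot(c*x) == fot(x)``.
    """
    if isinstance(intensities, pd.Series):
        return fot_normalize(intensities.to_frame("run")).iloc[:, 0]
    if (intensities < 0).any().any():
        bad = intensities.columns[(intensities < 0).any()][0]
        raise NormalizationError(f"negative intensity in run {bad!r}")
    totals = intensities.sum(axis=0, skipna=True)
    empty = totals[intensities.notna().sum(axis=0) == 0]
    if len(empty):
        raise NormalizationError(f"run(s) with no detected intensities: {list(empty.index)}")
    return intensities / totals * PPB_TOTAL


def map_groups_to_genes(
    table: ProteinGroupTable, ppb: pd.DataFrame, gene_map: GeneMap
) -> GeneAbundanceMatrix:
    """Collapse protein groups to canonical genes.

    ``ppb`` shares ``table``'s index (FOT-normalized intensities).  Returns a
    genes x runs matrix plus the excluded-group side table (reasons
    ``multi-gene`` and ``unmapped``).
    """
    gene_of_group: dict[int, str] = {}
    excluded: list[dict] = []
    for group_id, majority in table.meta["majority_protein_ids"].items():
        genes = {gene_map.lookup(acc) for acc in majority}
        if None in genes:
            excluded.append(
                {
                    "group_id": group_id,
                    "majority_ids": ";".join(majority),
                    "genes": ";".join(sorted(g for g in genes if g)),
                    "reason": "unmapped",
                }
            )
        elif len(genes) > 1:
            excluded.append(
                {
                    "group_id": group_id,
                    "majority_ids": ";".join(majority),
                    "genes": ";".join(sorted(genes)),  # type: ignore[arg-type]
                    "reason": "multi-gene",
                }
            )
        elif len(genes) == 1:
            gene_of_group[group_id] = genes.pop()  # type: ignore[assignment]
        else:  # empty majority list
            excluded.append(
                {"group_id": group_id, "majority_ids": "", "genes": "", "reason": "unmapped"}
            )

    kept = ppb.loc[list(gene_of_group)]
    genes = pd.Series(gene_of_group, name="gene_id")
    # median over detected values only; a gene missing in every contributing
    # group for a run stays missing
    values = kept.groupby(genes).median()
    values = values.sort_index()
    values.index.name = "gene_id"
    excluded_df = pd.DataFrame(excluded, columns=["group_id", "majority_ids", "genes", "reason"])
    return GeneAbundanceMatrix(values=values, excluded_groups=excluded_df)


def check_fot_conservation(ppb: pd.DataFrame, rtol: float = 1e-9) -> float:
    """Max relative deviation of per-run detected ppb totals from 1e9."""
    totals = ppb.sum(axis=0, skipna=True)
    rel_err = np.abs(totals - PPB_TOTAL) / PPB_TOTAL
    if (rel_err > rtol).any():
        raise NormalizationError(
            f"FOT conservation violated: max relative error {rel_err.max():.3e}"
        )
    return float(rel_err.max())
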