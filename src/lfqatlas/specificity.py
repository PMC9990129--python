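"""Organ-level bin profiles and specificity classification.

Each gene's binned abundances are summarized to one bin per organ (median of
detected sample bins across all samples of the organ, rounded half up; NA if
the gene is NA in every batch of the organ).  The profile is then classified
with a variant of the Uhlen tissue-specificity scheme operating on bins:

* organ-enriched — exactly one organ whose bin is at least twofold the mean
  bin across all organs;
* group-enriched — a group of 2–7 such organs;
* mixed — everything else.

The mean is taken over *all* organs including the candidate itself, with NA
counted as 0, so absence elsewhere strengthens specificity.  Both choices,
and the inclusive reading of "twofold higher" (bin >= 2 x mean), are exposed
as toggles.  Classification operates on the 5-level profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lfqatlas.binning import BinnedMatrix
from lfqatlas.io_formats import SampleMap

ORGAN_ENRICHED = "organ-enriched"
GROUP_ENRICHED = "group-enriched"
MIXED = "mixed"

GROUP_MIN = 2
GROUP_MAX = 7


def organ_bin_profile(binned: BinnedMatrix, sample_map: SampleMap) -> pd.DataFrame:
    """Summarize a binned genes x samples matrix to genes x organs.

    Per organ: median of detected sample bins over all the organ's samples
    (across datasets), rounded half up; all-NA -> NA.  Organs with zero
    samples in the matrix are simply absent from the output.
    """
    organ_of_sample = sample_map.organ_of_sample()
    organs = organ_of_sample.loc[binned.bins.columns]
    prof = binned.bins.T.groupby(organs.values).median().T
    prof = np.floor(prof + 0.5).where(prof.notna())
    prof = prof[sorted(prof.columns)]
    prof.index.name = "gene_id"
    return prof


@dataclass
class SpecificityResult:
    gene_id: str
    category: str
    enriched_organs: tuple[str, ...]
    mean_bin: float
    threshold: float
    flags: tuple[str, ...] = field(default=())


def classify_specificity(
    profile_row: pd.Series,
    include_self: bool = True,
    na_as_zero: bool = True,
    inclusive: bool = True,
) -> SpecificityResult:
    """Classify one gene's per-organ bin profile.

    ``include_self=False`` switches to the mean over the *other* organs for
    each candidate (the Uhlen variant); ``na_as_zero=False`` drops NA organs
    from the mean; ``inclusive=False`` requires bin > 2 x mean strictly.
    """
    gene_id = str(profile_row.name) if profile_row.name is not None else ""
    values = profile_row.astype(float)
    if values.notna().sum() == 0:
        return SpecificityResult(gene_id, MIXED, (), float("nan"), float("nan"), ("undetected",))
    filled = values.fillna(0.0) if na_as_zero else values

    def passes(organ: str) -> tuple[bool, float, float]:
        if include_self:
            mean = float(filled.mean()) if na_as_zero else float(filled.dropna().mean())
        else:
            others = filled.drop(organ)
            mean = float(others.mean()) if na_as_zero else float(others.dropna().mean())
        thr = 2.0 * mean
        v = values[organ]
        if np.isnan(v):
            return False, mean, thr
        ok = v >= thr if inclusive else v > thr
        return ok, mean, thr

    results = {organ: passes(organ) for organ in values.index}
    enriched = tuple(o for o, (ok, _, _) in results.items() if ok)
    # with include_self the mean/threshold are gene-level constants
    mean_bin = results[values.index[0]][1]
    threshold = results[values.index[0]][2]
    if len(enriched) == 1:
        category = ORGAN_ENRICHED
    elif GROUP_MIN <= len(enriched) <= GROUP_MAX:
        category = GROUP_ENRICHED
    else:
        category = MIXED
        enriched = ()
    return SpecificityResult(gene_id, category, enriched, mean_bin, threshold)


def classify_profiles(
    profile: pd.DataFrame,
    include_self: bool = True,
    na_as_zero: bool = True,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Classify every gene of a genes x organs profile; returns a tidy table."""
    rows = []
    for gene_id, row in profile.iterrows():
        res = classify_specificity(
            row, include_self=include_self, na_as_zero=na_as_zero, inclusive=inclusive
        )
        rows.append(
            {
                "gene_id": gene_id,
                "category": res.category,
                "enriched_organs": ";".join(res.enriched_organs),
                "mean_bin": res.mean_bin,
                "threshold": res.threshold,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def enriched_gene_lists(classified: pd.DataFrame) -> dict[str, list[str]]:
    """Per organ, the organ-enriched plus group-enriched genes (for external
    enrichment tools)."""
    lists: dict[str, list[str]] = {}
    sel = classified[classified["category"].isin([ORGAN_ENRICHED, GROUP_ENRICHED])]
    for gene_id, row in sel.iterrows():
        for organ in str(row["enriched_organs"]).split(";"):
            if organ:
                lists.setdefault(organ, []).append(str(gene_id))
    return {o: sorted(g) for o, g in sorted(lists.items())}
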