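"""Readers and writers for the external formats the pipeline touches.

The protein-group dialect follows MaxQuant ``proteinGroups.txt``: tab-separated,
one row per protein group, per-run intensity columns named ``iBAQ <run>``,
``"+"`` flags in ``Reverse`` (decoy) and ``Potential contaminant``.  Sample
metadata is an SDRF-like TSV relating MS runs to samples, tissues, organs and
datasets.  Matrices (genes x samples) are TSV with ``NA`` for missing cells and
round-trip exactly through :func:`write_matrix` / :func:`read_matrix`.

Header matching is exact after whitespace trimming; synonyms are declared
explicitly (``column_synonyms`` argument of :func:`read_sample_map`), never
guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

ATLAS_LEVELS = (
    "not detected",
    "low",
    "medium",
    "high",
    "ascending",
    "descending",
    "not representative",
)
ATLAS_RELIABILITIES = ("enhanced", "supported", "approved", "uncertain")

IBAQ_PREFIX = "iBAQ "


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


@dataclass
class ProteinGroupTable:
    """Protein groups of one dataset.

    ``meta`` is indexed by ``group_id`` and carries ``protein_ids`` and
    ``majority_protein_ids`` (lists of accessions), ``psm_count`` (dataset-total
    MS/MS count of the group), ``is_decoy`` and ``is_contaminant``.  ``ibaq``
    shares the index; its columns are run names and NaN means not detected
    (MaxQuant writes 0 for non-detection; zeros are read as missing).
    """

    meta: pd.DataFrame
    ibaq: pd.DataFrame

    @property
    def runs(self) -> list[str]:
        return list(self.ibaq.columns)

    def __len__(self) -> int:
        return len(self.meta)


@dataclass
class SampleMap:
    """Run -> sample -> tissue -> organ -> dataset -> condition relations.

    A *batch* is all samples of one tissue within one dataset; it is the unit
    within which the missing-value rules of the rank-bin transform apply.
    A *tissue* is a distinct functional or structural region within an organ
    (e.g. the left ventricle is a tissue of the heart).
    """

    table: pd.DataFrame  # columns run_name, sample_id, tissue, organ, dataset_id, condition

    def __post_init__(self) -> None:
        dup = self.table["run_name"].duplicated()
        if dup.any():
            raise FormatError(
                f"duplicate run names in sample map: {sorted(self.table.loc[dup, 'run_name'])}"
            )
        multi = self.table.groupby("run_name")["sample_id"].nunique()
        if (multi > 1).any():
            raise FormatError("a run must belong to exactly one sample")

    def batch_of_sample(self) -> pd.Series:
        """sample_id -> (dataset_id, tissue) batch key."""
        per_sample = self.table.drop_duplicates("sample_id").set_index("sample_id")
        return pd.Series(
            list(zip(per_sample["dataset_id"], per_sample["tissue"])),
            index=per_sample.index,
        )

    def organ_of_sample(self) -> pd.Series:
        per_sample = self.table.drop_duplicates("sample_id").set_index("sample_id")
        return per_sample["organ"]

    def sample_of_run(self) -> pd.Series:
        return self.table.set_index("run_name")["sample_id"]

    @property
    def batches(self) -> list[tuple[str, str]]:
        return sorted(set(zip(self.table["dataset_id"], self.table["tissue"])))


@dataclass
class GeneMap:
    """Protein accession -> stable gene identifier.

    Isoform accessions (``P1-2``) are entries of their own; an unknown
    accession is distinguishable from a mapped one (:meth:`lookup` -> None).
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def lookup(self, accession: str) -> str | None:
        return self.mapping.get(accession)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class CategoricalAtlas:
    """HPA-style categorical abundance: one level per (gene, organ)."""

    table: pd.DataFrame  # columns gene_id, organ, level, reliability

    def __post_init__(self) -> None:
        bad_level = set(self.table["level"]) - set(ATLAS_LEVELS)
        if bad_level:
            raise FormatError(
                f"unknown categorical level(s) {sorted(bad_level)}; allowed: {list(ATLAS_LEVELS)}"
            )
        bad_rel = set(self.table["reliability"]) - set(ATLAS_RELIABILITIES)
        if bad_rel:
            raise FormatError(
                f"unknown reliability score(s) {sorted(bad_rel)}; allowed: {list(ATLAS_RELIABILITIES)}"
            )
        if self.table.duplicated(["gene_id", "organ"]).any():
            raise FormatError("(gene_id, organ) pairs must be unique in a categorical atlas")


# ---------------------------------------------------------------------------
# proteinGroups.txt


def _split_ids(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    return [p.strip() for p in str(cell).split(";") if p.strip()]


def read_protein_groups(path: str | Path, psm_column: str = "MS/MS count") -> ProteinGroupTable:
    """Parse a MaxQuant-style ``proteinGroups.txt``.

    Empty and ``0`` iBAQ cells become missing.  ``psm_column`` names the PSM
    count column; the MaxQuant default is the all-peptide "MS/MS count", but a
    razor+unique variant can be supplied.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]

    for col in ("Majority protein IDs", psm_column):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    ibaq_cols = [c for c in df.columns if c.startswith(IBAQ_PREFIX) and c != "iBAQ peptides"]
    if not ibaq_cols:
        raise FormatError(f"{path.name}: no 'iBAQ <run>' intensity columns found")

    meta = pd.DataFrame(index=pd.RangeIndex(len(df), name="group_id"))
    majority = df["Majority protein IDs"].map(_split_ids)
    if "Protein IDs" in df.columns:
        protein_ids = df["Protein IDs"].map(_split_ids)
        # the majority list is by definition a subset of the full group
        protein_ids = [
            sorted(set(p) | set(m), key=(p + m).index) if not set(m) <= set(p) else p
            for p, m in zip(protein_ids, majority)
        ]
    else:
        protein_ids = list(majority)
    meta["protein_ids"] = protein_ids
    meta["majority_protein_ids"] = list(majority)

    psm_raw = df[psm_column].str.strip().replace("", "0")
    try:
        meta["psm_count"] = psm_raw.astype(float).round().astype(int)
    except ValueError as exc:
        raise FormatError(f"{path.name}: non-numeric {psm_column!r} value: {exc}") from exc
    if (meta["psm_count"] < 0).any():
        raise FormatError(f"{path.name}: negative PSM count")

    meta["is_decoy"] = (
        df["Reverse"].str.strip().eq("+") if "Reverse" in df.columns else False
    )
    meta["is_contaminant"] = (
        df["Potential contaminant"].str.strip().eq("+")
        if "Potential contaminant" in df.columns
        else False
    )

    ibaq = pd.DataFrame(index=meta.index)
    for col in ibaq_cols:
        raw = df[col].str.strip()
        vals = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = vals.isna() & raw.ne("") & raw.str.lower().ne("nan")
        if bad.any():
            raise FormatError(
                f"{path.name}: non-numeric intensity in column {col!r} at row {int(bad.idxmax())}"
            )
        vals = vals.mask(vals == 0)  # MaxQuant writes 0 for non-detection
        if (vals < 0).any():
            raise FormatError(f"{path.name}: negative intensity in column {col!r}")
        ibaq[col[len(IBAQ_PREFIX):]] = vals

    return ProteinGroupTable(meta=meta, ibaq=ibaq)


def write_protein_groups(table: ProteinGroupTable, path: str | Path) -> None:
    """Write a :class:`ProteinGroupTable` in the dialect :func:`read_protein_groups` reads."""
    out = pd.DataFrame(
        {
            "Protein IDs": [";".join(ids) for ids in table.meta["protein_ids"]],
            "Majority protein IDs": [";".join(ids) for ids in table.meta["majority_protein_ids"]],
        }
    )
    for run in table.ibaq.columns:
        out[IBAQ_PREFIX + run] = table.ibaq[run].fillna(0.0).map(repr)
    out["MS/MS count"] = table.meta["psm_count"].values
    out["Reverse"] = np.where(table.meta["is_decoy"], "+", "")
    out["Potential contaminant"] = np.where(table.meta["is_contaminant"], "+", "")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample metadata

#: default header synonyms: canonical field -> accepted column names
SAMPLE_MAP_SYNONYMS: Mapping[str, tuple[str, ...]] = {
    "run_name": ("run_name", "comment[data file]", "assay name", "data file"),
    "sample_id": ("sample_id", "source name", "sample"),
    "tissue": ("tissue", "characteristics[organism part]", "organism part"),
    "organ": ("organ", "characteristics[organ]"),
    "dataset_id": ("dataset_id", "comment[dataset]", "dataset"),
    "condition": ("condition", "characteristics[disease]", "disease"),
}


def read_sample_map(
    path: str | Path,
    column_synonyms: Mapping[str, tuple[str, ...]] | None = None,
) -> SampleMap:
    """Read an SDRF-like TSV relating runs to samples, tissues, organs, datasets."""
    syn = dict(SAMPLE_MAP_SYNONYMS)
    if column_synonyms:
        syn.update(column_synonyms)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lower = {c.strip().lower(): c for c in df.columns}
    cols = {}
    for field_name, names in syn.items():
        for name in names:
            if name.lower() in lower:
                cols[field_name] = lower[name.lower()]
                break
        else:
            raise FormatError(
                f"{Path(path).name}: no column for {field_name!r} (accepted: {list(names)})"
            )
    out = pd.DataFrame({k: df[v].str.strip() for k, v in cols.items()})
    return SampleMap(table=out.reset_index(drop=True))


def write_sample_map(sample_map: SampleMap, path: str | Path) -> None:
    sample_map.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene map, categorical atlas, matrices


def read_gene_map(path: str | Path) -> GeneMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("accession", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing mandatory column {col!r}")
    dup = df["accession"].duplicated()
    if dup.any():
        raise FormatError(
            f"{Path(path).name}: accession mapped more than once: {sorted(df.loc[dup, 'accession'])}"
        )
    return GeneMap(mapping=dict(zip(df["accession"], df["gene_id"])))


def write_gene_map(gene_map: GeneMap, path: str | Path) -> None:
    pd.DataFrame(
        {"accession": list(gene_map.mapping), "gene_id": list(gene_map.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_categorical_atlas(path: str | Path) -> CategoricalAtlas:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_id", "organ", "level", "reliability"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing mandatory column {col!r}")
    return CategoricalAtlas(table=df[["gene_id", "organ", "level", "reliability"]].copy())


def write_categorical_atlas(atlas: CategoricalAtlas, path: str | Path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix as TSV; missing cells become ``NA``."""
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=["NA"],
        keep_default_na=False,
        float_precision="round_trip",
    )
    df.index.name = "gene_id"
    df.index = df.index.astype(str)
    return df
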