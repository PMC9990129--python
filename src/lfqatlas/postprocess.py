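"""Row-level filtering of protein-group tables.

Groups flagged as decoys (reversed-sequence hits) or potential contaminants,
and groups supported by fewer than 2 peptide-spectrum matches, are removed
before any quantification.  A row failing several criteria is counted once in
the report, with precedence decoy > contaminant > low PSM, so the report is
deterministic and its counts reconcile: |input| = |output| + sum(removed).
"""

from __future__ import annotations

from dataclasses import dataclass

from lfqatlas.io_formats import ProteinGroupTable


@dataclass
class FilterReport:
    n_input: int
    n_decoy: int
    n_contaminant: int
    n_low_psm: int

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_decoy - self.n_contaminant - self.n_low_psm

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "decoy": self.n_decoy,
            "contaminant": self.n_contaminant,
            "low_psm": self.n_low_psm,
            "output": self.n_output,
        }


def filter_protein_groups(
    table: ProteinGroupTable, min_psm: int = 2
) -> tuple[ProteinGroupTable, FilterReport]:
    """Remove decoys, contaminants and groups with fewer than ``min_psm`` PSMs.

    Returns the surviving rows in their original order together with a
    :class:`FilterReport` of counts removed per reason.  Idempotent.
    """
    meta = table.meta
    decoy = meta["is_decoy"].to_numpy(bool)
    contam = meta["is_contaminant"].to_numpy(bool) & ~decoy
    low_psm = (meta["psm_count"].to_numpy() < min_psm) & ~decoy & ~meta[
        "is_contaminant"
    ].to_numpy(bool)
    keep = ~(decoy | contam | low_psm)
    report = FilterReport(
        n_input=len(meta),
        n_decoy=int(decoy.sum()),
        n_contaminant=int(contam.sum()),
        n_low_psm=int(low_psm.sum()),
    )
    return (
        ProteinGroupTable(meta=meta.loc[keep].copy(), ibaq=table.ibaq.loc[keep].copy()),
        report,
    )
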