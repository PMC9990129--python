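#!/usr/bin/env python
"""Generate the synthetic multi-dataset study used by the downstream analyses.

Writes MaxQuant-style protein-group tables (one per dataset), SDRF-like
sample metadata, the accession->gene map, the ground-truth table and the two
reference atlases under results/study/inputs/.
"""

from pathlib import Path

from lfqatlas import io_formats, synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results" / "study" / "inputs"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = syn.SimulationConfig(seed=SEED)
    truth = syn.generate_truth(config)
    tables, sample_map = syn.simulate_study(truth, config)
    for d, table in enumerate(tables):
        io_formats.write_protein_groups(table, OUT / f"proteinGroups_DS{d + 1}.txt")
    io_formats.write_sample_map(sample_map, OUT / "sdrf.tsv")
    io_formats.write_gene_map(truth.gene_map(), OUT / "gene_map.tsv")
    truth.to_frame().to_csv(OUT / "truth.tsv", sep="\t", index=False)
    categorical, continuous = syn.emit_reference_atlases(truth, noise_rate=0.0, seed=SEED)
    io_formats.write_categorical_atlas(categorical, OUT / "atlas_categorical.tsv")
    io_formats.write_matrix(continuous, OUT / "atlas_continuous.tsv")

    counts = truth.specificity_class.value_counts()
    print(f"simulated {config.n_datasets} datasets x {len(tables[0].runs)} runs, "
          f"{config.n_genes} genes ({counts.get('organ-enriched', 0)} organ-enriched, "
          f"{counts.get('group-enriched', 0)} group-enriched), "
          f"{len(truth.decoy_ids)} decoys, {len(truth.false_target_genes)} planted false targets")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
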