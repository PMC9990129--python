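"""End-to-end orchestration: per-dataset processing, pooling, integration, QC.

The architectural commitment mirrors the way a growing atlas is maintained:
every dataset is processed strictly independently (filter -> FOT -> gene
mapping), so adding a dataset later never changes the per-dataset matrices
already computed; integration happens only afterwards, through the rank-bin
transform.  Every stage reads the previous stage's files and writes TSVs, so
each is runnable standalone and the whole artifact directory is a pure
function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from lfqatlas import binning, compare, io_formats, normalize, postprocess, qc, specificity
from lfqatlas import synthetic


class PipelineError(RuntimeError):
    pass


DEFAULT_PARAMS: dict[str, Any] = {
    "min_psm": 2,
    "n_bins": 5,
    "rebin_bins": 3,
    "psm_column": "MS/MS count",
    "n_permutations": 10,
    "pca_min_fraction": 0.5,
    "atlas_noise_rate": 0.0,
}


def process_dataset(
    table: io_formats.ProteinGroupTable,
    gene_map: io_formats.GeneMap,
    min_psm: int = 2,
) -> tuple[normalize.GeneAbundanceMatrix, postprocess.FilterReport]:
    """Filter -> FOT-normalize -> collapse to genes, for one dataset."""
    filtered, report = postprocess.filter_protein_groups(table, min_psm=min_psm)
    ppb = normalize.fot_normalize(filtered.ibaq)
    normalize.check_fot_conservation(ppb)
    gene_matrix = normalize.map_groups_to_genes(filtered, ppb, gene_map)
    return gene_matrix, report


def group_key(majority_ids: list[str]) -> str:
    """Cross-dataset identity of a protein group: its sorted majority ids."""
    return ";".join(sorted(majority_ids))


def detections_across_datasets(
    tables: Mapping[str, io_formats.ProteinGroupTable],
) -> tuple[dict[str, set[str]], dict[str, bool]]:
    """Per protein-group key, the datasets where it has >=1 detected intensity.

    Consumes *unfiltered* tables so decoys are present.  Contaminants are not
    meaningful for the target/decoy bookkeeping and are left out.
    """
    detections: dict[str, set[str]] = {}
    is_decoy: dict[str, bool] = {}
    for dataset_id, table in tables.items():
        detected = table.ibaq.notna().any(axis=1)
        for group_id, majority in table.meta["majority_protein_ids"].items():
            if table.meta.at[group_id, "is_contaminant"]:
                continue
            if not detected.get(group_id, False):
                continue
            key = group_key(majority)
            detections.setdefault(key, set()).add(dataset_id)
            is_decoy[key] = bool(table.meta.at[group_id, "is_decoy"])
    return detections, is_decoy


def _write_yaml(data: Mapping, path: Path) -> None:
    path.write_text(yaml.safe_dump(dict(data), sort_keys=True))


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path, seed: int | None = None) -> Path:
    """Run the full pipeline into ``out_dir``; returns the artifact directory.

    ``config`` either names input files (``datasets``, ``sample_map``,
    ``gene_map``, optional ``categorical_atlas`` / ``continuous_atlas``) or
    contains a ``simulate`` block of :class:`~lfqatlas.synthetic.SimulationConfig`
    fields, in which case the inputs are generated first and written under
    ``inputs/`` so every later stage still runs from files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}

    # ------------------------------------------------------------------ inputs
    stage = "inputs"
    try:
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"])
            if seed is not None:
                sim_kwargs["seed"] = seed
            sim = synthetic.SimulationConfig(**sim_kwargs)
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            truth = synthetic.generate_truth(sim)
            tables, sample_map = synthetic.simulate_study(truth, sim)
            dataset_paths = {}
            for d, table in enumerate(tables):
                dataset_id = f"DS{d + 1}"
                path = inputs / f"proteinGroups_{dataset_id}.txt"
                io_formats.write_protein_groups(table, path)
                dataset_paths[dataset_id] = path
            io_formats.write_sample_map(sample_map, inputs / "sdrf.tsv")
            io_formats.write_gene_map(truth.gene_map(), inputs / "gene_map.tsv")
            truth.to_frame().to_csv(inputs / "truth.tsv", sep="\t", index=False)
            categorical, continuous = synthetic.emit_reference_atlases(
                truth, noise_rate=params["atlas_noise_rate"], seed=sim.seed
            )
            io_formats.write_categorical_atlas(categorical, inputs / "atlas_categorical.tsv")
            io_formats.write_matrix(continuous, inputs / "atlas_continuous.tsv")
            config = {
                **config,
                "datasets": {k: str(v) for k, v in dataset_paths.items()},
                "sample_map": str(inputs / "sdrf.tsv"),
                "gene_map": str(inputs / "gene_map.tsv"),
                "categorical_atlas": str(inputs / "atlas_categorical.tsv"),
                "continuous_atlas": str(inputs / "atlas_continuous.tsv"),
            }

        dataset_paths = {k: Path(v) for k, v in config["datasets"].items()}
        sample_map = io_formats.read_sample_map(config["sample_map"])
        gene_map = io_formats.read_gene_map(config["gene_map"])
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    summary_rows: list[dict[str, Any]] = []

    # ------------------------------------------------- per-dataset processing
    stage = "per-dataset"
    try:
        raw_tables: dict[str, io_formats.ProteinGroupTable] = {}
        gene_matrices: dict[str, pd.DataFrame] = {}
        ds_dir = out / "datasets"
        ds_dir.mkdir(exist_ok=True)
        for dataset_id in sorted(dataset_paths):
            table = io_formats.read_protein_groups(
                dataset_paths[dataset_id], psm_column=params["psm_column"]
            )
            raw_tables[dataset_id] = table
            missing = set(table.runs) - set(sample_map.table["run_name"])
            if missing:
                raise PipelineError(
                    f"run(s) of {dataset_id} absent from the sample map: {sorted(missing)}"
                )
            matrix, report = process_dataset(table, gene_map, min_psm=params["min_psm"])
            io_formats.write_matrix(matrix.values, ds_dir / f"{dataset_id}_gene_ppb.tsv")
            matrix.excluded_groups.to_csv(
                ds_dir / f"{dataset_id}_excluded_groups.tsv", sep="\t", index=False
            )
            gene_matrices[dataset_id] = matrix.values
            summary_rows.append(
                {
                    "dataset_id": dataset_id,
                    **report.as_dict(),
                    "excluded_multi_gene": int(
                        (matrix.excluded_groups["reason"] == "multi-gene").sum()
                    ),
                    "excluded_unmapped": int(
                        (matrix.excluded_groups["reason"] == "unmapped").sum()
                    ),
                    "genes_quantified": matrix.values.shape[0],
                    "runs": matrix.values.shape[1],
                }
            )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------------------ integration
    stage = "binning"
    try:
        pooled = pd.concat(
            [gene_matrices[d] for d in sorted(gene_matrices)], axis=1, join="outer"
        ).sort_index()
        io_formats.write_matrix(pooled, out / "pooled_gene_ppb.tsv")
        binned5 = binning.bin_pipeline(pooled, sample_map, n_bins=params["n_bins"])
        binned3 = binning.rebin(pooled, sample_map, n_bins=params["rebin_bins"])
        io_formats.write_matrix(binned5.bins, out / "bins5.tsv")
        io_formats.write_matrix(binned3.bins, out / "bins3.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "specificity"
    try:
        profile5 = specificity.organ_bin_profile(binned5, sample_map)
        io_formats.write_matrix(profile5, out / "organ_bin_profile.tsv")
        classified = specificity.classify_profiles(profile5)
        classified.to_csv(out / "specificity.tsv", sep="\t")
        lists = specificity.enriched_gene_lists(classified)
        pd.DataFrame(
            [(o, ";".join(g)) for o, g in lists.items()], columns=["organ", "genes"]
        ).to_csv(out / "organ_gene_lists.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "qc"
    try:
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        detections, decoy_flags = detections_across_datasets(raw_tables)
        fdr = qc.cross_dataset_fdr(detections, decoy_flags, n_datasets=len(raw_tables))
        fdr.to_csv(qc_dir / "cross_dataset_fdr.tsv", sep="\t")
        corr = qc.pairwise_bin_correlation(binned5)
        io_formats.write_matrix(corr, qc_dir / "sample_correlation.tsv")
        order = qc.cluster_order(corr)
        pd.DataFrame({"sample_id": order.leaf_order}).to_csv(
            qc_dir / "cluster_order.tsv", sep="\t", index=False
        )
        pca = qc.pca_on_bins(binned5, min_fraction=params["pca_min_fraction"])
        coords = pca.coordinates.iloc[:, : min(5, pca.coordinates.shape[1])].copy()
        coords["organ"] = sample_map.organ_of_sample().loc[coords.index]
        coords.to_csv(qc_dir / "pca_coordinates.tsv", sep="\t")
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(pca.explained_variance_ratio))],
                "variance_fraction": pca.explained_variance_ratio,
            }
        ).to_csv(qc_dir / "pca_variance.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "compare"
    compare_dir = out / "compare"
    try:
        if config.get("categorical_atlas"):
            compare_dir.mkdir(exist_ok=True)
            atlas = io_formats.read_categorical_atlas(config["categorical_atlas"])
            ref = compare.map_categorical_levels(atlas)
            profile3 = specificity.organ_bin_profile(binned3, sample_map)
            rng_seed = seed if seed is not None else 0
            rows = []
            for organ in sorted(set(profile3.columns) & set(ref.columns)):
                report = compare.randomized_edit_distance_difference(
                    profile3[organ],
                    ref[organ],
                    n_perm=params["n_permutations"],
                    seed=rng_seed,
                )
                rows.append(
                    {
                        "organ": organ,
                        "n_proteins": report.n_proteins,
                        "true_mean": report.true_distance_mean,
                        "randomized_mean": report.randomized_distance_mean,
                        "difference": report.difference,
                        "n_permutations": report.n_permutations,
                        "seed": rng_seed,
                    }
                )
                pipeline_genes = set(profile3.index[profile3[organ].notna()])
                ref_genes = set(ref.index[ref[organ].notna()])
                ov = compare.overlap_summary(pipeline_genes, ref_genes)
                rows[-1].update(
                    {
                        "overlap_common_pct": ov["common_pct"],
                        "overlap_pipeline_only_pct": ov["a_only_pct"],
                        "overlap_reference_only_pct": ov["b_only_pct"],
                    }
                )
            pd.DataFrame(rows).to_csv(compare_dir / "categorical_atlas.tsv", sep="\t", index=False)
        if config.get("continuous_atlas"):
            compare_dir.mkdir(exist_ok=True)
            cont = io_formats.read_matrix(config["continuous_atlas"])
            organ_of_run = sample_map.table.set_index("run_name")["organ"]
            corr_by_organ = compare.continuous_atlas_correlation(pooled, organ_of_run, cont)
            corr_by_organ.rename_axis("organ").to_frame().to_csv(
                compare_dir / "continuous_atlas.tsv", sep="\t"
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------------------- provenance
    summary = pd.DataFrame(summary_rows)
    all_genes = set()
    for m in gene_matrices.values():
        all_genes.update(m.index)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    def _relativize(value: Any) -> Any:
        # recorded relative to the artifact dir so reruns into different
        # directories stay byte-identical
        if isinstance(value, (str, Path)):
            try:
                return str(Path(value).resolve().relative_to(out.resolve()))
            except ValueError:
                return str(value)
        if isinstance(value, dict):
            return {k: _relativize(v) for k, v in value.items()}
        return value

    manifest = {
        "params": params,
        "seed": seed,
        "datasets": sorted(dataset_paths),
        "genes_quantified_total": len(all_genes),
        "samples": int(binned5.bins.shape[1]),
        "config": {k: _relativize(v) for k, v in config.items() if k != "params"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    _write_yaml({"params": params}, out / "params.yaml")
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
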