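"""Synthetic multi-dataset label-free proteomics inputs with known ground truth.

The generator emulates the structure of a collection of independently
acquired and independently searched tissue proteomics datasets:

* a log-normal global abundance distribution spanning ~5 orders of magnitude;
* organ-specific genes whose abundance is elevated by a multiplicative fold
  in one organ (organ-enriched) or in a group of 2-7 organs (group-enriched),
  while their level elsewhere sits near the detection limit — the biological
  signature of tissue-restricted expression;
* multiplicative per-dataset batch factors and per-run depth factors (these
  are strictly increasing transforms of each run, so rank-bins are invariant
  to them by construction — the regime the rank-bin integration exploits);
* abundance-dependent missingness: detection is Bernoulli with a logistic
  probability in log10 intensity;
* decoy rows with abundances drawn from the bottom half of the target
  distribution and detection independent across datasets, plus an equal
  number of *planted false targets* drawn from the same model but flagged as
  targets, so the decoy-based FDR estimate can be checked against a realized
  FDR;
* contaminant rows, isoform protein groups that must collapse to one gene,
  multi-gene groups that must be excluded, and a configured fraction of
  groups with fewer than 2 PSMs.

All randomness flows through :class:`numpy.random.Generator` (PCG64) seeded
from the config seed, so outputs are identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from lfqatlas.io_formats import (
    CategoricalAtlas,
    GeneMap,
    ProteinGroupTable,
    SampleMap,
)

ORGAN_POOL = [
    "brain",
    "heart",
    "liver",
    "kidney",
    "lung",
    "testis",
    "pancreas",
    "colon",
    "ovary",
    "spleen",
    "stomach",
    "esophagus",
]

ORGAN_ENRICHED = "organ-enriched"
GROUP_ENRICHED = "group-enriched"
MIXED = "mixed"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of the simulation.

    Defaults describe a three-dataset, six-organ design of 2,000 genes with
    eightfold organ enrichment, moderate dataset batch effects and
    abundance-dependent dropout — a desk-scale stand-in for a multi-dataset
    tissue atlas reanalysis.
    """

    n_genes: int = 2000
    n_datasets: int = 3
    n_organs: int = 6
    organs_per_dataset: int = 6
    tissues_per_organ: int = 2
    samples_per_tissue: int = 3
    runs_per_sample: int = 1
    frac_organ_enriched: float = 0.05
    frac_group_enriched: float = 0.05
    enrichment_fold: float = 8.0
    baseline_log10_median: float = 5.0
    baseline_log10_sd: float = 1.0
    #: off-organ level of enriched genes: offset below the global median (log10)
    restricted_log10_offset: float = 0.55
    restricted_log10_sd: float = 0.05
    batch_log10_sd: float = 0.3
    run_depth_log10_sd: float = 0.1
    noise_log10_sd: float = 0.08
    #: detection midpoint as a percentile of the baseline distribution; None = no dropout
    dropout_midpoint_percentile: float | None = 30.0
    #: logistic steepness per log10 intensity unit
    dropout_steepness: float = 4.0
    decoy_fraction: float = 0.05
    false_target_fraction: float = 0.05
    contaminant_count: int = 10
    isoform_fraction: float = 0.10
    multi_gene_group_count: int = 5
    low_psm_fraction: float = 0.05
    seed: int = 1

    def validate(self) -> None:
        counts = (
            self.n_genes,
            self.n_datasets,
            self.n_organs,
            self.organs_per_dataset,
            self.tissues_per_organ,
            self.samples_per_tissue,
            self.runs_per_sample,
        )
        if any(c < 1 for c in counts):
            raise SimulationError("all design counts must be positive")
        if self.organs_per_dataset > self.n_organs:
            raise SimulationError("organs_per_dataset cannot exceed n_organs")
        for frac in (
            self.frac_organ_enriched,
            self.frac_group_enriched,
            self.decoy_fraction,
            self.false_target_fraction,
            self.isoform_fraction,
            self.low_psm_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError("fractions must be in [0, 1]")
        if self.frac_organ_enriched + self.frac_group_enriched > 1.0:
            raise SimulationError("enriched fractions exceed 1")
        if self.enrichment_fold < 1.0:
            raise SimulationError("enrichment_fold must be >= 1")
        if self.frac_group_enriched > 0 and self.n_organs < 2:
            raise SimulationError("group-enriched genes require at least 2 organs")


@dataclass
class TruthModel:
    """Ground truth behind a simulation."""

    genes: list[str]
    organs: list[str]
    baseline_abundance: pd.Series  # gene -> positive scale (off-organ level)
    organ_effects: pd.DataFrame  # genes x organs multiplicative folds (>= 1)
    specificity_class: pd.Series  # gene -> organ-enriched | group-enriched | mixed
    enriched_organs: dict[str, tuple[str, ...]]
    isoform_count: pd.Series  # gene -> positive int
    decoy_ids: list[str] = field(default_factory=list)
    decoy_abundance: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    false_target_genes: list[str] = field(default_factory=list)
    false_target_abundance: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def accession_of_gene(self, gene: str) -> str:
        return gene.replace("G", "P", 1)

    def gene_map(self) -> GeneMap:
        mapping: dict[str, str] = {}
        for gene in self.genes:
            acc = self.accession_of_gene(gene)
            mapping[acc] = gene
            for j in range(1, int(self.isoform_count[gene]) + 1):
                mapping[f"{acc}-{j}"] = gene
        for fg in self.false_target_genes:
            mapping[fg.replace("FG", "FP", 1)] = fg
        return GeneMap(mapping=mapping)

    def true_organ_abundance(self) -> pd.DataFrame:
        """Expected (noise-free) abundance per gene and organ."""
        return self.organ_effects.mul(self.baseline_abundance, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.genes,
                "class": self.specificity_class.loc[self.genes].values,
                "enriched_organs": [
                    ";".join(self.enriched_organs.get(g, ())) for g in self.genes
                ],
                "baseline": self.baseline_abundance.loc[self.genes].values,
                "isoform_count": self.isoform_count.loc[self.genes].values,
            }
        )


def _detection_midpoint(config: SimulationConfig) -> float | None:
    """Log10-intensity at which detection probability is 1/2.

    Expressed as a percentile of the *global* log-normal baseline
    distribution, so it has the same meaning whatever the abundance scale.
    """
    if config.dropout_midpoint_percentile is None:
        return None
    from scipy.stats import norm

    z = norm.ppf(config.dropout_midpoint_percentile / 100.0)
    return config.baseline_log10_median + z * config.baseline_log10_sd


def generate_truth(config: SimulationConfig) -> TruthModel:
    """Draw the ground-truth model: classes, folds, baselines, isoforms.

    Organ- and group-enriched genes draw their off-organ baseline from a
    narrow band just below the detection midpoint (tissue-restricted proteins
    are near or below the detection limit outside their organs); the
    configured fold lifts them into the quantifiable range where they are
    enriched.  Mixed genes draw from the global log-normal.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    organs = [
        ORGAN_POOL[i] if i < len(ORGAN_POOL) else f"organ{i + 1}"
        for i in range(config.n_organs)
    ]
    width = len(str(config.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]

    n_oe = round(config.n_genes * config.frac_organ_enriched)
    n_ge = round(config.n_genes * config.frac_group_enriched)
    order = rng.permutation(config.n_genes)
    classes = pd.Series(MIXED, index=genes, name="class")
    oe_genes = [genes[i] for i in order[:n_oe]]
    ge_genes = [genes[i] for i in order[n_oe : n_oe + n_ge]]
    classes.loc[oe_genes] = ORGAN_ENRICHED
    classes.loc[ge_genes] = GROUP_ENRICHED

    log10_base = pd.Series(
        config.baseline_log10_median + rng.normal(0.0, config.baseline_log10_sd, config.n_genes),
        index=genes,
    )
    restricted = classes != MIXED
    log10_base[restricted] = (
        config.baseline_log10_median
        - config.restricted_log10_offset
        + rng.normal(0.0, config.restricted_log10_sd, int(restricted.sum()))
    )
    baseline = 10.0 ** log10_base

    folds = pd.DataFrame(1.0, index=genes, columns=organs)
    enriched: dict[str, tuple[str, ...]] = {}
    for g in oe_genes:
        organ = organs[rng.integers(config.n_organs)]
        folds.loc[g, organ] = config.enrichment_fold
        enriched[g] = (organ,)
    # group sizes are capped at the largest size the twofold-over-mean rule
    # can detect at bin 5 for this organ count (k <= 3*n_organs/8); beyond it
    # the enriched organs dominate the mean and the planted truth would be
    # unlearnable by construction
    group_max = min(7, max(2, (3 * config.n_organs) // 8))
    for g in ge_genes:
        k = int(rng.integers(2, group_max + 1))
        chosen = tuple(sorted(rng.choice(organs, size=k, replace=False)))
        folds.loc[g, list(chosen)] = config.enrichment_fold
        enriched[g] = chosen

    iso = pd.Series(1, index=genes, dtype=int)
    multi = rng.random(config.n_genes) < config.isoform_fraction
    iso[multi] = rng.integers(2, 4, int(multi.sum()))

    n_decoys = round(config.n_genes * config.decoy_fraction)
    decoy_ids = [f"REV__P{i + 1:0{width}d}" for i in range(n_decoys)]
    decoy_abund = pd.Series(
        10.0
        ** (
            config.baseline_log10_median
            - np.abs(rng.normal(0.0, config.baseline_log10_sd, n_decoys))
        ),
        index=decoy_ids,
    )
    n_false = round(config.n_genes * config.false_target_fraction)
    false_genes = [f"FG{i + 1:0{width}d}" for i in range(n_false)]
    false_abund = pd.Series(
        10.0
        ** (
            config.baseline_log10_median
            - np.abs(rng.normal(0.0, config.baseline_log10_sd, n_false))
        ),
        index=false_genes,
    )

    return TruthModel(
        genes=genes,
        organs=organs,
        baseline_abundance=baseline,
        organ_effects=folds,
        specificity_class=classes,
        enriched_organs=enriched,
        isoform_count=iso,
        decoy_ids=decoy_ids,
        decoy_abundance=decoy_abund,
        false_target_genes=false_genes,
        false_target_abundance=false_abund,
    )


def _dataset_design(
    truth: TruthModel, config: SimulationConfig, dataset_index: int, rng: np.random.Generator
) -> pd.DataFrame:
    dataset_id = f"DS{dataset_index + 1}"
    if config.organs_per_dataset < config.n_organs:
        organs = sorted(
            rng.choice(truth.organs, size=config.organs_per_dataset, replace=False)
        )
    else:
        organs = list(truth.organs)
    rows = []
    for organ in organs:
        for t in range(1, config.tissues_per_organ + 1):
            tissue = f"{organ}_region{t}"
            for s in range(1, config.samples_per_tissue + 1):
                sample = f"{dataset_id}_{organ}_r{t}_s{s}"
                for r in range(1, config.runs_per_sample + 1):
                    rows.append(
                        {
                            "run_name": f"{sample}_run{r}",
                            "sample_id": sample,
                            "tissue": tissue,
                            "organ": organ,
                            "dataset_id": dataset_id,
                            "condition": "normal",
                        }
                    )
    return pd.DataFrame(rows)


def simulate_dataset(
    truth: TruthModel, config: SimulationConfig, dataset_index: int
) -> tuple[ProteinGroupTable, SampleMap]:
    """Simulate one dataset's protein-group table and sample metadata.

    Per-run intensity = baseline x organ fold x dataset batch factor x run
    depth factor x log-normal noise; detection is Bernoulli with logistic
    probability in log10 intensity.  Isoform genes emit one protein group per
    isoform sharing the gene's signal; decoy, planted-false-target,
    contaminant and multi-gene rows are appended.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101, dataset_index]))
    design = _dataset_design(truth, config, dataset_index, rng)
    sample_map = SampleMap(table=design)
    runs = design["run_name"].tolist()
    run_organ = design["organ"].tolist()
    n_runs = len(runs)

    ds_factor = rng.normal(0.0, config.batch_log10_sd)  # one log10 factor per dataset
    depth = rng.normal(0.0, config.run_depth_log10_sd, n_runs)
    midpoint = _detection_midpoint(config)

    # gene-level expected log10 intensity per run
    log_base = np.log10(truth.baseline_abundance[truth.genes].to_numpy())
    log_fold = np.log10(truth.organ_effects.loc[truth.genes, run_organ].to_numpy())
    gene_log = log_base[:, None] + log_fold + ds_factor + depth[None, :]

    # expand genes to protein groups (one per isoform), sharing the signal
    group_rows: list[dict] = []
    gene_row_idx: list[int] = []
    shares: list[float] = []
    width = len(str(config.n_genes))
    for gi, gene in enumerate(truth.genes):
        acc = truth.accession_of_gene(gene)
        c = int(truth.isoform_count[gene])
        if c == 1:
            group_rows.append(
                {"protein_ids": [acc], "majority_protein_ids": [acc], "is_decoy": False, "is_contaminant": False}
            )
            gene_row_idx.append(gi)
            shares.append(1.0)
        else:
            share = rng.dirichlet(np.full(c, 5.0))
            for j in range(c):
                iso_acc = f"{acc}-{j + 1}"
                # the first isoform group also lists the canonical accession:
                # both resolve to the same gene, exercising within-group collapse
                majority = [iso_acc, acc] if j == 0 else [iso_acc]
                group_rows.append(
                    {
                        "protein_ids": majority,
                        "majority_protein_ids": majority,
                        "is_decoy": False,
                        "is_contaminant": False,
                    }
                )
                gene_row_idx.append(gi)
                shares.append(float(share[j]))

    group_log = gene_log[gene_row_idx, :] + np.log10(np.array(shares))[:, None]
    group_log = group_log + rng.normal(0.0, config.noise_log10_sd, group_log.shape)

    # decoy and planted-false-target rows: random matches, so whether a row
    # shows up at all is an independent per-dataset event (probability follows
    # the same logistic in its abundance); an absent row is all-missing here
    from scipy.special import expit as _expit

    extra_logs: list[np.ndarray] = []
    for abund_series, flags in (
        (truth.decoy_abundance, {"is_decoy": True, "is_contaminant": False}),
        (truth.false_target_abundance, {"is_decoy": False, "is_contaminant": False}),
    ):
        for acc, abund in abund_series.items():
            majority = [acc.replace("FG", "FP", 1) if acc.startswith("FG") else acc]
            group_rows.append(
                {"protein_ids": majority, "majority_protein_ids": majority, **flags}
            )
            present = True
            if midpoint is not None:
                p_present = float(_expit(config.dropout_steepness * (np.log10(abund) - midpoint)))
                present = bool(rng.random() < p_present)
            if present:
                extra_logs.append(
                    np.log10(abund)
                    + ds_factor
                    + depth
                    + rng.normal(0.0, config.noise_log10_sd, n_runs)
                )
            else:
                rng.normal(0.0, config.noise_log10_sd, n_runs)  # keep the stream aligned
                extra_logs.append(np.full(n_runs, -np.inf))
    for ci in range(config.contaminant_count):
        acc = f"CON__C{ci + 1:0{width}d}"
        group_rows.append(
            {"protein_ids": [acc], "majority_protein_ids": [acc], "is_decoy": False, "is_contaminant": True}
        )
        extra_logs.append(
            config.baseline_log10_median
            + 1.0
            + rng.normal(0.0, 0.5)
            + ds_factor
            + depth
            + rng.normal(0.0, config.noise_log10_sd, n_runs)
        )
    for _ in range(config.multi_gene_group_count):
        gi, gj = rng.choice(config.n_genes, size=2, replace=False)
        acc_i = truth.accession_of_gene(truth.genes[gi])
        acc_j = truth.accession_of_gene(truth.genes[gj])
        group_rows.append(
            {
                "protein_ids": [acc_i, acc_j],
                "majority_protein_ids": [acc_i, acc_j],
                "is_decoy": False,
                "is_contaminant": False,
            }
        )
        extra_logs.append(gene_log[gi] - 1.0 + rng.normal(0.0, config.noise_log10_sd, n_runs))

    all_log = np.vstack([group_log] + [np.atleast_2d(x) for x in extra_logs]) if extra_logs else group_log

    if midpoint is None:
        detected = np.ones(all_log.shape, dtype=bool)
    else:
        from scipy.special import expit

        p = expit(config.dropout_steepness * (all_log - midpoint))
        detected = rng.random(all_log.shape) < p
    intensity = np.where(detected, 10.0**all_log, np.nan)

    meta = pd.DataFrame(group_rows)
    meta.index.name = "group_id"

    # PSM counts increase with mean intensity; a configured fraction of
    # target gene groups is forced below the 2-PSM filter
    with np.errstate(invalid="ignore"):
        mean_log = np.nanmean(all_log, axis=1)
    ref = midpoint if midpoint is not None else config.baseline_log10_median - 1.0
    mean_log = np.nan_to_num(mean_log, nan=ref, neginf=ref)
    lam = np.clip((mean_log - ref) * 3.0, 0.0, None)
    psm = 2 + rng.poisson(lam)
    n_gene_groups = len(gene_row_idx)
    n_low = round(config.low_psm_fraction * n_gene_groups)
    if n_low:
        low_idx = rng.choice(n_gene_groups, size=n_low, replace=False)
        psm[low_idx] = rng.integers(0, 2, n_low)
    meta["psm_count"] = psm
    meta = meta[["protein_ids", "majority_protein_ids", "psm_count", "is_decoy", "is_contaminant"]]

    ibaq = pd.DataFrame(intensity, index=meta.index, columns=runs)
    return ProteinGroupTable(meta=meta, ibaq=ibaq), sample_map


def simulate_study(
    truth: TruthModel, config: SimulationConfig
) -> tuple[list[ProteinGroupTable], SampleMap]:
    """Simulate every dataset and pool the sample metadata."""
    tables = []
    maps = []
    for d in range(config.n_datasets):
        table, smap = simulate_dataset(truth, config, d)
        tables.append(table)
        maps.append(smap.table)
    return tables, SampleMap(table=pd.concat(maps, ignore_index=True))


def emit_reference_atlases(
    truth: TruthModel,
    noise_rate: float = 0.0,
    seed: int = 0,
    uncertain_fraction: float = 0.0,
) -> tuple[CategoricalAtlas, pd.DataFrame]:
    """Reference atlases derived from the truth.

    Categorical levels are per-organ terciles (low/medium/high) of the true
    organ-level abundance; with probability ``noise_rate`` a level is
    resampled uniformly.  The continuous atlas is the true organ abundance
    with log-normal noise of log10 sd ``noise_rate``.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise SimulationError("noise rate must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))
    true_ab = truth.true_organ_abundance()
    n = len(true_ab)
    levels = {1: "low", 2: "medium", 3: "high"}
    rows = []
    for organ in true_ab.columns:
        ranks = true_ab[organ].rank(method="min").astype(np.int64)
        terciles = -(-ranks * 3 // n)
        noisy = terciles.copy()
        flip = rng.random(n) < noise_rate
        noisy[flip] = rng.integers(1, 4, int(flip.sum()))
        uncertain = rng.random(n) < uncertain_fraction
        for gene, level, unc in zip(true_ab.index, noisy, uncertain):
            rows.append(
                {
                    "gene_id": gene,
                    "organ": organ,
                    "level": levels[int(level)],
                    "reliability": "uncertain" if unc else "supported",
                }
            )
    categorical = CategoricalAtlas(table=pd.DataFrame(rows))
    continuous = true_ab * 10.0 ** rng.normal(0.0, noise_rate, true_ab.shape)
    return categorical, continuous


def noiseless_config(config: SimulationConfig) -> SimulationConfig:
    """A copy of ``config`` with no batch effects, noise or dropout."""
    return replace(
        config,
        batch_log10_sd=0.0,
        run_depth_log10_sd=0.0,
        noise_log10_sd=0.0,
        dropout_midpoint_percentile=None,
        low_psm_fraction=0.0,
    )
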