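# lfqatlas

Cross-dataset integration of label-free quantitative proteomics.

Public repositories hold many independently acquired tissue proteomics
datasets, each searched separately (MaxQuant-style `proteinGroups.txt`
output, iBAQ intensities). Their absolute intensities are not comparable:
instrument depth, sample preparation and search settings impose strong
multiplicative batch effects, and low-abundance proteins drop out of
detection dataset by dataset. `lfqatlas` implements the post-search analysis
that turns such a collection into one comparable organ-level protein
abundance resource, for computational proteomics researchers building or
evaluating baseline expression atlases.

## The method

Per dataset (processed strictly independently, so adding a dataset never
changes existing results):

1. **Filtering** — remove decoy (reversed-sequence) hits, potential
   contaminants and protein groups with fewer than 2 PSMs.
2. **FOT normalization** — scale each protein group's iBAQ intensity by its
   MS run's total signal, in parts per billion:
   `ppb_i = iBAQ_i / Σ_j iBAQ_j × 10⁹` (detected groups only; per run the
   detected ppb sum is 10⁹ to relative 10⁻⁹).
3. **Gene mapping** — map each group's majority protein identifiers to gene
   identifiers. Isoform groups of one gene collapse to that gene
   ("canonical protein"); groups resolving to several genes are excluded
   (reported, not silently dropped); several groups on one gene aggregate by
   the per-run median.

Across datasets:

4. **Rank-binning** — per MS run, detected abundances are ranked ascending
   and cut into 5 equal-frequency bins, `bin(r) = ⌈r·5/m⌉` for rank `r` of
   `m` detected values (ties share the lower bin). Ranks are invariant to any
   strictly increasing distortion, so dataset batch factors cancel by
   construction. Within each *batch* (samples of one tissue in one dataset):
   a gene undetected everywhere stays NA; a gene detected in some samples
   gets bin 1 in the rest.
5. **Organ specificity** — per-organ summary bin (median, rounded half up),
   then a bin-based variant of the Uhlén scheme: *organ-enriched* (exactly
   one organ with bin ≥ 2× the mean bin across all organs, NA counted as 0),
   *group-enriched* (2–7 such organs), otherwise *mixed*.
6. **QC** — protein FDR as a function of the number of datasets a group is
   detected in, `FDR(k) = D(k)/T(k)` from decoy counts in the unfiltered
   tables; pairwise-complete Pearson correlation of binned abundances;
   hierarchical clustering (Euclidean, complete linkage); PCA on genes
   quantified in ≥50% of samples.
7. **Atlas comparison** — against a categorical reference
   (low/medium/high → 1/2/3 after re-binning to 3 levels): the *randomized
   edit distance difference*, `mean over permutations of (mean |b₁ − π(b₂)|)
   − mean |b₁ − b₂|`, near zero for unrelated noise and positive for
   concordant signal; gene-set overlap percentages; and per-organ Pearson r
   of log2 organ medians against a continuous reference.

A synthetic-data generator (`lfqatlas.synthetic`) emulates the whole input
ensemble — log-normal abundances over ~5 orders of magnitude, organ
enrichment with known ground truth, per-dataset batch factors,
abundance-dependent dropout, decoys, planted false targets, isoform and
multi-gene groups — so every stage has a known-answer test.

## Worked example

The numbered scripts under `analysis/` run the default synthetic study
(2,000 genes, 3 datasets, 6 organs, eightfold enrichment, seed 1) end to
end, writing tables under `results/study/`:

```
$ python analysis/01_simulate.py
simulated 3 datasets x 36 runs, 2000 genes (100 organ-enriched, 100 group-enriched),
100 decoys, 100 planted false targets

$ python analysis/02_process_datasets.py
dataset_id  input  decoy  contaminant  low_psm  output  genes  multi_gene  unmapped
       DS1   2508    100           10      115    2283   2008           5         0
...

$ python analysis/03_bin_and_classify.py
2100 genes x 108 samples binned (NA fraction 0.21)
classification: {'mixed': 1902, 'organ-enriched': 141, 'group-enriched': 57}
organ-enriched recovery vs truth: 96.0% of 100 planted genes

$ python analysis/04_qc.py
decoy-based FDR by minimum dataset count:
1    2.67
2    1.60
3    0.47
mean within-organ r = 0.941, between-organ r = 0.893

$ python analysis/05_compare_atlases.py
mean randomized edit distance difference: concordant atlas 0.65, randomized atlas -0.01
per-organ Pearson r vs continuous atlas: {'brain': 0.991, ...}
```

Reading the numbers: the 2,508 groups per dataset lose decoys, contaminants
and <2-PSM rows before normalization; 96% of the planted organ-enriched
genes are recovered by the twofold rule; the decoy-estimated FDR falls from
2.7% (proteins seen in any one dataset) to 0.5% (seen in all three),
the reason cross-dataset detection counts matter; binned abundances
correlate more strongly within than between organs despite the simulated
batch effects; and the randomized edit distance difference separates the
concordant reference atlas (+0.65) from a fully randomized one (≈0).

The same pipeline runs from one command, or stage by stage, via the CLI:

```
lfqatlas run-all --seed 1 --out artifacts/
lfqatlas simulate --seed 1 --out sim/
lfqatlas map-genes sim/proteinGroups_DS1.txt --gene-map sim/gene_map.tsv --out DS1.tsv
```

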