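# Methods

## Scope and model

`lfqatlas` operates downstream of peptide/protein identification: its unit
of input is the protein-group table of one dataset (iBAQ intensities per MS
run, dataset-total MS/MS counts, decoy and contaminant flags) plus sample
metadata relating runs to samples, tissues, organs and datasets. A *tissue*
is a distinct functional or structural region within an *organ* (left
ventricle and aorta are tissues of the heart); a *batch* is all samples of
one tissue within one dataset and is the unit for missing-value handling.

The central modelling commitment is that absolute intensities are only
meaningful within a run. Fraction-of-total normalization removes per-run
depth; everything cross-dataset happens on within-run ranks, grouped into
`n` equal-frequency bins. Because any strictly increasing transform of a
run's intensities leaves ranks unchanged, multiplicative batch effects — the
dominant distortion between independently processed datasets — cancel
exactly, at the price of discarding scale information. This rank invariance
is asserted as a property test.

## Numerical and procedural choices

* **Binning.** `bin(r) = ⌈r·n/m⌉` over the `m` detected entries, computed in
  exact integer arithmetic (`(r·n + m − 1) // m`), equal-frequency rather
  than equal-width (equal-width on a distribution spanning five orders of
  magnitude would place nearly everything in bin 1). Ties take their minimum
  rank, so tied values always share the *lower* bin; this keeps the
  transform deterministic and monotone. An independent sort-and-slice oracle
  (cumulative slice boundaries `⌊b·m/n⌋`, tie-collapse onto the first sorted
  position) is used in tests.
* **Missing values.** Within a batch: all-missing → NA (not detected there);
  partially missing → bin 1 (present but below detection). NA handling is
  resolved per batch, never globally, so sparse datasets cannot erase a
  gene detected elsewhere.
* **Fractions/replicate runs.** When a sample has several runs, the sample
  bin is the median of detected run bins, rounded half up. With one run per
  sample (the default design) this is the identity.
* **Re-binning to 3 levels** recomputes from ppb with `n = 3` rather than
  collapsing the 5-level bins, keeping one self-consistent definition; a
  collapse mode ({1,2}→1, {3,4}→2, {5}→3) is provided.
* **Specificity rule.** The mean bin is taken over *all* organs including
  the candidate, with NA counted as 0, and "twofold higher" is read
  inclusively (bin ≥ 2·mean). All three choices are toggles
  (`include_self`, `na_as_zero`, `inclusive`). Counting NA as 0 lets absence
  elsewhere strengthen specificity, which is the intended biology; its cost
  is that a gene detected (bin 1) in exactly one organ and NA elsewhere is
  called organ-enriched on minimal evidence.
* **FDR.** Estimated on distinct protein groups before gene mapping (decoys
  have no gene mapping), from the unfiltered tables. `FDR(k) = D(k)/T(k)`
  with `D`, `T` counts of decoy/target groups detected in ≥ k datasets;
  `T(k) = 0` is reported NA.
* **Randomized edit distance difference.** NA pairs are dropped before both
  the true and the randomized statistic, so both use the same support
  (otherwise missingness and distance are confounded). The null permutes the
  reference vector across proteins (sampling without replacement), which
  preserves its bin composition; resampling with replacement is available.
  Default 10 permutation replicates; convergence tests use thousands.
* **Clustering/PCA.** Complete-linkage hierarchical clustering on Euclidean
  distances between correlation-matrix rows, rows presorted lexicographically
  for deterministic tie-breaks. PCA keeps genes quantified in ≥50% of
  samples, imputes remaining NA as 0 (undetected ≈ lowest signal;
  mean-imputation available), centers genes, and takes coordinates from the
  SVD.
* **Order of operations.** FOT denominators are computed after filtering, so
  contaminant and decoy signal does not distort ppb. Whether the <2-PSM
  filter precedes normalization is configurable (`min_psm`), with filtering
  first as the default.

## The synthetic-data generator

The generator emulates a multi-dataset tissue-atlas reanalysis with known
ground truth. Defaults (the study conditions of the analysis scripts and
acceptance checks): 2,000 genes, 3 datasets × 6 organs × 2 tissues × 3
samples × 1 run, eightfold organ enrichment, seed-driven PCG64 randomness
throughout (identical output across platforms).

* **Abundance.** Gene baselines are log-normal, log10 median 5, log10 sd 1
  (~5 orders of magnitude). Run intensity = baseline × organ fold ×
  per-dataset batch factor (log10 sd 0.3) × per-run depth factor (log10 sd
  0.1) × log-normal noise (log10 sd 0.08).
* **Detection.** Bernoulli per group and run with logistic probability in
  log10 intensity: midpoint at the 30th percentile of the baseline
  distribution, steepness 4 per log10 unit, i.e. the detection transition
  spans roughly one order of magnitude, as in label-free LFQ practice.
  Missingness is therefore abundance-dependent by construction (tested by
  decile).
* **Tissue-restricted genes.** 5% organ-enriched and 5% group-enriched
  genes carry the configured fold in their enriched organ(s). Their
  *off-organ* baseline is drawn from a narrow band just below the detection
  midpoint (median − 0.55 ± 0.05 in log10). This encodes the biology that
  tissue-specific proteins sit at or below the detection limit outside their
  organ, and makes the planted truth recoverable in principle: the band is
  placed so that bin 1/dropout is the off-organ norm while an eightfold lift
  reaches the middle of the detected range. Because the fold (0.9 log10)
  spans only ~2.5 bins, recoverability is intrinsically tight; across seeds
  the organ-enriched recovery of the default study is typically 85–95%
  (median ≈ 90%, occasional lower seeds when the enriched level lands on the
  bin-2/3 boundary). Group sizes for group-enriched genes are drawn from
  2..min(7, ⌊3·n_organs/8⌋): beyond that size the enriched organs dominate
  the mean bin and the twofold rule cannot detect the group even at bin 5,
  so larger planted groups would be unlearnable by construction (with 6
  organs only pairs qualify — and indeed recovered group-enriched calls are
  rare in the default study; the rule is designed for ~30 organs).
* **Decoys and planted false targets.** Equal fractions (5% of the gene
  count each) with abundance from the bottom half of the target
  distribution. Whether such a row appears in a dataset at all is an
  independent per-dataset Bernoulli event (probability from the same
  logistic), reflecting that decoy hits are random matches; this makes
  FDR(k) fall with k and lets the decoy estimate be checked against the
  realized false-target rate (calibrated within a factor of ~1.3 in the
  default study).
* **Structure variants.** ~10% of genes emit one protein group per isoform
  (shares Dirichlet-distributed; the first isoform group also lists the
  canonical accession, exercising within-group collapse); a handful of
  groups span two genes (must be excluded as multi-gene); 5% of gene groups
  are forced below the 2-PSM filter; contaminant rows are flagged.
* **Reference atlases.** Categorical: per-organ terciles of the true organ
  abundance (low/medium/high), each level resampled uniformly with the
  configured noise rate — at rate 0 the atlas is the exact discretized
  truth, at rate 1 it is pure noise (the edit-distance negative control).
  Continuous: true organ abundance with log-normal noise (log10 sd = noise
  rate).

### What the generator does not emulate

Peptide-level identity and spectra; retention-time structure; correlated
(non-multiplicative) batch effects such as protocol-specific protein losses;
shared-peptide ambiguity beyond the simple two-gene groups; real isoform
quantification. Passing tests therefore demonstrate the correctness and
calibration of the post-search pipeline under multiplicative batch effects
and abundance-dependent dropout — not the end-to-end fidelity of any
specific published reanalysis, whose inputs (raw data, search engine,
reference atlas versions) are outside this package's scope.

## Problem sizes

The analysis scripts, tests and the acceptance script all use the default
2,000-gene, 3-dataset design (108 runs) — large enough for stable rank
statistics and FDR counts at ≥5 decoys per level, small enough that the full
suite runs in seconds. Determinism checks use a 200–300 gene, 2-dataset
variant.

## Known limitations

* Gene-level aggregation uses the median over protein groups; summed
  isoform abundance is deliberately out of scope.
* The specificity rule inherits the fragility of NA-as-0 averaging for
  nearly-undetected genes (see above); ~5% of truly unspecific genes are
  called enriched in the default study, mirroring the false-positive
  accumulation that the cross-dataset FDR curve quantifies.
* Continuous cross-dataset normalization (ComBat/Limma-style) is not
  provided; the rank-bin transform is the integration device.
* The categorical-atlas comparison assumes the reference uses the
  low/medium/high vocabulary with the documented auxiliary levels.
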