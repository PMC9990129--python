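import numpy as np
import pandas as pd
import pytest

from lfqatlas import binning, pipeline, specificity
from lfqatlas import synthetic as syn
from lfqatlas.io_formats import SampleMap


@pytest.fixture(scope="session")
def default_config() -> syn.SimulationConfig:
    return syn.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_study(default_config):
    """Full default simulation processed through binning and classification.

    Shared session-wide: the heavier known-answer checks (specificity
    recovery, atlas comparison, FDR calibration) all read from here.
    """
    truth = syn.generate_truth(default_config)
    tables, sample_map = syn.simulate_study(truth, default_config)
    gene_map = truth.gene_map()
    raw = {f"DS{i + 1}": t for i, t in enumerate(tables)}
    matrices = {}
    reports = {}
    for dataset_id, table in raw.items():
        matrix, report = pipeline.process_dataset(table, gene_map)
        matrices[dataset_id] = matrix
        reports[dataset_id] = report
    pooled = pd.concat(
        [matrices[d].values for d in sorted(matrices)], axis=1, join="outer"
    ).sort_index()
    binned5 = binning.bin_pipeline(pooled, sample_map, n_bins=5)
    binned3 = binning.rebin(pooled, sample_map, n_bins=3)
    profile5 = specificity.organ_bin_profile(binned5, sample_map)
    classified = specificity.classify_profiles(profile5)
    return {
        "config": default_config,
        "truth": truth,
        "sample_map": sample_map,
        "raw_tables": raw,
        "gene_matrices": matrices,
        "filter_reports": reports,
        "pooled_ppb": pooled,
        "binned5": binned5,
        "binned3": binned3,
        "profile5": profile5,
        "classified": classified,
    }


@pytest.fixture()
def simple_sample_map() -> SampleMap:
    """One dataset, one organ, two tissues, two samples each, one run per sample."""
    rows = []
    for tissue in ("cortex", "cerebellum"):
        for s in (1, 2):
            rows.append(
                {
                    "run_name": f"{tissue}_s{s}_r1",
                    "sample_id": f"{tissue}_s{s}",
                    "tissue": tissue,
                    "organ": "brain",
                    "dataset_id": "DS1",
                    "condition": "normal",
                }
            )
    return SampleMap(table=pd.DataFrame(rows))


def sort_and_slice_oracle(values, n_bins):
    """Independent equal-frequency binning oracle.

    Sorts the detected entries, cuts the sorted order into contiguous slices
    whose cumulative sizes are floor(b*m/n_bins), and collapses ties onto the
    bin of their first (lowest) sorted position.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    detected = np.where(~np.isnan(values))[0]
    m = len(detected)
    if m == 0:
        return out
    order = detected[np.argsort(values[detected], kind="stable")]
    bin_of_pos = np.empty(m, dtype=int)
    start = 0
    for b in range(1, n_bins + 1):
        end = (b * m) // n_bins
        bin_of_pos[start:end] = b
        start = end
    first_bin_of_value: dict[float, int] = {}
    for pos, idx in enumerate(order):
        v = values[idx]
        if v not in first_bin_of_value:
            first_bin_of_value[v] = bin_of_pos[pos]
        out[idx] = first_bin_of_value[v]
    return out
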