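import numpy as np
import pandas as pd
import pytest

from mqtlcollapse.regions import GenomicInterval
from mqtlcollapse.scan import ScanData
from mqtlcollapse.simulate import default_study_config, simulate_dataset


@pytest.fixture(scope="session")
def study_dataset():
    """Canonical synthetic cohort: 800 samples, 12 islands, one planted
    region per effect mode (regions 0-4) and the rest null."""
    return simulate_dataset(default_study_config(seed=0))


@pytest.fixture(scope="session")
def study_islands(study_dataset):
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in study_dataset.islands.itertuples()
    ]


@pytest.fixture(scope="session")
def study_scan_data(study_dataset):
    ds = study_dataset
    return ScanData(
        dosages=ds.dosages,
        variant_ids=ds.variants["id"].tolist(),
        variant_mafs=ds.variants["maf"].to_numpy(),
        methylation=ds.methylation,
        covariates=ds.covariates.to_numpy(dtype=float),
    )


def region_genotypes(ds, k, include_special=False):
    """Dosage columns + variant sub-table for island region k."""
    v = ds.variants
    mask = v["region"] == k
    if not include_special:
        mask &= v["block"] >= 0
    sel = v[mask]
    return ds.dosages[:, sel.index], sel.reset_index(drop=True)


def special_column(ds, k, prefix):
    """Column index of a region's index ('idx') or overlap ('ovl') variant."""
    v = ds.variants
    idx = v.index[(v["region"] == k) & (v["id"].str.startswith(prefix))]
    return int(idx[0])
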