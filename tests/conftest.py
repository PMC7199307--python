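import dataclasses

import numpy as np
import pytest

from rohmap.io import GenotypeDataset, MarkerMap
from rohmap.roh import ROHParams
from rohmap.simulate import PROFILES, simulate_genotypes, simulate_phenotypes

# scaled-down scan parameters matching the desk marker panel (~10 kb/SNP)
DESK_ROH_PARAMS = ROHParams(window_snp=50, min_snp=50, min_kb=500.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_sim():
    """One 'tiny' profile simulation shared across tests."""
    cfg = dataclasses.replace(PROFILES["tiny"], seed=11)
    dataset, pedigree, truth = simulate_genotypes(cfg)
    records, truth = simulate_phenotypes(dataset, truth, cfg)
    return {
        "config": cfg,
        "dataset": dataset,
        "pedigree": pedigree,
        "truth": truth,
        "records": records,
    }


def evenly_spaced_dataset(calls_rows, spacing_bp=10_000, chrom=1):
    """Build a one-chromosome dataset from explicit call rows."""
    calls = np.asarray(calls_rows, dtype=np.int8)
    n, m = calls.shape
    markers = MarkerMap(
        np.full(m, chrom, dtype=np.int64),
        np.array([f"m{j}" for j in range(m)], dtype=object),
        (np.arange(m, dtype=np.int64) * spacing_bp) + 1,
    )
    return GenotypeDataset([f"s{i}" for i in range(n)], markers, calls)
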