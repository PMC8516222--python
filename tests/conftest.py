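import numpy as np
import pandas as pd
import pytest

from hsgwas.climate import ExposureTable
from hsgwas.geno_qc import GenotypeMatrix, mean_impute, vanraden_grm
from hsgwas.synthdata import (
    SimulationConfig,
    simulate_genotypes,
    simulate_markers,
)


def make_genotypes(doses, chrom=None, pos=None, animal_ids=None):
    """GenotypeMatrix from a raw dose array (NaN = missing)."""
    doses = np.asarray(doses, dtype=float)
    n, m = doses.shape
    markers = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else [1] * m,
        "pos": pos if pos is not None else list(range(1, m + 1)),
        "a1": "A", "a2": "B",
    })
    ids = animal_ids if animal_ids is not None else [f"a{i}" for i in range(n)]
    return GenotypeMatrix(np.asarray(ids), markers, doses)


def make_exposure(animal_ids, flags, week=1, thi_hot=65.0, thi_cool=55.0):
    flags = np.asarray(flags, dtype=int)
    return ExposureTable(pd.DataFrame({
        "animal_id": [str(a) for a in animal_ids],
        "week": week,
        "weekly_thi": np.where(flags == 1, thi_hot, thi_cool),
        "hs_flag": flags,
    }))


@pytest.fixture(scope="session")
def hwe_genotypes():
    """300 animals x 500 HWE markers, complete, with the GRM attached."""
    cfg = SimulationConfig(n_animals=300, n_snps=500, seed=42, missing_rate=0.0)
    markers = simulate_markers(cfg)
    genotypes = simulate_genotypes(cfg, markers)
    grm = vanraden_grm(mean_impute(genotypes))
    return genotypes, grm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
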