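import numpy as np
import pandas as pd
import pytest

from seaflow import SeascapeSpec, make_seascape
from seaflow.experiments import desk_connectivity
from seaflow.genotypes import GenotypeTable


@pytest.fixture(scope="session")
def small_sea():
    return make_seascape(SeascapeSpec(nx=40, ny=24, n_times=6, period=60.0,
                                      gyre_amplitude=0.25, land_fraction=0.2, seed=7))


@pytest.fixture(scope="session")
def desk_run():
    """Five-population, 10-day tracking run shared across tests."""
    return desk_connectivity(n_pops=5, seed=11, n_release=8, particles_per_day=1,
                             n_days=5, duration_days=10.0, nx=60, ny=32)


def build_genotypes(pop_alleles: dict, loci=None, sites=None) -> GenotypeTable:
    """Assemble a GenotypeTable from {pop: (n, L, 2) arrays} (test helper)."""
    rows, blocks = [], []
    for pop, arr in pop_alleles.items():
        arr = np.asarray(arr, dtype=np.int32)
        blocks.append(arr)
        site = sites.get(pop, pop) if sites else pop
        for k in range(arr.shape[0]):
            rows.append({"id": f"{pop}_{k}", "site": site, "population": pop})
    alleles = np.concatenate(blocks, axis=0)
    loci = loci or [f"L{j + 1}" for j in range(alleles.shape[1])]
    return GenotypeTable(pd.DataFrame(rows), loci, alleles)


@pytest.fixture
def two_pop_random():
    """Random two-population, three-locus toy table."""
    rng = np.random.default_rng(42)
    return build_genotypes({
        "A": rng.integers(8, 14, size=(12, 3, 2)),
        "B": rng.integers(10, 18, size=(15, 3, 2)),
    })
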