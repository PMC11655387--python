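import numpy as np
import pandas as pd
import pytest

from archoffset import simdata
from archoffset.genio import CLIMATE_PREDICTORS, GenotypeMatrix


def make_gm(dosage, chrom=None, sample_ids=None):
    """Wrap a raw dosage array in a GenotypeMatrix with minimal metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    snp_meta = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * m,
        "pos": np.arange(1, m + 1) * 100,
        "ref": "A",
        "alt": "T",
        "mean_depth": 20.0,
    })
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    return GenotypeMatrix(dosage, snp_meta, pd.DataFrame({"id": ids}))


@pytest.fixture(scope="session")
def small_arch():
    return simdata.make_archipelago(n_islands=6, cells_per_island=10, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_arch):
    """120 individuals, 150 neutral + 50 adaptive loci, moderate cline."""
    gm, truth = simdata.simulate_genotypes(
        small_arch, n_per_island=20, n_neutral=150, n_adaptive=50,
        fst=0.05, effect_b=3.0, seed=12,
    )
    return gm, truth


@pytest.fixture(scope="session")
def sample_climate(small_arch, small_sim):
    gm, _ = small_sim
    grid = small_arch.grid.set_index("cell_id")
    return grid.loc[gm.sample_meta["cell_id"], CLIMATE_PREDICTORS].reset_index(
        drop=True
    )
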