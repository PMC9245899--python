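import numpy as np
import pandas as pd
import pytest

from insulome.core_io import SITE_COLUMNS, GeneticMap, GenotypeMatrix
from insulome.synthetic_data import make_founders


@pytest.fixture(scope="session")
def small_gmap() -> GeneticMap:
    """Two chromosomes, 150 + 120 cM, uniform 1 cM/Mb."""
    return GeneticMap.uniform({"chr1": 150.0, "chr2": 120.0})


@pytest.fixture(scope="session")
def small_panel(small_gmap):
    """60 founder haplotypes, 2000 sites/chromosome (~14.8 SNPs/cM)."""
    return make_founders(60, 2000, small_gmap, seed=11)


def random_matrix(
    n_ind: int,
    n_sites: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    chrom: str = "chr1",
) -> GenotypeMatrix:
    """A random genotype panel with evenly spaced sites on one chromosome."""
    rng = np.random.default_rng(seed)
    bp = np.arange(1, n_sites + 1) * 10_000
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "bp": bp,
            "cM": bp / 1e6,
            "ref": "A",
            "alt": "G",
            "p": 0.0,
        }
    )[SITE_COLUMNS]
    p = rng.uniform(0.05, 0.95, size=n_sites)
    g = (rng.random((n_ind, n_sites)) < p).astype(np.int8)
    g += (rng.random((n_ind, n_sites)) < p).astype(np.int8)
    if missing_rate > 0:
        g[rng.random((n_ind, n_sites)) < missing_rate] = -1
    gm = GenotypeMatrix(
        ids=[f"ind{i}" for i in range(n_ind)], sites=sites, genotypes=g
    )
    return gm.recompute_frequencies()
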