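import numpy as np
import pandas as pd
import pytest

from blupgwas.genotypes import GenotypeMatrix
from blupgwas.simulate import SimulationConfig, simulate_cohort


def make_variants(n, chrom="1", prefix="v"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": 1000 * (np.arange(n) + 1),
            "id": [f"{prefix}{j + 1}" for j in range(n)],
            "ref": "A",
            "alt": "G",
            "multiallelic": False,
        }
    )


def make_gm(dosages, chrom="1", samples=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        variants=make_variants(m, chrom=chrom),
        samples=samples or [f"S{i + 1}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """300-sample, 200-SNP cohort with mild LD and 5 causal SNPs."""
    return simulate_cohort(
        SimulationConfig(
            n_samples=300, n_snps=200, ld_block_size=5, within_block_r=0.4,
            n_causal=5, heritability=0.4, seed=42,
        )
    )


@pytest.fixture(scope="session")
def default_cohort_small():
    """Default study proportions at the full n=1076 but few SNPs (fast)."""
    return simulate_cohort(
        SimulationConfig(n_samples=1076, n_snps=50, n_causal=5, seed=5)
    )
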