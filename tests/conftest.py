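import warnings

import numpy as np
import pandas as pd
import pytest

from rorp_prs import SimulationConfig, simulate_cohort
from rorp_prs.simulate import GenotypeMatrix

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest development-style cohort shared by read-only tests."""
    cfg = SimulationConfig(n_samples=800, seed=11, n_ld_pairs=6)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def covariates(small_cohort):
    cols = [f"PC{i}" for i in range(1, 11)] + ["study"]
    return small_cohort.clinical[cols]


def make_genotypes(n, m, maf=0.3, seed=0, prefix="rs"):
    """Plain HWE genotype matrix helper for unit tests."""
    rng = np.random.default_rng(seed)
    G = rng.binomial(2, maf, (n, m)).astype(float)
    snps = [f"{prefix}{i}" for i in range(m)]
    dos = pd.DataFrame(G, index=pd.Index([f"S{i}" for i in range(n)], name="sample"), columns=snps)
    info = pd.DataFrame(
        {"effect_allele": "A", "other_allele": "G", "maf_true": maf, "pub_p": 1e-9},
        index=pd.Index(snps, name="snp"),
    )
    return GenotypeMatrix(dosages=dos, snp_info=info)


def make_pc_covars(n, seed=0, index=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.normal(0, 1, (n, 10)), columns=[f"PC{i}" for i in range(1, 11)]
    )
    if index is not None:
        df.index = index
    return df
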