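import numpy as np
import pandas as pd
import pytest

from inflaqtl.expression import pca_and_outliers, select_num_pcs
from inflaqtl.genotype import ibs_kinship
from inflaqtl.lmm import SpectralKinship
from inflaqtl.simulate import simulate_dataset


@pytest.fixture(scope="session")
def bundle():
    """Small planted dataset shared by the scan tests."""
    return simulate_dataset(
        n_individuals=100, n_genes=60, n_variants=180,
        n_main=5, n_gxe=3, n_de=5, seed=7,
    )


@pytest.fixture(scope="session")
def kinship(bundle):
    return ibs_kinship(bundle.genotypes)


@pytest.fixture(scope="session")
def spectral(kinship):
    return SpectralKinship(kinship.to_numpy(), kinship.sample_ids)


@pytest.fixture(scope="session")
def pcs(bundle):
    p, _ = pca_and_outliers(bundle.expression)
    p.n_selected = max(select_num_pcs(p), 2)
    return p


def block_kinship(n_individuals=165, n_samples=280, seed=0):
    """Kinship with exact duplicate blocks: individuals sampled twice share rows."""
    rng = np.random.default_rng(seed)
    geno = rng.binomial(2, 0.3, size=(n_individuals, 120)).astype(float)
    owners = np.concatenate([
        np.arange(n_individuals),
        rng.choice(n_individuals, size=n_samples - n_individuals, replace=False),
    ])
    g = geno[owners]
    d = pd.DataFrame(g, index=[f"s{i}" for i in range(n_samples)],
                     columns=[f"v{j}" for j in range(120)])
    return ibs_kinship(d), owners
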