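"""Shared fixtures: small simulated F2 datasets and unrelated-cohort data.

Everything is generated programmatically at fixed seeds; no data files.
"""

import numpy as np
import pytest

import omicblup as ob
from omicblup.data import GenotypeData


@pytest.fixture(scope="session")
def f2_small():
    """Small F2 dataset: 5 half-sib groups, 120 animals, 300 SNPs, 40 transcripts."""
    return ob.simulate.simulate_dataset(n_snps=300, k=40, f2_per_mating=12,
                                        n_testdays=5, seed=11)


@pytest.fixture(scope="session")
def f2_study():
    """Study-scale F2 dataset: 10 groups, 480 animals, 800 SNPs, 80 transcripts."""
    return ob.simulate.simulate_dataset(n_snps=800, k=80, seed=23)


@pytest.fixture(scope="session")
def unrelated():
    """Unrelated cohort: iid binomial dosages, n=80 animals, 200 SNPs."""
    rng = np.random.default_rng(5)
    p = rng.uniform(0.1, 0.9, 200)
    dos = rng.binomial(2, p, size=(80, 200))
    geno = GenotypeData(dos, [f"a{i}" for i in range(80)],
                        [f"s{j}" for j in range(200)])
    tx, truth = ob.simulate.simulate_transcripts(geno, 30, 0.25, seed=6)
    truth.sigma2_g_true, truth.sigma2_t_true, truth.sigma2_e_true = 0.25, 0.35, 0.40
    phen = ob.simulate.simulate_phenotypes(geno, tx, truth, n_testdays=4, seed=7)
    return geno, tx, phen, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
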