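import numpy as np
import pandas as pd
import pytest

from crossblup.genome import build_genome, trait_architecture
from crossblup.simulate import PopulationDesign, simulate_population


@pytest.fixture(scope="session")
def toy_genome():
    return build_genome(1, 25.0, 300)


@pytest.fixture(scope="session")
def toy_pop_sim5(toy_genome):
    """Small SIM5-style population (QTLs explain all heritability)."""
    trait = trait_architecture("SIM5", toy_genome, max_qtl=40)
    return simulate_population(toy_genome, trait, PopulationDesign.toy(), seed=3)


@pytest.fixture(scope="session")
def toy_pop_sim1(toy_genome):
    """Small purely polygenic population."""
    trait = trait_architecture("SIM1", toy_genome)
    return simulate_population(toy_genome, trait, PopulationDesign.toy(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_pedigree(n, n_founders, seed=0):
    """Random valid pedigree as index arrays and a DataFrame."""
    r = np.random.default_rng(seed)
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for i in range(n_founders, n):
        sire[i] = r.integers(0, i)
        dam[i] = r.integers(0, i)
        if sire[i] == dam[i]:
            dam[i] = -1
    ped = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sire": np.where(sire >= 0, sire + 1, 0),
            "dam": np.where(dam >= 0, dam + 1, 0),
        }
    )
    return sire, dam, ped
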