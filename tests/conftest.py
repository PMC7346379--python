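"""Shared fixtures: small simulated datasets built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from lrhap.experiments import desk_params, founder_dataset
from lrhap.popsim import SimParams, simulate_population


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def founder_pop():
    """Small founder-haplotype population: complete genotypes, known pedigree."""
    genotypes, pedigree, truth = founder_dataset(
        n_individuals=200, n_snps=300, seed=5
    )
    return genotypes, pedigree, truth


@pytest.fixture(scope="session")
def founder_params(founder_pop):
    genotypes, _, _ = founder_pop
    return desk_params(
        genotypes.n_snps, subset_size=genotypes.n_individuals, rng_seed=3,
        core_length=50, min_match_alleles=20, min_shared_markers=25,
    )


@pytest.fixture(scope="session")
def sim_pop():
    """Small two-breed selected population with full truth."""
    params = SimParams(
        n_snps=200,
        recent_split_counts=(2,),
        n_generations_selection=3,
        n_sires=5,
        n_dams=20,
        n_offspring_per_breed_gen=60,
        founder_pop_size=50,
        n_qtn=50,
        rng_seed=7,
    )
    return simulate_population(params)
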