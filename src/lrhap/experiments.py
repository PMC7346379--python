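"""Canned desk-scale experiments: dataset builders and accuracy sweeps.

These are the package's worked examples — scaled-down versions of the
study conditions the method was designed for, sized so each runs on a
laptop in seconds to minutes.  The scaling rules are fixed (see
docs/methods.md): the chromosome stays 1 Morgan, cores are ~10% of the
chromosome, the haplotype-identity threshold is 40% of a core, and the
surrogate disagreement allowance is zero because simulated genotypes are
error-free.
"""

from __future__ import annotations

import numpy as np

from .evaluate import PhasingStats, phasing_statistics
from .pipeline import phase_dataset
from .popsim import (
    SimParams,
    build_array_scheme,
    meiosis,
    simulate_population,
    two_array_spec,
)
from .types import GenotypeMatrix, Pedigree, PhasingParams, UNKNOWN_PARENT


def desk_params(n_snps: int, subset_size: int, rng_seed: int = 0,
                core_frac: float = 0.10, **overrides) -> PhasingParams:
    """Phasing parameters scaled to a desk-sized, error-free simulation.

    Cores are ``core_frac`` of the chromosome, haplotype identity needs
    40% of a core co-observed, surrogacy needs half a core shared, and no
    opposing homozygotes are tolerated between surrogates (the genotypes
    carry no error).
    """
    core_length = max(2, int(round(core_frac * n_snps)))
    defaults = dict(
        core_length=core_length,
        subset_size=subset_size,
        min_match_alleles=max(2, int(round(0.4 * core_length))),
        min_shared_markers=max(2, core_length // 2),
        surrogate_disagree_frac=0.0,
        rng_seed=rng_seed,
    )
    defaults.update(overrides)
    return PhasingParams(**defaults)


def founder_dataset(
    n_individuals: int = 500,
    n_snps: int = 500,
    n_founder_haplotypes: int = 8,
    offspring_per_generation: int = 100,
    seed: int = 0,
) -> tuple[GenotypeMatrix, Pedigree, np.ndarray]:
    """Individuals bred from a handful of known founder haplotypes.

    Founders carry random haplotypes; later generations are produced by
    meiosis from randomly paired parents of the previous generation, so
    every haplotype in the population is a recombinant mosaic of the
    founder haplotypes.  Genotypes are complete and the pedigree is known.

    Returns (genotypes, pedigree, true_haplotypes).
    """
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.uniform(0.0, 1.0, n_snps))
    founder_haps = rng.integers(0, 2, size=(n_founder_haplotypes, n_snps)).astype(np.int8)
    n_founders = n_founder_haplotypes // 2
    haps = [np.stack([founder_haps[2 * k], founder_haps[2 * k + 1]])
            for k in range(n_founders)]
    sire = [UNKNOWN_PARENT] * n_founders
    dam = [UNKNOWN_PARENT] * n_founders
    cohort = list(range(n_founders))
    while len(haps) < n_individuals:
        males = cohort[: max(1, len(cohort) // 2)]
        females = cohort[max(1, len(cohort) // 2):] or cohort
        new = []
        for _ in range(min(offspring_per_generation, n_individuals - len(haps))):
            s = int(rng.choice(males))
            d = int(rng.choice(females))
            child = np.stack([
                meiosis(haps[s], positions, rng),
                meiosis(haps[d], positions, rng),
            ])
            sire.append(s)
            dam.append(d)
            new.append(len(haps))
            haps.append(child)
        cohort = new
    truth = np.stack(haps)
    ids = [f"I{k}" for k in range(len(haps))]
    genotypes = GenotypeMatrix(ids=ids, codes=truth.sum(axis=1).astype(np.int8))
    pedigree = Pedigree(ids=list(ids), sire=np.asarray(sire), dam=np.asarray(dam))
    return genotypes, pedigree, truth


def founder_recovery(seed: int = 0) -> PhasingStats:
    """Phase the founder-haplotype dataset and score against truth."""
    genotypes, pedigree, truth = founder_dataset(seed=seed)
    params = desk_params(genotypes.n_snps, subset_size=genotypes.n_individuals,
                         rng_seed=seed)
    haps, cores, _ = phase_dataset(genotypes, pedigree, params)
    return phasing_statistics(haps, truth, genotypes, cores, scope="heterozygous")


def breeding_dataset(
    n_snps: int = 1050,
    n_breeds: int = 2,
    n_generations: int = 5,
    n_sires: int = 10,
    n_dams: int = 50,
    offspring_per_breed_gen: int = 400,
    founder_pop_size: int = 150,
    seed: int = 0,
) -> tuple[GenotypeMatrix, Pedigree, np.ndarray, SimParams]:
    """Simulate a breeding population; the dataset is the selected
    offspring generations (founders are pedigree ancestors only).

    Returns (complete genotypes, pedigree, true haplotypes, sim params).
    """
    sp = SimParams(
        n_snps=n_snps,
        recent_split_counts=(n_breeds,) if n_breeds > 1 else (1,),
        split_generations=(400, 50) if n_breeds > 1 else (400, 50),
        n_generations_selection=n_generations,
        n_sires=n_sires,
        n_dams=n_dams,
        n_offspring_per_breed_gen=offspring_per_breed_gen,
        founder_pop_size=founder_pop_size,
        n_qtn=200,
        rng_seed=seed,
    )
    pop = simulate_population(sp)
    rows = np.flatnonzero(pop.generation >= 1)
    genotypes = GenotypeMatrix(
        ids=[pop.ids[k] for k in rows],
        codes=pop.haplotypes[rows].sum(axis=1).astype(np.int8),
    )
    return genotypes, pop.pedigree, pop.haplotypes[rows], sp


def trend_params(n_snps: int, subset_size: int, rng_seed: int = 0,
                 **overrides) -> PhasingParams:
    """Parameters for the 4000-individual experiments: 150-SNP cores
    (~1/7 of the chromosome), identity at 100 matching alleles, surrogacy
    at 75 shared markers."""
    return desk_params(
        n_snps, subset_size, rng_seed=rng_seed,
        core_length=min(150, n_snps),
        min_match_alleles=overrides.pop("min_match_alleles", 100),
        min_shared_markers=overrides.pop("min_shared_markers", 75),
        **overrides,
    )


def subset_size_sweep(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    truth: np.ndarray,
    subset_sizes=(250, 1000, 4000),
    seed: int = 0,
) -> dict[int, PhasingStats]:
    """Het-locus accuracy of the full pipeline for each subset size."""
    out = {}
    for size in subset_sizes:
        params = trend_params(genotypes.n_snps, subset_size=size, rng_seed=seed)
        haps, cores, _ = phase_dataset(genotypes, pedigree, params)
        out[size] = phasing_statistics(
            haps, truth, genotypes, cores, scope="heterozygous"
        )
    return out


def homogeneous_vs_two_array(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    truth: np.ndarray,
    overlap_frac: float = 0.6,
    seed: int = 0,
    subset_size: int | None = None,
) -> dict[str, PhasingStats]:
    """Phase the same truth genotyped on one array vs two half-overlapping
    arrays (1:1 assignment) and score both at heterozygous loci."""
    n = genotypes.n_individuals
    subset_size = subset_size or n
    # thresholds chosen so that haplotype identity and surrogacy remain
    # satisfiable across arrays: with 60% overlap, two individuals on
    # different arrays co-observe ~60% of an array's core SNPs
    params = trend_params(
        genotypes.n_snps, subset_size=subset_size, rng_seed=seed,
        min_match_alleles=60, min_shared_markers=50,
    )
    results = {}
    haps, cores, _ = phase_dataset(genotypes, pedigree, params)
    results["homogeneous"] = phasing_statistics(
        haps, truth, genotypes, cores, scope="heterozygous"
    )
    rng = np.random.default_rng(seed + 1)
    scheme = build_array_scheme(
        two_array_spec(overlap_frac), n, n_snps=genotypes.n_snps, rng=rng
    )
    from .types import MISSING

    masked = np.full(genotypes.codes.shape, MISSING, dtype=np.int8)
    for k, snps in enumerate(scheme.arrays):
        rows = np.flatnonzero(scheme.assignment == k)
        masked[np.ix_(rows, snps)] = genotypes.codes[np.ix_(rows, snps)]
    masked_geno = GenotypeMatrix(ids=list(genotypes.ids), codes=masked)
    haps, cores, _ = phase_dataset(masked_geno, pedigree, params)
    results["two_array"] = phasing_statistics(
        haps, truth, masked_geno, cores, scope="heterozygous"
    )
    return results
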