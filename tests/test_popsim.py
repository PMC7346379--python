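"""Population simulator: meiosis, breeding design, arrays and masking."""

import numpy as np
import pytest

from lrhap.exceptions import SimulationError
from lrhap.popsim import (
    PRESETS,
    SimParams,
    build_array_scheme,
    mask_genotypes,
    meiosis,
    simulate_population,
    two_array_spec,
)
from lrhap.types import MISSING, UNKNOWN_PARENT


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def test_meiosis_zero_crossovers_copies_one_parent(rng):
    parent = rng.integers(0, 2, size=(2, 50)).astype(np.int8)
    positions = np.sort(rng.uniform(0, 1e-9, 50))
    # chromosome length ~0 Morgan: Poisson(0) crossovers almost surely
    gamete = meiosis(parent, positions, np.random.default_rng(0), chrom_length=1e-12)
    assert np.array_equal(gamete, parent[0]) or np.array_equal(gamete, parent[1])


def test_meiosis_alleles_come_from_parent(rng):
    parent = rng.integers(0, 2, size=(2, 200)).astype(np.int8)
    positions = np.sort(rng.uniform(0, 1, 200))
    for _ in range(20):
        g = meiosis(parent, positions, rng)
        assert ((g == parent[0]) | (g == parent[1])).all()


def test_meiosis_mean_crossover_count_is_one():
    """Observed switch count over dense distinguishable haplotypes averages
    ~1 per Morgan (Monte Carlo, 3 standard errors)."""
    L = 5000
    positions = np.linspace(0, 1, L)
    parent = np.stack([np.zeros(L, np.int8), np.ones(L, np.int8)])
    rng = np.random.default_rng(77)
    n_draws = 10_000
    switches = np.empty(n_draws)
    for k in range(n_draws):
        g = meiosis(parent, positions, rng)
        switches[k] = (np.diff(g) != 0).sum()
    se = switches.std(ddof=1) / np.sqrt(n_draws)
    assert abs(switches.mean() - 1.0) < 3 * se + 0.01  # +small dense-map bias


# ---------------------------------------------------------------------------
# simulate_population
# ---------------------------------------------------------------------------

def _small_params(**kw):
    defaults = dict(
        n_snps=120, recent_split_counts=(2,), n_generations_selection=3,
        n_sires=4, n_dams=15, n_offspring_per_breed_gen=100,
        founder_pop_size=40, n_qtn=30, rng_seed=13,
    )
    defaults.update(kw)
    return SimParams(**defaults)


def test_offspring_counts_and_labels(sim_pop):
    pop = sim_pop
    non_founders = pop.generation >= 1
    # 2 breeds x 3 generations x 60 offspring
    assert non_founders.sum() == 2 * 3 * 60
    for b in range(2):
        for g in range(1, 4):
            assert ((pop.breed == b) & (pop.generation == g)).sum() == 60


def test_maf_filter_holds_at_base_generation(sim_pop):
    pop = sim_pop
    founders = pop.generation == 0
    freq = pop.haplotypes[founders].reshape(-1, pop.n_snps).mean(axis=0)
    assert (np.minimum(freq, 1 - freq) >= 0.05).all()


def test_simulation_error_when_too_few_snps():
    with pytest.raises(SimulationError, match="founder_pop_size"):
        simulate_population(_small_params(n_snps=100_000))


def test_positive_selection_differential(sim_pop):
    """Selected sires out-perform their male cohort in every breed-generation."""
    pop = sim_pop
    checked = 0
    for b in range(2):
        for g in range(0, 3):
            cohort = (pop.breed == b) & (pop.generation == g) & (pop.sex == 0)
            sires = cohort & pop.selected_sire
            if sires.any() and cohort.sum() > sires.sum():
                assert pop.phenotype[sires].mean() > pop.phenotype[cohort].mean()
                checked += 1
    assert checked > 0


def test_mendelian_consistency(sim_pop):
    pop = sim_pop
    ped = pop.pedigree
    for k in np.flatnonzero(pop.generation >= 1)[:100]:
        s, d = ped.sire[k], ped.dam[k]
        assert s != UNKNOWN_PARENT and d != UNKNOWN_PARENT
        for slot, parent in ((0, s), (1, d)):
            gamete = pop.haplotypes[k, slot]
            ph = pop.haplotypes[parent]
            assert ((gamete == ph[0]) | (gamete == ph[1])).all()


def test_same_seed_reproduces_population():
    a = simulate_population(_small_params())
    b = simulate_population(_small_params())
    assert a.ids == b.ids
    assert np.array_equal(a.haplotypes, b.haplotypes)
    assert np.array_equal(a.phenotype, b.phenotype)


def test_older_split_gives_larger_divergence():
    """Allele-frequency divergence across the 400-generation split exceeds
    divergence across the 50-generation split."""
    params = SimParams(
        n_snps=150, recent_split_counts=(2, 2), split_generations=(400, 50),
        n_generations_selection=1, n_sires=4, n_dams=15,
        n_offspring_per_breed_gen=30, founder_pop_size=40, n_qtn=10, rng_seed=3,
    )
    pop = simulate_population(params)
    founders = pop.generation == 0

    def freqs(breed):
        rows = founders & (pop.breed == breed)
        return pop.haplotypes[rows].reshape(-1, pop.n_snps).mean(axis=0)

    f = [freqs(b) for b in range(4)]
    # breeds (0,1) and (2,3) split 50 generations ago; across groups 400
    recent = 0.5 * (np.abs(f[0] - f[1]).mean() + np.abs(f[2] - f[3]).mean())
    old = np.mean([np.abs(f[a] - f[b]).mean() for a in (0, 1) for b in (2, 3)])
    assert old > recent


# ---------------------------------------------------------------------------
# array schemes and masking
# ---------------------------------------------------------------------------

def test_md_preset_natural_size():
    scheme = build_array_scheme("md", n_individuals=10, rng=0)
    assert len(scheme.arrays) == 1 and scheme.arrays[0].size == 6711
    assert (scheme.assignment == 0).all()


def test_mixed_md_hd_ratio_and_union():
    scheme = build_array_scheme("mixed_md_hd", n_individuals=1000, rng=0)
    counts = np.bincount(scheme.assignment)
    assert counts.tolist() == [900, 100]  # 9:1
    assert scheme.arrays[0].size == 6711 and scheme.arrays[1].size == 49_579
    union = np.unique(np.concatenate(scheme.arrays))
    assert union.size == PRESETS["mixed_md_hd"]["union"]


@pytest.mark.parametrize("preset", list(PRESETS))
def test_every_preset_covers_the_snp_universe(preset):
    n_snps = 600
    scheme = build_array_scheme(preset, n_individuals=50, n_snps=n_snps, rng=1)
    union = np.unique(np.concatenate(scheme.arrays))
    assert union.size == n_snps


def test_two_array_spec_overlap():
    spec = two_array_spec(0.6)
    scheme = build_array_scheme(spec, n_individuals=100, n_snps=700, rng=2)
    a, b = scheme.arrays
    inter = np.intersect1d(a, b).size
    assert abs(inter / a.size - 0.6) < 0.02


def test_mask_genotypes(sim_pop):
    pop = sim_pop
    full = pop.haplotypes.sum(axis=1).astype(np.int8)
    single = build_array_scheme("md", pop.n_individuals, n_snps=pop.n_snps, rng=0)
    assert (mask_genotypes(pop, single).codes != MISSING).all()
    spec = two_array_spec(0.5)
    scheme = build_array_scheme(spec, pop.n_individuals, n_snps=pop.n_snps, rng=3)
    masked = mask_genotypes(pop, scheme).codes
    for k in range(pop.n_individuals):
        on = scheme.arrays[scheme.assignment[k]]
        off = np.setdiff1d(np.arange(pop.n_snps), on)
        assert (masked[k, on] == full[k, on]).all()
        assert (masked[k, off] == MISSING).all()
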