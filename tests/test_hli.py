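"""Haplotype library imputation: matching, merging, insertion, iteration."""

import numpy as np
import pytest

from lrhap.exceptions import ValidationError
from lrhap.haplotypes import CoreLibrary
from lrhap.hli import (
    hli_phase_core,
    maintain_library,
    match_haplotype,
    merge_library_entries,
    update_library,
)
from lrhap.types import MISSING, PhasingParams


def _params(**kw):
    defaults = dict(min_match_alleles=200, library_cluster_mismatches=0,
                    min_phased_frac_library=0.80)
    defaults.update(kw)
    return PhasingParams(**defaults)


def _h(length, fill=0):
    return np.full(length, fill, dtype=np.int8)


# ---------------------------------------------------------------------------
# match_haplotype
# ---------------------------------------------------------------------------

def test_match_needs_enough_co_observed_alleles():
    params = _params()
    lib = CoreLibrary(300)
    entry = _h(300, MISSING)
    entry[:250] = 0
    lib.add(entry)
    h = _h(300, MISSING)
    h[:250] = 0
    assert match_haplotype(h, lib, params) == [0]   # 250 co-observed, 0 mismatches
    h2 = _h(300, MISSING)
    h2[:150] = 0
    assert match_haplotype(h2, lib, params) == []   # 150 < 200 required


def test_single_mismatch_breaks_identity_at_zero_allowance():
    params = _params()
    lib = CoreLibrary(300)
    entry = _h(300, 0)
    lib.add(entry)
    h = _h(300, 0)
    h[7] = 1
    assert match_haplotype(h, lib, params) == []
    assert match_haplotype(h, lib, _params(library_cluster_mismatches=1)) == [0]


# ---------------------------------------------------------------------------
# merge_library_entries
# ---------------------------------------------------------------------------

def test_merge_complementary_partials_covers_union():
    """Two haplotypes observed on complementary SNP subsets that agree on
    the intersection merge into one haplotype observed on the union."""
    lib = CoreLibrary(10)
    a = np.array([0, 1, 0, 1, 0, MISSING, MISSING, MISSING, 0, 1], dtype=np.int8)
    b = np.array([MISSING, MISSING, MISSING, 1, 0, 1, 1, 0, 0, 1], dtype=np.int8)
    ea = lib.add(a, count=3, carriers={(0, 0)})
    eb = lib.add(b, count=2, carriers={(1, 1)})
    merged = merge_library_entries(lib, [ea, eb])
    out = lib.alleles(merged)
    assert out.tolist() == [0, 1, 0, 1, 0, 1, 1, 0, 0, 1]
    assert lib.counts[merged] == 5
    assert lib.carriers[merged] == {(0, 0), (1, 1)}
    assert not lib.is_alive(ea) and not lib.is_alive(eb)


def test_merge_identical_copy_sums_counts():
    lib = CoreLibrary(6)
    a = np.array([0, 1, 1, 0, 1, 0], dtype=np.int8)
    e1 = lib.add(a.copy(), count=4)
    e2 = lib.add(a.copy(), count=1)
    merged = merge_library_entries(lib, [e1, e2])
    assert np.array_equal(lib.alleles(merged), a)
    assert lib.counts[merged] == 5


def test_merge_rejects_conflicting_entries():
    lib = CoreLibrary(4)
    e1 = lib.add(np.array([0, 0, 1, 1], dtype=np.int8))
    e2 = lib.add(np.array([0, 1, 1, 1], dtype=np.int8))
    with pytest.raises(ValidationError, match="opposing"):
        merge_library_entries(lib, [e1, e2])


def test_transitive_merge_through_new_haplotype():
    """Three pairwise non-overlapping partial entries are recognised as one
    haplotype by a new haplotype that matches all of them."""
    L = 30
    params = _params(min_match_alleles=10)
    truth = np.tile(np.array([0, 1, 1], dtype=np.int8), 10)
    lib = CoreLibrary(L)
    for block in range(3):
        part = np.full(L, MISSING, dtype=np.int8)
        part[block * 10 : (block + 1) * 10] = truth[block * 10 : (block + 1) * 10]
        lib.add(part, count=1)
    assert lib.n_entries == 3
    update_library(lib, truth.copy(), carrier=(9, 0),
                   genotyped=np.ones(L, bool), params=params)
    assert lib.n_entries == 1
    (eid,) = lib.entry_ids()
    assert np.array_equal(lib.alleles(eid), truth)


# ---------------------------------------------------------------------------
# update_library
# ---------------------------------------------------------------------------

def test_underphased_haplotype_rejected_at_80_percent():
    L = 100
    params = _params(min_match_alleles=10)
    lib = CoreLibrary(L)
    h = np.full(L, MISSING, dtype=np.int8)
    h[:70] = 1  # 70% phased of 100 genotyped
    assert update_library(lib, h, (0, 0), np.ones(L, bool), params) is None
    assert lib.n_entries == 0
    h[:85] = 1
    assert update_library(lib, h, (0, 0), np.ones(L, bool), params) is not None


def test_phased_fraction_counts_only_genotyped_snps():
    """An individual genotyped on half the core can contribute a haplotype
    phased only at its own array's SNPs."""
    L = 100
    params = _params(min_match_alleles=10)
    lib = CoreLibrary(L)
    genotyped = np.zeros(L, bool)
    genotyped[:50] = True
    h = np.full(L, MISSING, dtype=np.int8)
    h[:45] = 0  # 45/50 = 90% of genotyped SNPs, 45% of the core
    assert update_library(lib, h, (0, 0), genotyped, params) is not None


def test_conflicting_matches_insert_new_entry():
    L = 40
    params = _params(min_match_alleles=10)
    lib = CoreLibrary(L)
    # two entries that match a new haplotype on disjoint halves but
    # conflict with each other on a shared middle stretch
    a = np.full(L, MISSING, dtype=np.int8)
    a[:25] = 0
    b = np.full(L, MISSING, dtype=np.int8)
    b[15:] = 1
    ea = lib.add(a)
    eb = lib.add(b)
    h = np.full(L, MISSING, dtype=np.int8)
    h[:15] = 0
    h[25:] = 1  # matches a on [0,15), b on [25,40); a and b conflict on [15,25)
    eid = update_library(lib, h, (0, 0), genotyped=h != MISSING, params=params)
    assert lib.is_alive(ea) and lib.is_alive(eb)
    assert eid not in (ea, eb)
    assert lib.n_entries == 3


# ---------------------------------------------------------------------------
# maintenance + iteration
# ---------------------------------------------------------------------------

def test_maintenance_leaves_no_matching_pair(rng):
    L = 60
    params = _params(min_match_alleles=15)
    lib = CoreLibrary(L)
    base = rng.integers(0, 2, size=L).astype(np.int8)
    for k in range(6):
        part = base.copy()
        mask = rng.random(L) < 0.3
        part[mask] = MISSING
        lib.add(part, count=1)
    maintain_library(lib, params)
    ids = lib.entry_ids()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            ha, hb = lib.alleles(ids[a]), lib.alleles(ids[b])
            both = (ha != MISSING) & (hb != MISSING)
            conflict_free = (ha[both] == hb[both]).all()
            assert not (conflict_free and both.sum() >= params.min_match_alleles)


def test_fully_phased_gamete_resolves_partner_in_one_pass():
    L = 12
    params = _params(min_match_alleles=6)
    codes = np.ones((1, L), dtype=np.int8)  # heterozygous everywhere
    haps = np.stack([
        np.stack([np.tile(np.array([0, 1], np.int8), 6),
                  np.full(L, MISSING, np.int8)])
    ])
    lib = CoreLibrary(L)
    out, _ = hli_phase_core(codes, haps, lib, params)
    assert (out[0, 1] == 1 - out[0, 0]).all()


def test_empty_library_and_underphased_input_terminates_unchanged():
    L = 20
    params = _params(min_match_alleles=10)
    codes = np.ones((2, L), dtype=np.int8)
    haps = np.full((2, 2, L), MISSING, dtype=np.int8)
    haps[:, :, 0] = [[0, 1], [1, 0]]  # 5% phased: below the 80% library bar
    before = haps.copy()
    out, lib = hli_phase_core(codes, haps, CoreLibrary(L), params)
    assert np.array_equal(out, before)
    assert lib.n_entries == 0


def test_hli_completes_founder_haplotypes_to_truth(rng):
    """20 individuals drawn from 3 founder haplotypes with partial phase:
    HLI completes every pair to the truth."""
    L = 60
    params = _params(min_match_alleles=12)
    founders = rng.integers(0, 2, size=(3, L)).astype(np.int8)
    picks = rng.integers(0, 3, size=(20, 2))
    truth = founders[picks]  # (20, 2, L)
    codes = truth.sum(axis=1).astype(np.int8)
    haps = truth.copy()
    # blank a random 15% of alleles, keeping each gamete above 80% phased
    mask = rng.random((20, 2, L)) < 0.15
    haps[mask] = MISSING
    out, lib = hli_phase_core(codes.copy(), haps, CoreLibrary(L), params)
    # orientation per individual is fixed by construction here: compare both
    for k in range(20):
        direct = (out[k] == truth[k]).all()
        swapped = (out[k] == truth[k, ::-1]).all()
        assert direct or swapped


def test_phased_count_monotone_and_terminates(founder_pop, founder_params):
    from lrhap.subsetting import phase_by_subsets
    from lrhap.hli import hli_phase
    from lrhap.haplotypes import HaplotypeLibrary

    genotypes, pedigree, _ = founder_pop
    haps, cores = phase_by_subsets(genotypes, pedigree, founder_params)
    n_before = (haps != MISSING).sum()
    out, _ = hli_phase(genotypes.codes, haps, cores, HaplotypeLibrary(cores),
                       founder_params)
    assert (out != MISSING).sum() >= n_before


def test_no_fill_contradicts_genotype(founder_pop, founder_params):
    from lrhap.subsetting import phase_by_subsets
    from lrhap.hli import hli_phase
    from lrhap.haplotypes import HaplotypeLibrary

    genotypes, pedigree, _ = founder_pop
    haps, cores = phase_by_subsets(genotypes, pedigree, founder_params)
    out, _ = hli_phase(genotypes.codes, haps, cores, HaplotypeLibrary(cores),
                       founder_params)
    codes = genotypes.codes
    for slot in (0, 1):
        assert (out[:, slot, :][codes == 0] == 0).all()
        assert (out[:, slot, :][codes == 2] == 1).all()
    het = codes == 1
    both = het & (out[:, 0, :] != MISSING) & (out[:, 1, :] != MISSING)
    assert (out[:, 0, :][both] != out[:, 1, :][both]).all()


def test_merge_order_independent(rng):
    """Pairwise-compatible partials merge to the same entry regardless of
    insertion order."""
    L = 40
    params = _params(min_match_alleles=8)
    base = rng.integers(0, 2, size=L).astype(np.int8)
    parts = []
    for k in range(4):
        p = base.copy()
        p[rng.random(L) < 0.25] = MISSING
        parts.append(p)
    results = []
    for order in ([0, 1, 2, 3], [3, 1, 0, 2]):
        lib = CoreLibrary(L)
        for k in order:
            update_library(lib, parts[k].copy(), (k, 0), np.ones(L, bool), params)
        maintain_library(lib, params)
        assert lib.n_entries == 1
        (eid,) = lib.entry_ids()
        results.append(lib.alleles(eid).copy())
    assert np.array_equal(results[0], results[1])
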