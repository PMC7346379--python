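"""Core partitioning, surrogate detection, side assignment and LRP voting."""

import numpy as np
import pytest

from lrhap.bits import pack
from lrhap.evaluate import phasing_statistics
from lrhap.exceptions import ParameterError
from lrhap.experiments import desk_params, founder_dataset
from lrhap.lrp import (
    SIDE_MATERNAL,
    SIDE_PATERNAL,
    SIDE_UNKNOWN,
    SurrogateGraph,
    build_surrogate_graph,
    opposing_and_shared,
    partition_cores,
    partition_sides,
    phase_core,
    phase_core_lrp,
)
from lrhap.subsetting import phase_by_subsets
from lrhap.types import MISSING, Core, GenotypeMatrix, PhasingParams


# ---------------------------------------------------------------------------
# partition_cores
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n,L,expected",
    [
        (100, 50, [(0, 50), (50, 100)]),
        (105, 50, [(0, 50), (50, 105)]),            # remainder 5 < 25 absorbed
        (130, 50, [(0, 50), (50, 100), (100, 130)]),  # remainder 30 >= 25 stands
        (50, 50, [(0, 50)]),
    ],
)
def test_partition_cores_tiling(n, L, expected):
    cores = partition_cores(n, L)
    assert [(c.start, c.end) for c in cores] == expected


def test_partition_cores_invalid_length():
    with pytest.raises(ParameterError):
        partition_cores(100, 0)
    with pytest.raises(ParameterError):
        partition_cores(100, 101)


# ---------------------------------------------------------------------------
# opposing / shared and the surrogate graph
# ---------------------------------------------------------------------------

def test_opposing_and_shared_example():
    m = GenotypeMatrix(
        ids=["i", "j"],
        codes=np.array([[0, 2, 1, MISSING], [2, 2, MISSING, 0]], dtype=np.int8),
    )
    assert opposing_and_shared(pack(m), 0, 1, Core(0, 4)) == (1, 2)


def test_identical_rows_share_everything(rng):
    codes = rng.integers(-1, 3, size=30).astype(np.int8)
    m = GenotypeMatrix(ids=["a", "b"], codes=np.stack([codes, codes]))
    n_opp, n_shr = opposing_and_shared(pack(m), 0, 1, Core(0, 30))
    assert n_opp == 0 and n_shr == (codes != MISSING).sum()


def test_surrogate_graph_equals_bruteforce_oracle(rng):
    """Graph over 20 random individuals equals exhaustive pairwise testing."""
    codes = rng.integers(0, 3, size=(20, 80)).astype(np.int8)
    codes[rng.random(codes.shape) < 0.3] = MISSING
    params = PhasingParams(min_shared_markers=20, surrogate_disagree_frac=0.10)
    core = Core(10, 75)
    graph = build_surrogate_graph(codes, core, params)
    for i in range(20):
        for j in range(20):
            n_opp = n_shr = 0
            for s in range(core.start, core.end):
                a, b = codes[i, s], codes[j, s]
                if a != MISSING and b != MISSING:
                    n_shr += 1
                    if {a, b} == {0, 2}:
                        n_opp += 1
            expect = (
                i != j
                and n_shr >= params.min_shared_markers
                and n_opp <= int(params.surrogate_disagree_frac * n_shr)
            )
            assert graph.is_surrogate[i, j] == expect


def test_surrogacy_boundary_of_disagreement_rule():
    """n_shared=100 with n_opposing=10 at a 10% allowance is a surrogate."""
    base = np.ones(100, dtype=np.int8) * 1
    a = base.copy()
    b = base.copy()
    a[:10] = 0
    b[:10] = 2  # exactly 10 opposing out of 100 shared
    codes = np.stack([a, b])
    params = PhasingParams(min_shared_markers=3, surrogate_disagree_frac=0.10)
    graph = build_surrogate_graph(codes, Core(0, 100), params)
    assert graph.is_surrogate[0, 1]
    # one more opposing tips it over
    a[10] = 0
    b[10] = 2
    graph = build_surrogate_graph(np.stack([a, b]), Core(0, 100), params)
    assert not graph.is_surrogate[0, 1]


def test_min_shared_blocks_testing():
    codes = np.array([[0, 0, MISSING, MISSING], [0, 0, MISSING, MISSING]],
                     dtype=np.int8)
    params = PhasingParams(min_shared_markers=3)
    graph = build_surrogate_graph(codes, Core(0, 4), params)
    assert not graph.is_surrogate[0, 1]


def test_raising_min_shared_never_adds_edges(rng):
    codes = rng.integers(-1, 3, size=(15, 60)).astype(np.int8)
    core = Core(0, 60)
    lo = build_surrogate_graph(codes, core, PhasingParams(min_shared_markers=5))
    hi = build_surrogate_graph(codes, core, PhasingParams(min_shared_markers=25))
    assert not (hi.is_surrogate & ~lo.is_surrogate).any()


# ---------------------------------------------------------------------------
# side partitioning
# ---------------------------------------------------------------------------

def test_sire_surrogate_labeled_paternal():
    # individual 0 with sire 1 and dam 2; 1 and 2 both surrogates of 0
    is_surr = np.zeros((3, 3), dtype=bool)
    is_surr[0, 1] = is_surr[1, 0] = True
    is_surr[0, 2] = is_surr[2, 0] = True
    graph = SurrogateGraph(
        core=Core(0, 10),
        n_opposing=np.zeros((3, 3), np.int32),
        n_shared=np.full((3, 3), 10, np.int32),
        is_surrogate=is_surr,
        sides=np.zeros((3, 3), np.int8),
    )
    labels = partition_sides(graph, 0, sire=1, dam=2)
    assert labels[1] == SIDE_PATERNAL and labels[2] == SIDE_MATERNAL


def test_surrogate_of_both_parents_is_unknown():
    is_surr = np.zeros((4, 4), dtype=bool)
    # 3 is a surrogate of focal 0, of sire 1 and of dam 2
    for a, b in [(0, 3), (1, 3), (2, 3), (0, 1), (0, 2)]:
        is_surr[a, b] = is_surr[b, a] = True
    graph = SurrogateGraph(
        core=Core(0, 10),
        n_opposing=np.zeros((4, 4), np.int32),
        n_shared=np.full((4, 4), 10, np.int32),
        is_surrogate=is_surr,
        sides=np.zeros((4, 4), np.int8),
    )
    labels = partition_sides(graph, 0, sire=1, dam=2)
    assert labels[3] == SIDE_UNKNOWN


def test_anchor_clustering_recovers_sides_from_founder_haplotypes():
    """Pedigree-free toy built from 4 known founder haplotypes: individuals
    sharing the focal's paternal haplotype cluster with the anchor, those
    carrying only the maternal haplotype land on the other side."""
    rng = np.random.default_rng(123)
    H = rng.integers(0, 2, size=(4, 60)).astype(np.int8)  # founder haplotypes
    pairs = [(0, 1), (0, 2), (0, 3), (1, 3)]  # focal, pat-sharing x2, mat-sharing
    codes = np.stack([H[a] + H[b] for a, b in pairs]).astype(np.int8)
    params = PhasingParams(min_shared_markers=10, surrogate_disagree_frac=0.0)
    graph = build_surrogate_graph(codes, Core(0, 60), params)
    assert graph.is_surrogate[0, [1, 2, 3]].all()
    labels = partition_sides(graph, 0, params=params)
    assert labels[1] == SIDE_PATERNAL and labels[2] == SIDE_PATERNAL
    assert labels[3] == SIDE_MATERNAL


# ---------------------------------------------------------------------------
# LRP voting
# ---------------------------------------------------------------------------

def _manual_graph(codes, sides_for_0):
    m = codes.shape[0]
    is_surr = np.zeros((m, m), dtype=bool)
    sides = np.zeros((m, m), dtype=np.int8)
    for s, side in sides_for_0.items():
        is_surr[0, s] = is_surr[s, 0] = True
        sides[0, s] = side
    return SurrogateGraph(
        core=Core(0, codes.shape[1]),
        n_opposing=np.zeros((m, m), np.int32),
        n_shared=np.full((m, m), codes.shape[1], np.int32),
        is_surrogate=is_surr,
        sides=sides,
    )


def test_single_homozygous_surrogate_phases_het_snp():
    codes = np.array([[1, 1], [0, 1]], dtype=np.int8)
    graph = _manual_graph(codes, {1: SIDE_PATERNAL})
    pair = phase_core_lrp(0, graph, codes, PhasingParams(consensus_agreement_frac=0.9))
    assert pair[0, 0] == 0 and pair[1, 0] == 1  # paternal 0, maternal complement


def test_split_votes_leave_allele_missing():
    # two paternal surrogates voting opposite alleles at SNP 0
    codes = np.array([[1, 1], [0, 1], [2, 1]], dtype=np.int8)
    graph = _manual_graph(codes, {1: SIDE_PATERNAL, 2: SIDE_PATERNAL})
    pair = phase_core_lrp(0, graph, codes, PhasingParams(consensus_agreement_frac=0.9))
    assert pair[0, 0] == MISSING and pair[1, 0] == MISSING


def test_zero_surrogate_individual_gets_genotype_forced_phase_only():
    codes = np.array([[0, 2, 1, MISSING]], dtype=np.int8)
    graph = _manual_graph(codes, {})
    pair = phase_core_lrp(0, graph, codes, PhasingParams())
    assert pair.tolist() == [[0, 1, MISSING, MISSING], [0, 1, MISSING, MISSING]]


def test_phase_never_contradicts_genotype(rng):
    codes = rng.integers(-1, 3, size=(30, 50)).astype(np.int8)
    params = PhasingParams(min_shared_markers=10, surrogate_disagree_frac=0.1,
                           consensus_agreement_frac=0.6)
    graph = build_surrogate_graph(codes, Core(0, 50), params)
    graph.sides[graph.is_surrogate] = SIDE_PATERNAL
    haps = phase_core(codes, graph, params)
    hom0 = codes == 0
    hom2 = codes == 2
    het = codes == 1
    for slot in (0, 1):
        assert (haps[:, slot, :][hom0] == 0).all()
        assert (haps[:, slot, :][hom2] == 1).all()
    both = het & (haps[:, 0, :] != MISSING) & (haps[:, 1, :] != MISSING)
    assert (haps[:, 0, :][both] != haps[:, 1, :][both]).all()


def test_lrp_is_deterministic(founder_pop, founder_params):
    genotypes, pedigree, _ = founder_pop
    a, _ = phase_by_subsets(genotypes, pedigree, founder_params)
    b, _ = phase_by_subsets(genotypes, pedigree, founder_params)
    assert np.array_equal(a, b)


def test_lrp_recovers_truth_on_founder_simulation():
    """50 individuals bred from 4 founder haplotypes, complete genotypes,
    known pedigree: LRP phase checked against the simulation truth."""
    genotypes, pedigree, truth = founder_dataset(
        n_individuals=50, n_snps=200, n_founder_haplotypes=4,
        offspring_per_generation=20, seed=9,
    )
    params = desk_params(200, subset_size=50, rng_seed=2, core_length=50,
                         min_match_alleles=20, min_shared_markers=25)
    haps, cores = phase_by_subsets(genotypes, pedigree, params)
    stats = phasing_statistics(haps, truth, genotypes, cores, scope="heterozygous")
    assert stats.percent_correct > 75.0
    assert stats.percent_incorrect < 5.0
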