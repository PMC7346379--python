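"""Long-range phasing within a set of individuals.

Phasing proceeds core by core.  Within a core, two individuals are
*surrogates* when they share a haplotype, detected by (near-)absence of
opposing homozygous genotypes across the markers both were genotyped on.
Surrogates are partitioned into paternal and maternal sides (by pedigree
when available, otherwise by clustering around an anchor surrogate), and
each side's homozygous surrogates — reached directly or through chains of
surrogates of surrogates — vote on the focal individual's allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import lrp_vote_kernel
from .bits import opposing_and_shared, pairwise_opposing_shared  # noqa: F401 (re-export)
from .exceptions import ParameterError
from .haplotypes import complement_from_genotype
from .types import MISSING, UNKNOWN_PARENT, Core, Pedigree, PhasingParams

SIDE_UNKNOWN, SIDE_PATERNAL, SIDE_MATERNAL = 0, 1, 2


def partition_cores(n_snps: int, core_length: int) -> list[Core]:
    """Tile ``[0, n_snps)`` into consecutive cores of ``core_length`` SNPs.

    A terminal remainder shorter than half a core is absorbed into the final
    core; a longer remainder stands as its own core.
    """
    if core_length <= 0:
        raise ParameterError(f"core_length must be positive, got {core_length}")
    if core_length > n_snps:
        raise ParameterError(
            f"core_length {core_length} exceeds the number of SNPs {n_snps}"
        )
    starts = list(range(0, n_snps, core_length))
    cores = [Core(s, min(s + core_length, n_snps)) for s in starts]
    if len(cores) >= 2 and len(cores[-1]) < core_length / 2:
        last = cores.pop()
        prev = cores.pop()
        cores.append(Core(prev.start, last.end))
    return cores


@dataclass
class SurrogateGraph:
    """Surrogate relations for one core over one subset of individuals.

    Indices are subset-local (0..m-1).  ``sides[i, s]`` labels surrogate
    ``s`` of focal individual ``i``; sides are directional (the label of
    ``s`` from ``i``'s viewpoint), surrogacy itself is symmetric.
    """

    core: Core
    n_opposing: np.ndarray   # (m, m) int32
    n_shared: np.ndarray     # (m, m) int32
    is_surrogate: np.ndarray  # (m, m) bool, False on the diagonal
    sides: np.ndarray        # (m, m) int8

    @property
    def n_individuals(self) -> int:
        return self.is_surrogate.shape[0]

    def surrogates_of(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.is_surrogate[i])


def _disagree_allowance(n_shared: np.ndarray, frac: float) -> np.ndarray:
    return np.floor(frac * n_shared).astype(np.int64)


def build_surrogate_graph(
    codes: np.ndarray, core: Core, params: PhasingParams
) -> SurrogateGraph:
    """Detect all surrogate pairs within a core.

    ``j`` is a surrogate of ``i`` iff they share at least
    ``min_shared_markers`` genotyped markers in the core and their
    opposing-homozygote count does not exceed
    ``floor(surrogate_disagree_frac * n_shared)``.

    Parameters
    ----------
    codes
        ``(m, n_snps)`` int8 genotype codes for the subset.
    """
    sub = np.ascontiguousarray(codes[:, core.slice()])
    n_opp, n_shr = pairwise_opposing_shared(sub)
    allow = _disagree_allowance(n_shr, params.surrogate_disagree_frac)
    is_surr = (n_shr >= params.min_shared_markers) & (n_opp <= allow)
    np.fill_diagonal(is_surr, False)
    sides = np.zeros(is_surr.shape, dtype=np.int8)
    return SurrogateGraph(
        core=core, n_opposing=n_opp, n_shared=n_shr, is_surrogate=is_surr, sides=sides
    )


def partition_sides(
    graph: SurrogateGraph,
    i: int,
    sire: int | None = None,
    dam: int | None = None,
    params: PhasingParams | None = None,
) -> np.ndarray:
    """Label individual ``i``'s surrogates paternal/maternal/unknown.

    With pedigree (``sire``/``dam`` given as subset-local indices, or None
    when unknown or outside the subset): a surrogate is paternal when it is
    the sire or a surrogate of the sire and not likewise linked to the dam;
    maternal symmetrically; linked to both or neither -> unknown.

    Without any parent in the subset, anchor clustering is used: the
    surrogate sharing the most markers with ``i`` anchors the paternal side;
    surrogates of the anchor join it, surrogates with opposing-homozygote
    conflicts against the anchor beyond the disagreement allowance go
    maternal, the rest stay unknown.
    """
    params = params or PhasingParams()
    surr = graph.surrogates_of(i)
    labels = np.zeros(graph.n_individuals, dtype=np.int8)
    if surr.size == 0:
        return labels
    if sire is not None or dam is not None:
        pat = np.zeros(graph.n_individuals, dtype=bool)
        mat = np.zeros(graph.n_individuals, dtype=bool)
        if sire is not None:
            pat[surr] = (surr == sire) | graph.is_surrogate[surr, sire]
        if dam is not None:
            mat[surr] = (surr == dam) | graph.is_surrogate[surr, dam]
        labels[pat & ~mat] = SIDE_PATERNAL
        labels[mat & ~pat] = SIDE_MATERNAL
        return labels
    # pedigree-free: anchor clustering
    shared = graph.n_shared[i, surr]
    anchor = surr[np.argmax(shared)]  # argmax takes the first on ties
    labels[anchor] = SIDE_PATERNAL
    others = surr[surr != anchor]
    if others.size:
        with_anchor = graph.is_surrogate[others, anchor]
        allow = _disagree_allowance(
            graph.n_shared[others, anchor], params.surrogate_disagree_frac
        )
        against_anchor = graph.n_opposing[others, anchor] > allow
        labels[others[with_anchor]] = SIDE_PATERNAL
        labels[others[~with_anchor & against_anchor]] = SIDE_MATERNAL
    return labels


def parent_rows(pedigree: Pedigree | None, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Map each genotype row to its parents' genotype rows (-1 if unknown
    or not genotyped)."""
    n = len(ids)
    sire_rows = np.full(n, -1, dtype=np.int64)
    dam_rows = np.full(n, -1, dtype=np.int64)
    if pedigree is None:
        return sire_rows, dam_rows
    row_of = {ident: k for k, ident in enumerate(ids)}
    ped_of = {ident: k for k, ident in enumerate(pedigree.ids)}
    for k, ident in enumerate(ids):
        p = ped_of.get(ident)
        if p is None:
            continue
        for arr, parent in ((sire_rows, pedigree.sire[p]), (dam_rows, pedigree.dam[p])):
            if parent != UNKNOWN_PARENT:
                arr[k] = row_of.get(pedigree.ids[parent], -1)
    return sire_rows, dam_rows


def assign_all_sides(
    graph: SurrogateGraph,
    subset_global: np.ndarray,
    sire_rows: np.ndarray,
    dam_rows: np.ndarray,
    params: PhasingParams,
) -> None:
    """Fill ``graph.sides`` for every focal individual (in place).

    ``subset_global`` maps subset-local indices to global genotype rows;
    ``sire_rows``/``dam_rows`` give each global row's parents as global rows
    (-1 = unknown).  Individuals with no parent inside the subset fall back
    to anchor clustering.
    """
    local_of = {int(g): l for l, g in enumerate(subset_global)}
    for i in range(graph.n_individuals):
        g = int(subset_global[i])
        sire = local_of.get(int(sire_rows[g])) if sire_rows[g] >= 0 else None
        dam = local_of.get(int(dam_rows[g])) if dam_rows[g] >= 0 else None
        if sire is None and dam is None:
            graph.sides[i] = partition_sides(graph, i, params=params)
        else:
            graph.sides[i] = partition_sides(graph, i, sire=sire, dam=dam, params=params)


def _graph_csr(graph: SurrogateGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rows, cols = np.nonzero(graph.is_surrogate)
    indptr = np.zeros(graph.n_individuals + 1, dtype=np.int64)
    np.add.at(indptr[1:], rows, 1)
    indptr = np.cumsum(indptr)
    return indptr, cols.astype(np.int64), graph.sides[rows, cols]


def phase_core(
    codes: np.ndarray, graph: SurrogateGraph, params: PhasingParams
) -> np.ndarray:
    """Long-range phase every individual of a subset over one core.

    Returns ``(m, 2, core_length)`` alleles; slot 0 is the paternal gamete
    where the pedigree informed sides, otherwise the orientation is fixed
    but arbitrary.  Output never contradicts the genotypes: homozygous SNPs
    are forced, and heterozygous SNPs where the two sides' votes collide are
    left unphased.
    """
    core = graph.core
    sub = np.ascontiguousarray(codes[:, core.slice()])
    m, L = sub.shape
    out = np.full((m, 2, L), MISSING, dtype=np.int8)
    indptr, indices, edge_sides = _graph_csr(graph)
    lrp_vote_kernel(
        sub,
        indptr,
        indices,
        edge_sides,
        params.max_surrogates,
        params.max_surrogate_depth,
        params.consensus_agreement_frac,
        out,
    )
    # genotype-forced positions override any vote
    hom0 = sub == 0
    hom2 = sub == 2
    for slot in (0, 1):
        out[:, slot, :][hom0] = 0
        out[:, slot, :][hom2] = 1
    # heterozygous SNPs where both sides voted the same allele: conflict -> blank
    het = sub == 1
    clash = het & (out[:, 0, :] != MISSING) & (out[:, 0, :] == out[:, 1, :])
    out[:, 0, :][clash] = MISSING
    out[:, 1, :][clash] = MISSING
    # complement each gamete from the genotype
    for i in range(m):
        pat, mat = out[i, 0], out[i, 1]
        comp = complement_from_genotype(sub[i], pat)
        fill = (mat == MISSING) & (comp != MISSING)
        mat[fill] = comp[fill]
        comp = complement_from_genotype(sub[i], mat)
        fill = (pat == MISSING) & (comp != MISSING)
        pat[fill] = comp[fill]
    return out


def phase_core_lrp(
    i: int, graph: SurrogateGraph, codes: np.ndarray, params: PhasingParams
) -> np.ndarray:
    """Phase a single individual over the graph's core (``(2, core_length)``)."""
    return phase_core(codes, graph, params)[i]
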