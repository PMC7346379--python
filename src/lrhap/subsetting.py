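"""Scaling long-range phasing to large datasets by random sub-setting.

Finding surrogates is an all-against-all search, so its cost grows with
the square of the number of individuals.  Partitioning the individuals
into random subsets, running LRP inside each subset and merging the
per-subset results bounds the quadratic term at ``subset_size`` while the
subsequent haplotype-library imputation step recovers the across-subset
information.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ParameterError
from .lrp import (
    assign_all_sides,
    build_surrogate_graph,
    parent_rows,
    partition_cores,
    phase_core,
)
from .types import MISSING, Core, GenotypeMatrix, Pedigree, PhasingParams


def make_subsets(ids: list[str], subset_size: int, rng_seed: int) -> list[list[str]]:
    """Randomly partition ``ids`` into disjoint subsets covering all of them.

    Each subset holds exactly ``subset_size`` members except the last, which
    holds the remainder; a remainder smaller than half a subset is folded
    into the previous subset.
    """
    if subset_size < 2:
        raise ParameterError(f"subset_size must be at least 2, got {subset_size}")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[k] for k in order]
    subsets = [shuffled[lo : lo + subset_size] for lo in range(0, len(ids), subset_size)]
    if len(subsets) >= 2 and len(subsets[-1]) < subset_size / 2:
        tail = subsets.pop()
        subsets[-1].extend(tail)
    return subsets


def phase_by_subsets(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree | None,
    params: PhasingParams,
    cores: list[Core] | None = None,
) -> tuple[np.ndarray, list[Core]]:
    """Run per-subset LRP over every core and merge the results.

    Each individual is phased using only the members of its own subset
    (pedigree links crossing subset boundaries are simply absent).  Within
    a subset, individuals are processed in their original input order, so
    the merged output does not depend on subset processing order and a
    subset size >= n reproduces the whole-set run exactly.

    Returns
    -------
    (haplotypes, cores)
        ``(n, 2, n_snps)`` int8 alleles ({0, 1, MISSING}) and the core
        tiling used.
    """
    if cores is None:
        cores = partition_cores(genotypes.n_snps, params.core_length)
    n = genotypes.n_individuals
    haps = np.full((n, 2, genotypes.n_snps), MISSING, dtype=np.int8)
    sire_rows, dam_rows = parent_rows(pedigree, genotypes.ids)
    row_of = {ident: k for k, ident in enumerate(genotypes.ids)}
    subsets = make_subsets(genotypes.ids, params.subset_size, params.rng_seed)
    for subset in subsets:
        member_rows = np.sort(np.asarray([row_of[i] for i in subset], dtype=np.int64))
        codes = genotypes.codes[member_rows]
        for core in cores:
            graph = build_surrogate_graph(codes, core, params)
            assign_all_sides(graph, member_rows, sire_rows, dam_rows, params)
            haps[member_rows, :, core.start : core.end] = phase_core(codes, graph, params)
    return haps, cores
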