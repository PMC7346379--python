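"""End-to-end orchestration: (optional) simulate -> subsetted LRP -> HLI
-> (optional) evaluate."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .evaluate import PhasingStats, grouped_stats, phasing_statistics
from .exceptions import ParameterError, ValidationError
from .haplotypes import HaplotypeLibrary
from .hli import hli_phase
from .lrp import partition_cores
from .popsim import ArrayScheme, SimParams, TruePopulation, build_array_scheme, mask_genotypes
from .subsetting import phase_by_subsets
from .types import Core, GenotypeMatrix, Pedigree, PhasingParams

logger = logging.getLogger("lrhap")


@dataclass
class PipelineResult:
    haplotypes: np.ndarray          # (n, 2, n_snps); unphased = MISSING
    cores: list[Core]
    library: HaplotypeLibrary
    genotypes: GenotypeMatrix
    truth: TruePopulation | None = None
    stats: dict | None = None


def phase_dataset(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree | None,
    params: PhasingParams,
    library_in: HaplotypeLibrary | None = None,
    core_indices: list[int] | None = None,
) -> tuple[np.ndarray, list[Core], HaplotypeLibrary]:
    """Subsetted LRP followed by HLI; the core of the pipeline.

    ``core_indices`` restricts computation to the named cores (for per-core
    parallel runs); SNPs outside them stay unphased.  A prior library's
    entries seed HLI (its core tiling must match).
    """
    if params.core_length > genotypes.n_snps:
        raise ParameterError(
            f"core_length {params.core_length} exceeds n_snps {genotypes.n_snps}"
        )
    all_cores = partition_cores(genotypes.n_snps, params.core_length)
    if library_in is not None:
        if list(library_in.cores) != all_cores:
            raise ValidationError("prior library core tiling does not match this dataset")
        library = library_in
    else:
        library = HaplotypeLibrary(all_cores)
    run_cores = (
        all_cores if core_indices is None else [all_cores[k] for k in core_indices]
    )
    logger.info(
        "phasing %d individuals x %d SNPs: %d core(s), subset size %d, seed %d",
        genotypes.n_individuals, genotypes.n_snps, len(run_cores),
        params.subset_size, params.rng_seed,
    )
    haps, _ = phase_by_subsets(genotypes, pedigree, params, cores=run_cores)
    for k, core in enumerate(all_cores):
        if core not in run_cores:
            continue
        logger.info("HLI on core %d [%d, %d)", k, core.start, core.end)
        hli_phase(genotypes.codes, haps, [core],
                  _single_core_view(library, k), params)
    return haps, all_cores, library


class _single_core_view:
    """Adapter exposing one core of a HaplotypeLibrary as index 0."""

    def __init__(self, library: HaplotypeLibrary, k: int):
        self._library = library
        self._k = k

    def __getitem__(self, idx: int):
        assert idx == 0
        return self._library[self._k]


def run_pipeline(
    params: PhasingParams | None = None,
    genotypes: GenotypeMatrix | None = None,
    pedigree: Pedigree | None = None,
    sim_params: SimParams | None = None,
    array_preset=None,
    scheme: ArrayScheme | None = None,
    library_in: HaplotypeLibrary | None = None,
    evaluate: bool = False,
    scope: str = "heterozygous",
    snp_scope: str = "all",
    core_indices: list[int] | None = None,
) -> PipelineResult:
    """Full pipeline on in-memory objects.

    Either pass ``genotypes`` (with optional ``pedigree``) or ``sim_params``
    (with an optional ``array_preset``/``scheme``) to simulate the inputs.
    With ``evaluate=True`` (requires simulated truth) per-breed and
    per-generation statistics are computed.
    """
    params = params or PhasingParams()
    truth = None
    if sim_params is not None:
        if genotypes is not None:
            raise ParameterError("pass either genotypes or sim_params, not both")
        from .popsim import simulate_population

        truth = simulate_population(sim_params)
        if scheme is None:
            scheme = build_array_scheme(
                array_preset or {"sizes_frac": [1.0], "ratio": (1,)},
                truth.n_individuals,
                n_snps=truth.n_snps,
                rng=np.random.default_rng(sim_params.rng_seed + 1),
            )
        genotypes = mask_genotypes(truth, scheme)
        pedigree = truth.pedigree
    if genotypes is None:
        raise ParameterError("no genotypes given and no simulation requested")

    haps, cores, library = phase_dataset(
        genotypes, pedigree, params, library_in=library_in, core_indices=core_indices
    )

    stats = None
    if evaluate:
        if truth is None:
            raise ParameterError("evaluation requires simulated truth")
        overall = phasing_statistics(
            haps, truth.haplotypes, genotypes, cores, scope=scope, snp_scope=snp_scope
        )
        per_breed, breed_avg = grouped_stats(
            haps, truth.haplotypes, genotypes, cores, truth.breed,
            scope=scope, snp_scope=snp_scope,
        )
        per_gen, gen_avg = grouped_stats(
            haps, truth.haplotypes, genotypes, cores, truth.generation,
            scope=scope, snp_scope=snp_scope,
        )
        stats = {
            "overall": overall,
            "per_breed": per_breed,
            "per_breed_average": breed_avg,
            "per_generation": per_gen,
            "per_generation_average": gen_avg,
        }
    return PipelineResult(
        haplotypes=haps, cores=cores, library=library,
        genotypes=genotypes, truth=truth, stats=stats,
    )


def stats_table(stats: dict[str, PhasingStats]) -> str:
    """Tab-separated report: one row per scenario/scope entry."""
    cols = [
        "scenario", "scope", "percent_correct", "percent_unphased",
        "percent_incorrect",
    ]
    lines = ["\t".join(cols)]
    for name, st in stats.items():
        lines.append(
            f"{name}\t{st.scope}\t{st.percent_correct:.2f}"
            f"\t{st.percent_unphased:.2f}\t{st.percent_incorrect:.2f}"
        )
    return "\n".join(lines) + "\n"
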