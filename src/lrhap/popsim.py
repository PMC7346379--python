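"""Forward simulation of structured, selectively bred SNP-array populations.

The generator emulates the kind of livestock data the phasing method is
designed for: a single ancestral breed splits into three breeds 400
generations ago, each of which splits again 50 generations ago into three
or four breeds (ten in total); each breed then undergoes ten generations
of within-breed truncation selection (25 sires and 500 dams producing
1000 offspring per breed and generation).  A single 1-Morgan chromosome
is simulated; SNPs are retained at base-generation minor allele frequency
of at least 0.05; individuals are assigned to (possibly partially
overlapping) SNP arrays and their genotypes masked accordingly.  Complete
truth (haplotypes, pedigree, breed and generation labels) is retained for
evaluation.

Base haplotypes through the breed-split history come from a coalescent
simulation (msprime) with recombination and mutation; the selective
breeding stage runs forward in time with explicit meioses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, SimulationError
from .types import UNKNOWN_PARENT, GenotypeMatrix, Pedigree


@dataclass
class SimParams:
    """Simulation parameters.

    Defaults mirror the 100k-individual study design: 8771 candidate SNPs
    on a 1-Morgan chromosome, a 1 -> 3 -> 10 breed tree with splits 400 and
    50 generations ago, ten generations of truncation selection with 25
    sires, 500 dams and 1000 offspring per breed-generation, 10,000 QTN
    with standard-normal effects, and a MAF filter at 0.05.
    ``founder_pop_size`` (diploids sampled per terminal breed),
    ``ancestral_ne`` and ``mutation_rate`` (expected mutations per Morgan
    per generation along a lineage) are free parameters of the coalescent
    stand-in for the base-population simulator; heritability of the
    selected trait defaults to 0.3.
    """

    n_snps: int = 8771
    chrom_length: float = 1.0
    split_generations: tuple[int, int] = (400, 50)
    recent_split_counts: tuple[int, ...] = (3, 3, 4)
    n_generations_selection: int = 10
    n_sires: int = 25
    n_dams: int = 500
    n_offspring_per_breed_gen: int = 1000
    n_qtn: int = 10_000
    maf_min: float = 0.05
    heritability: float = 0.3
    founder_pop_size: int = 1000
    ancestral_ne: float = 1000.0
    mutation_rate: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_min < 0.5:
            raise ParameterError(f"maf_min must be in (0, 0.5), got {self.maf_min}")
        if not 0.0 <= self.heritability <= 1.0:
            raise ParameterError(f"heritability must be in [0, 1], got {self.heritability}")
        for name in (
            "n_snps", "n_generations_selection", "n_sires", "n_dams",
            "n_offspring_per_breed_gen", "n_qtn", "founder_pop_size",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.split_generations[0] <= self.split_generations[1]:
            raise ParameterError("older split must predate the recent split")

    @property
    def n_breeds(self) -> int:
        return int(sum(self.recent_split_counts))


@dataclass
class TruePopulation:
    """Complete simulation truth.

    ``haplotypes`` has shape ``(n, 2, n_snps)`` over the retained SNPs;
    ``generation`` is 0 for founders; ``phenotype``/``sex``/selection flags
    support checks on the breeding design.
    """

    ids: list[str]
    haplotypes: np.ndarray
    breed: np.ndarray
    generation: np.ndarray
    pedigree: Pedigree
    snp_positions: np.ndarray       # Morgans
    qtn_positions: np.ndarray       # Morgans
    qtn_effects: np.ndarray
    sex: np.ndarray                 # 0 male, 1 female
    phenotype: np.ndarray
    selected_sire: np.ndarray = field(default=None)
    selected_dam: np.ndarray = field(default=None)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[2]

    def genotypes(self) -> GenotypeMatrix:
        """Error-free, complete genotypes (allele sums of the true haplotypes)."""
        return GenotypeMatrix(
            ids=list(self.ids),
            codes=self.haplotypes.sum(axis=1).astype(np.int8),
        )


def meiosis(parent_haps: np.ndarray, positions: np.ndarray, rng: np.random.Generator,
            chrom_length: float = 1.0) -> np.ndarray:
    """One gamete from a diploid parent.

    Crossover count is Poisson(``chrom_length``), breakpoints are uniform
    (no interference), and the starting haplotype is chosen with
    probability 1/2.
    """
    n_x = rng.poisson(chrom_length)
    start = int(rng.integers(2))
    if n_x == 0:
        return parent_haps[start].copy()
    breaks = np.sort(rng.uniform(0.0, chrom_length, size=n_x))
    segment = np.searchsorted(breaks, positions, side="right")
    choice = (start + segment) % 2
    return np.where(choice == 0, parent_haps[0], parent_haps[1]).astype(np.int8)


def _breed_demography(params: SimParams):
    """Build the msprime demography for the breed-split tree."""
    import msprime

    ne = params.ancestral_ne
    demo = msprime.Demography()
    counts = params.recent_split_counts
    n_breeds = sum(counts)
    leaves = [f"breed{k}" for k in range(n_breeds)]
    for name in leaves:
        demo.add_population(name=name, initial_size=ne)
    if len(counts) == 1 and counts[0] == 1:
        return demo, leaves
    old_gen, recent_gen = params.split_generations
    mids = []
    k = 0
    for g, c in enumerate(counts):
        group = leaves[k : k + c]
        k += c
        if c == 1:
            mids.append(group[0])
            continue
        mid = f"mid{g}"
        demo.add_population(name=mid, initial_size=ne)
        demo.add_population_split(time=recent_gen, derived=group, ancestral=mid)
        mids.append(mid)
    if len(mids) > 1:
        demo.add_population(name="anc", initial_size=ne)
        demo.add_population_split(time=old_gen, derived=mids, ancestral="anc")
    return demo, leaves


def _founder_haplotypes(params: SimParams, seed: int):
    """Coalescent base haplotypes: (2*n_founders_total, n_sites), positions."""
    import msprime

    demo, leaves = _breed_demography(params)
    ts = msprime.sim_ancestry(
        samples={name: params.founder_pop_size for name in leaves},
        demography=demo,
        sequence_length=params.chrom_length,
        recombination_rate=1.0,
        discrete_genome=False,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=params.mutation_rate,  # per Morgan per generation
        random_seed=seed + 1,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
    )
    geno = ts.genotype_matrix().astype(np.int8)  # (sites, haplotypes), 0/1
    positions = np.asarray([s.position for s in ts.sites()])
    founder_breed = np.repeat(np.arange(len(leaves)), params.founder_pop_size)
    return np.ascontiguousarray(geno.T), positions, founder_breed


def simulate_population(params: SimParams) -> TruePopulation:
    """Simulate the full breed-structured, selected population with truth.

    Stage 1 samples base haplotypes through the breed-split tree; stage 2
    applies the base-generation MAF filter, samples ``n_snps`` SNPs and
    assigns QTN with standard-normal effects; stage 3 runs per-breed
    truncation selection with explicit meioses.
    """
    rng = np.random.default_rng(params.rng_seed)
    msprime_seed = int(rng.integers(1, 2**31 - 2))
    haps_base, positions, founder_breed = _founder_haplotypes(params, msprime_seed)

    # stage 2: MAF filter at the base generation, SNP and QTN assignment
    freq = haps_base.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    candidates = np.flatnonzero(maf >= params.maf_min)
    if candidates.size < params.n_snps:
        raise SimulationError(
            f"only {candidates.size} segregating sites pass the MAF filter but "
            f"{params.n_snps} SNPs were requested; increase founder_pop_size, "
            f"ancestral_ne or mutation_rate"
        )
    snp_sites = np.sort(rng.choice(candidates, size=params.n_snps, replace=False))
    remaining = np.setdiff1d(candidates, snp_sites)
    n_qtn = min(params.n_qtn, remaining.size)
    qtn_sites = (
        np.sort(rng.choice(remaining, size=n_qtn, replace=False)) if n_qtn else
        np.empty(0, dtype=np.int64)
    )
    qtn_effects = rng.standard_normal(n_qtn)

    # keep only the sites the forward stage needs
    keep = np.union1d(snp_sites, qtn_sites)
    site_pos = positions[keep]
    snp_cols = np.searchsorted(keep, snp_sites)
    qtn_cols = np.searchsorted(keep, qtn_sites)
    founder_haps = haps_base[:, keep]  # (2*n_founders, n_keep)
    n_founders = founder_haps.shape[0] // 2
    founder_haps = founder_haps.reshape(n_founders, 2, -1)

    # stage 3: forward truncation selection within each breed
    def genetic_value(hap_block: np.ndarray) -> np.ndarray:
        dosage = hap_block[:, 0, qtn_cols] + hap_block[:, 1, qtn_cols]
        return dosage.astype(np.float64) @ qtn_effects

    h2 = params.heritability
    ids: list[str] = []
    haps: list[np.ndarray] = []
    breed: list[int] = []
    generation: list[int] = []
    sire_idx: list[int] = []
    dam_idx: list[int] = []
    sex: list[int] = []
    phenotype: list[float] = []
    sel_sire: list[bool] = []
    sel_dam: list[bool] = []

    gv_founders = genetic_value(founder_haps)
    var_g = float(np.var(gv_founders)) or 1.0
    sd_e = np.sqrt(var_g * (1.0 - h2) / h2) if h2 > 0 else np.sqrt(var_g) * 10.0

    for k in range(n_founders):
        b = int(founder_breed[k])
        ids.append(f"B{b}G0I{k % params.founder_pop_size}")
        haps.append(founder_haps[k])
        breed.append(b)
        generation.append(0)
        sire_idx.append(UNKNOWN_PARENT)
        dam_idx.append(UNKNOWN_PARENT)
        sex.append(int(rng.integers(2)))
        phenotype.append(float(gv_founders[k] + rng.normal(0.0, sd_e)))
        sel_sire.append(False)
        sel_dam.append(False)

    n_breeds = params.n_breeds
    cohort = {b: [k for k in range(n_founders) if founder_breed[k] == b]
              for b in range(n_breeds)}
    for gen in range(1, params.n_generations_selection + 1):
        new_cohort: dict[int, list[int]] = {}
        for b in range(n_breeds):
            members = np.asarray(cohort[b])
            pheno = np.asarray([phenotype[k] for k in members])
            is_male = np.asarray([sex[k] == 0 for k in members])
            males = members[is_male]
            females = members[~is_male]
            sires = males[np.argsort(pheno[is_male])[::-1][: params.n_sires]]
            dams = females[np.argsort(pheno[~is_male])[::-1][: params.n_dams]]
            if sires.size == 0 or dams.size == 0:
                raise SimulationError(
                    f"breed {b} generation {gen}: no candidate sires or dams"
                )
            for k in sires:
                sel_sire[k] = True
            for k in dams:
                sel_dam[k] = True
            children = []
            for j in range(params.n_offspring_per_breed_gen):
                s = int(rng.choice(sires))
                d = int(rng.choice(dams))
                gamete_s = meiosis(haps[s], site_pos, rng, params.chrom_length)
                gamete_d = meiosis(haps[d], site_pos, rng, params.chrom_length)
                child = np.stack([gamete_s, gamete_d])
                idx = len(ids)
                ids.append(f"B{b}G{gen}I{j}")
                haps.append(child)
                breed.append(b)
                generation.append(gen)
                sire_idx.append(s)
                dam_idx.append(d)
                sex.append(int(rng.integers(2)))
                gv = float(
                    (child[0, qtn_cols] + child[1, qtn_cols]).astype(np.float64)
                    @ qtn_effects
                )
                phenotype.append(gv + float(rng.normal(0.0, sd_e)))
                sel_sire.append(False)
                sel_dam.append(False)
                children.append(idx)
            new_cohort[b] = children
        cohort = new_cohort

    all_haps = np.stack(haps)[:, :, snp_cols]
    pedigree = Pedigree(
        ids=list(ids),
        sire=np.asarray(sire_idx),
        dam=np.asarray(dam_idx),
    )
    return TruePopulation(
        ids=ids,
        haplotypes=all_haps.astype(np.int8),
        breed=np.asarray(breed),
        generation=np.asarray(generation),
        pedigree=pedigree,
        snp_positions=site_pos[snp_cols],
        qtn_positions=site_pos[qtn_cols],
        qtn_effects=qtn_effects,
        sex=np.asarray(sex),
        phenotype=np.asarray(phenotype),
        selected_sire=np.asarray(sel_sire),
        selected_dam=np.asarray(sel_dam),
    )


# ---------------------------------------------------------------------------
# SNP-array schemes
# ---------------------------------------------------------------------------

@dataclass
class ArrayScheme:
    """Which SNP indices each array covers and who is on which array."""

    arrays: list[np.ndarray]        # sorted SNP-index arrays; union = all SNPs
    assignment: np.ndarray          # per individual: array index
    preset: str = "custom"

    def covers(self, n_snps: int) -> bool:
        union = np.unique(np.concatenate(self.arrays))
        return union.size == n_snps and union[0] == 0 and union[-1] == n_snps - 1


#: Named genotyping scenarios: per-array SNP counts on their natural SNP
#: universe, and the individual-assignment ratio.  Counts follow the bovine
#: array sizes and unions of the evaluated scenarios (e.g. the homogeneous
#: MD array has 6711 SNPs; the MD/HD mix unions to 50,142 with a 9:1
#: assignment ratio).
PRESETS: dict[str, dict] = {
    "md": {"union": 6711, "sizes": [6711], "ratio": (1,)},
    "hd": {"union": 49_579, "sizes": [49_579], "ratio": (1,)},
    "two_illumina": {"union": 6924, "sizes": [6711, 6711], "ratio": (1, 1)},
    "two_mixed": {"union": 7245, "sizes": [6711, 6711], "ratio": (1, 1)},
    "three_md": {"union": 10_033, "sizes": [6711, 6711, 6711], "ratio": (1, 1, 1)},
    "mixed_md_hd": {"union": 50_142, "sizes": [6711, 49_579], "ratio": (9, 1)},
}


def two_array_spec(overlap_frac: float, ratio: tuple[int, int] = (1, 1)) -> dict:
    """Custom two-array scheme where each array shares ``overlap_frac`` of
    its SNPs with the other (equal array sizes)."""
    size_frac = 1.0 / (2.0 - overlap_frac)
    return {"sizes_frac": [size_frac, size_frac], "ratio": ratio}


def _sample_two_arrays(sizes: list[int], n_snps: int, rng) -> list[np.ndarray]:
    s1, s2 = sizes
    inter = s1 + s2 - n_snps
    if inter < 0:
        raise ParameterError("array sizes cannot cover the SNP set")
    perm = rng.permutation(n_snps)
    common = perm[:inter]
    a_only = perm[inter : inter + (s1 - inter)]
    b_only = perm[inter + (s1 - inter) :]
    return [np.sort(np.concatenate([common, a_only])),
            np.sort(np.concatenate([common, b_only]))]


def _sample_symmetric_arrays(sizes: list[int], n_snps: int, rng) -> list[np.ndarray]:
    k = len(sizes)
    f = sizes[0] / n_snps
    c = (k * f - 1.0) / (k - 1.0)
    if not 0.0 <= c <= 1.0:
        raise ParameterError("infeasible array sizes for a shared-core design")
    n_common = int(round(c * n_snps))
    perm = rng.permutation(n_snps)
    common = perm[:n_common]
    exclusive = np.array_split(perm[n_common:], k)
    return [np.sort(np.concatenate([common, ex])) for ex in exclusive]


def _assign_ratio(n: int, ratio, rng) -> np.ndarray:
    ratio = np.asarray(ratio, dtype=np.float64)
    weights = ratio / ratio.sum()
    counts = np.floor(weights * n).astype(np.int64)
    # largest-remainder allocation of the leftover individuals
    for k in np.argsort(weights * n - counts)[::-1][: n - counts.sum()]:
        counts[k] += 1
    labels = np.repeat(np.arange(len(ratio)), counts)
    return labels[rng.permutation(n)]


def build_array_scheme(
    preset, n_individuals: int, n_snps: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> ArrayScheme:
    """Construct a genotyping scheme from a preset name or a custom spec.

    A custom spec is a dict with ``sizes_frac`` (per-array size as a
    fraction of the SNP universe) or ``sizes`` (absolute counts) and
    ``ratio`` (individual assignment ratio).  ``n_snps`` defaults to the
    preset's natural SNP-universe size.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ParameterError(f"unknown array preset {preset!r}")
        spec = dict(PRESETS[preset])
        name = preset
        if n_snps is None:
            n_snps = spec["union"]
        sizes = [max(1, int(round(s / spec["union"] * n_snps))) for s in spec["sizes"]]
    else:
        spec = dict(preset)
        name = spec.get("name", "custom")
        if n_snps is None:
            raise ParameterError("a custom array spec requires n_snps")
        if "sizes_frac" in spec:
            sizes = [max(1, int(round(f * n_snps))) for f in spec["sizes_frac"]]
        else:
            sizes = [int(s) for s in spec["sizes"]]
    ratio = spec["ratio"]
    if len(sizes) != len(ratio):
        raise ParameterError("one ratio entry per array is required")
    if len(sizes) == 1:
        arrays = [np.arange(n_snps, dtype=np.int64)]
    elif len(sizes) == 2:
        arrays = _sample_two_arrays(sizes, n_snps, rng)
    else:
        if len(set(sizes)) != 1:
            raise ParameterError("3+ arrays are supported with equal sizes only")
        arrays = _sample_symmetric_arrays(sizes, n_snps, rng)
    assignment = _assign_ratio(n_individuals, ratio, rng)
    scheme = ArrayScheme(arrays=arrays, assignment=assignment, preset=name)
    union = np.unique(np.concatenate(arrays))
    if union.size != n_snps:
        raise ParameterError("sampled arrays do not cover the SNP set")
    return scheme


def mask_genotypes(pop: TruePopulation, scheme: ArrayScheme) -> GenotypeMatrix:
    """Observed genotypes under a scheme: allele sums on the individual's
    array, missing elsewhere."""
    from .types import MISSING

    full = pop.haplotypes.sum(axis=1).astype(np.int8)
    codes = np.full(full.shape, MISSING, dtype=np.int8)
    for k, snps in enumerate(scheme.arrays):
        rows = np.flatnonzero(scheme.assignment == k)
        codes[np.ix_(rows, snps)] = full[np.ix_(rows, snps)]
    return GenotypeMatrix(ids=list(pop.ids), codes=codes)
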