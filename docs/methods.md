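# Methods

## The phasing problem and the heuristic

Given unphased SNP genotypes (codes 0/1/2, 9 for missing) for a set of
related individuals, the package infers each individual's two haplotypes.
The method is heuristic, built from two classical livestock-genetics
ideas:

**Long-range phasing (LRP).** The chromosome is tiled into *cores* —
blocks of consecutive SNPs phased independently.  Within a core, two
individuals that carry a haplotype in common can never show *opposing
homozygotes* (one genotype 0 where the other is 2), so candidate
haplotype sharers ("surrogate parents") are found by scanning all pairs
for (near-)absence of opposing homozygotes.  Because different SNP
arrays observe different markers, a pair is only tested for surrogacy
when at least `min_shared_markers` markers are observed in both
individuals, and the disagreement allowance is a fraction
(`surrogate_disagree_frac`) of the markers actually shared, not of the
core length.  Surrogates are split into a paternal and a maternal side —
by pedigree when parents are known (a surrogate of the sire that is not
also linked to the dam is paternal, and symmetrically; ambiguous
surrogates are left out), otherwise by clustering around the surrogate
with the most shared markers (anchor).  At every heterozygous or missing
SNP of the focal individual, each side's surrogates vote: a homozygous
surrogate votes its allele; a heterozygous or missing surrogate is a
conduit to *its* surrogates, searched breadth-first, one level deeper
only when the current level produced no vote at all (remote chains can
attach to either haplotype of an intermediate, so their votes are noisier
and serve as a fallback).  At most `max_surrogates` chains vote, to depth
`max_surrogate_depth`; the allele is set when the plurality share reaches
`consensus_agreement_frac` (ties stay unphased).  The opposite gamete is
completed from the genotype.

**Haplotype library imputation (HLI).**  Per core, phased (possibly
partial) haplotypes are collected in a library.  A haplotype joins the
library only when at least `min_phased_frac_library` of its carrier's
*genotyped* core SNPs are phased — the denominator deliberately excludes
SNPs the carrier's array does not cover, since a medium-density-genotyped
individual can never phase high-density-only SNPs by LRP.  Two haplotypes
are identified as *the same* when they are co-observed at
`min_match_alleles` or more positions with at most
`library_cluster_mismatches` disagreements.  Matching entries fill a
gamete's missing alleles where they unanimously agree (and the fill is
consistent with the genotype and the opposite gamete); newly extended
haplotypes are fed back: no match inserts, mutually compatible matches
merge with the candidate into one entry observed on the union of
positions (carriers united, counts summed), matches that conflict with
one another are left alone and the candidate is inserted beside them.  A
maintenance step merges any two entries that the identity rule links —
this is how a new haplotype can transitively reveal that several
non-overlapping partial entries were one haplotype all along.  Passes
repeat until a pass phases no allele and leaves the library unchanged;
the phased-allele count is non-decreasing, so the loop terminates.

**Sub-setting.**  Surrogate search is all-against-all, hence quadratic in
the number of individuals.  For large datasets the individuals are
partitioned at random into subsets of `subset_size`; LRP runs inside each
subset and the merged result feeds a single HLI stage over everyone.
Subsets are disjoint and cover the dataset; a terminal remainder smaller
than half a subset is folded into the previous subset.  Membership is
randomized by `rng_seed`, but within a subset individuals are processed
in input order, which makes the output invariant to subset processing
order and makes `subset_size >= n` reproduce the unsubsetted run
bit-for-bit.  Cores can also be phased in separate processes and
concatenated; with a fixed seed the concatenation is byte-identical to a
single run.

## Parameters

| name | default | meaning |
|---|---|---|
| `core_length` | 500 SNPs | core size; accuracy degrades when a core spans too much genetic map (recommendation: ~10% of a 1-Morgan chromosome) |
| `subset_size` | 5000 | individuals per LRP subset; larger = more surrogates = more accurate, at quadratic cost |
| `max_surrogates` | 10 | chains voting per allele |
| `surrogate_disagree_frac` | 0.10 | opposing-homozygote tolerance between surrogates, as a fraction of shared markers; absorbs genotyping error |
| `min_shared_markers` | 100 | shared observed markers before surrogacy is tested |
| `min_phased_frac_library` | 0.80 | phased fraction (of the carrier's genotyped core SNPs) required to enter the library |
| `min_match_alleles` | 200 | co-observed agreeing alleles required to call two haplotypes identical |
| `library_cluster_mismatches` | 0 | mismatches tolerated when clustering near-identical library haplotypes |
| `max_surrogate_depth` | 10 | maximum chain depth |
| `consensus_agreement_frac` | 0.9 | plurality share needed to set an allele; ties go unphased |

`min_match_alleles` is an *absolute* count on purpose: the probability of
a spurious identity depends on the number of co-observed alleles, not on
their fraction of the core, so the same value serves medium- and
high-density arrays.

## The synthetic-data generator

`lrhap.popsim` emulates the kind of data the method targets: a single
ancestral cattle-like population splits into three breeds 400 generations
ago and into ten breeds (3/3/4) 50 generations ago; each breed then
undergoes ten generations of truncation selection (25 sires and 500 dams
per generation, 1000 offspring per breed-generation at the 100k scale) on
a phenotype with 10,000 QTN of standard-normal effect and heritability
0.3 (a value the generator must fix; the study design leaves it open).
One 1-Morgan chromosome is simulated; SNPs are sampled from segregating
sites with base-generation minor allele frequency >= 0.05; genotypes are
error-free.  Individuals can be assigned to overlapping SNP arrays
(presets mirror the bovine-array scenarios: one MD array of 6711 SNPs,
one HD array of 49,579, two-array and three-array mixes with 1:1 / 1:1:1
ratios, and a 9:1 MD/HD mix over a 50,142-SNP union) and their genotypes
masked to their array.

Base haplotypes are drawn from a coalescent simulation (msprime) with
recombination and mutation through the breed-split demography — the
natural choice for a neutral multi-population history and exact for it;
the selective-breeding stage then runs forward in time with explicit
meioses (Poisson crossovers, no interference, uniform breakpoints).
`founder_pop_size`, `ancestral_ne` and `mutation_rate` (per Morgan per
generation) are free parameters of that stand-in; defaults are sized so
the MAF filter leaves enough SNPs at desk scale.  Mating is random
sire x dam with replacement; sex is assigned at random.

What the generator does *not* emulate: genotyping error (genotypes are
exact allele sums), multi-chromosome genomes, crossover interference,
non-random mating, and the exact bovine-array SNP overlap structure
(overlaps are parameterized instead).  Passing tests therefore show the
algorithmic machinery is correct and that the method's qualitative
behaviour (subset-size response, heterogeneous-array penalty) reproduces;
they do not certify accuracy on real, error-containing data.

## Evaluation

Three statistics are computed against simulation truth at either all loci
or heterozygous loci (the informative ones): percent correctly phased,
percent unphased, percent incorrectly phased; they sum to 100.  Cores are
phased independently, so the inferred pair is aligned to the true pair
per core, scoring both assignments and keeping the better one — a global
within-core gamete swap is free, switches *within* a core are penalized.
Aggregation over breeds or over generations is an unweighted mean of the
group percentages.  Scoring covers all SNPs by default (heterogeneous
scenarios impute phase at off-array SNPs); `snp_scope="genotyped"`
restricts to each individual's own array.

## Desk-scale experiment design

The study-scale datasets (100k-1M individuals, 6711-49,579 SNPs) are not
desk-sized, so the packaged experiments scale down while keeping the
quantities that govern the heuristic's behaviour:

* the chromosome stays 1 Morgan and cores stay ~10-15% of it
  (founder-recovery: 500 SNPs, 50-SNP cores; trend experiments: 1050
  SNPs, 150-SNP cores);
* `min_match_alleles` stays as large as the partial-haplotype overlap
  structure permits (100 of a 150-SNP core; 60 when two arrays share only
  60% of their SNPs), because identity confidence rides on the absolute
  count;
* `surrogate_disagree_frac` is 0 in the experiments: the simulated
  genotypes carry no error, and on short cores a 10% allowance would
  admit false surrogates outright.  The package default remains 0.10,
  the published operating point for error-containing data;
* the founder-recovery scenario (500 individuals bred from 8 founder
  haplotypes, complete genotypes, known pedigree) is the regression
  anchor: reference runs phase 97-98% of heterozygous alleles correctly
  with ~0.7-0.8% incorrect, and the acceptance test locks in >= 94%
  correct and <= 1.5% incorrect;
* the trend experiments use a fixed 4000-individual two-breed population;
  subset sizes 250/1000/4000 show monotone accuracy gains, and masking
  the same truth onto two 60%-overlapping arrays raises the incorrect
  rate relative to the single-array run.

## Numerical and design choices

* Genotypes and haplotypes are stored as disjoint bit planes in 64-bit
  words (32-bit supported and tested for width-independence); opposing /
  shared / match counts are AND + popcount reductions.
* Missing is −1 internally, 9 on disk; coordinates are 0-based half-open.
* Conflicts between a haplotype and a homozygous genotype are reported
  and blanked by default (tolerance to upstream error), or raised on
  request.
* Votes tie toward missing; a fill never contradicts the genotype or
  claims the opposite gamete's allele at a heterozygous SNP.
* When a submitted haplotype adds nothing beyond its single matching
  entry, the carrier is attached without rewriting the entry (the merge
  would be an identity); library maintenance re-checks only entries added
  since the no-duplicates invariant last held.  Both are pure
  optimizations: entry rows are immutable once written.
* The library file format is versioned (`#lrhap-library v1`) and stores
  core boundaries in header lines so loading is an exact inverse; carrier
  sets are deliberately not persisted.
* Sides are re-derived per core; with a pedigree, parents outside the
  subset simply do not inform sides (anchor clustering is the fallback
  when neither parent is present).
* Individuals with no surrogates receive genotype-forced phase only.
* "Core tails" (surrogate testing extended beyond core boundaries, found
  in some older LRP implementations) are not implemented; surrogacy here
  is strictly within-core.

## Known limitations

* The heuristic's absolute accuracy at desk scale is below the
  full-study figures simply because small populations offer few
  surrogates; the per-population ~94%-correct regime reappears once
  subsets reach the low thousands.
* No probabilistic model: no phase likelihoods, no switch-error
  estimates, no recombination-point output.
* X-chromosome/haploid data, dosage input and genotype-error
  re-estimation are out of scope.
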