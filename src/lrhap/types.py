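"""Core domain types: genotype matrix, pedigree, cores and phasing parameters.

Conventions used throughout the package:

* genotype codes are ``0`` (homozygous reference), ``1`` (heterozygous),
  ``2`` (homozygous alternate); missing is the sentinel :data:`MISSING`
  (``-1``) internally and ``9`` on disk;
* haplotype alleles are ``0``/``1`` with the same :data:`MISSING` sentinel
  for unphased positions;
* SNP coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .exceptions import ParameterError, ValidationError

#: Internal sentinel for a missing genotype code or an unphased allele.
MISSING: int = -1

#: On-disk code for missing genotypes / unphased alleles.
DISK_MISSING: int = 9

#: Pedigree sentinel for an unknown parent.
UNKNOWN_PARENT: int = -1


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of genotype codes.

    Parameters
    ----------
    ids
        Ordered, unique individual identifiers (one per row).
    codes
        ``(n_individuals, n_snps)`` int8 array with values in
        ``{0, 1, 2, MISSING}``.
    """

    ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValidationError("genotype codes must be a 2-D array")
        if len(self.ids) != self.codes.shape[0]:
            raise ValidationError(
                f"{len(self.ids)} identifiers for {self.codes.shape[0]} genotype rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("individual identifiers must be unique")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid genotype code {self.codes[i, j]} for individual "
                f"{self.ids[i]!r} at SNP {j}"
            )

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def row(self, identifier: str) -> np.ndarray:
        return self.codes[self.ids.index(identifier)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return self.ids == other.ids and np.array_equal(self.codes, other.codes)


@dataclass
class Pedigree:
    """Sire/dam links by row index into an individual list.

    ``sire[i]``/``dam[i]`` are indices into ``ids`` or
    :data:`UNKNOWN_PARENT`.  Parents that appear only in the parent columns
    (not genotyped themselves) are appended to ``ids`` and flagged in
    ``external_founder``.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    external_founder: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if self.external_founder is None:
            self.external_founder = np.zeros(n, dtype=bool)
        self.external_founder = np.asarray(self.external_founder, dtype=bool)
        if not (len(self.sire) == len(self.dam) == n == len(self.external_founder)):
            raise ValidationError("pedigree arrays must have one entry per individual")
        for name, arr in (("sire", self.sire), ("dam", self.dam)):
            out = (arr != UNKNOWN_PARENT) & ((arr < 0) | (arr >= n))
            if out.any():
                raise ValidationError(f"{name} index out of range")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        n = len(self.ids)
        state = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 on stack, 2 done
        for start in range(n):
            if state[start]:
                continue
            stack = [(start, 0)]
            while stack:
                node, pi = stack[-1]
                if pi == 0:
                    state[node] = 1
                parents = (self.sire[node], self.dam[node])
                if pi < 2:
                    stack[-1] = (node, pi + 1)
                    p = parents[pi]
                    if p == UNKNOWN_PARENT:
                        continue
                    if state[p] == 1:
                        raise ValidationError(
                            f"pedigree cycle: {self.ids[node]!r} descends from itself"
                        )
                    if state[p] == 0:
                        stack.append((p, 0))
                else:
                    state[node] = 2
                    stack.pop()

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def index_of(self, identifier: str) -> int:
        return self.ids.index(identifier)


@dataclass(frozen=True)
class Core:
    """A contiguous, half-open block of SNPs phased as a unit."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(f"invalid core [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def slice(self) -> slice:
        return slice(self.start, self.end)


@dataclass
class PhasingParams:
    """Tunable parameters of the phasing pipeline.

    Defaults follow the published operating point of the heuristic:
    at most 10 surrogates vote per position, 10% of shared markers may
    disagree between surrogates, library haplotypes need 80% of the
    carrier's genotyped core SNPs phased, haplotype identity requires 200
    matching alleles, and near-identical library haplotypes are clustered
    at zero mismatches.
    """

    core_length: int = 500
    subset_size: int = 5000
    max_surrogates: int = 10
    surrogate_disagree_frac: float = 0.10
    min_shared_markers: int = 100
    min_phased_frac_library: float = 0.80
    min_match_alleles: int = 200
    library_cluster_mismatches: int = 0
    max_surrogate_depth: int = 10
    consensus_agreement_frac: float = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.endswith("_frac"):
                if not 0.0 <= v <= 1.0:
                    raise ParameterError(f"{f.name} must be in [0, 1], got {v}")
            elif f.name in ("rng_seed", "library_cluster_mismatches"):
                if v < 0:
                    raise ParameterError(f"{f.name} must be non-negative, got {v}")
            else:
                if v <= 0:
                    raise ParameterError(f"{f.name} must be positive, got {v}")
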