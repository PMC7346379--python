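"""Haplotype-level primitives: genotype complement and the haplotype library.

The haplotype library is per-core: each entry is a possibly *partial*
allele sequence over the core (missing alleles arise when all of the
entry's carriers were genotyped on arrays that skip those SNPs), together
with the set of carrier gametes and a frequency count.  Partial entries are
what make phasing across multiple SNP arrays possible: entries observed on
complementary SNP subsets that agree wherever both are observed can be
merged into a single, more complete haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import PhaseConflictError, ValidationError
from .types import MISSING


def complement_from_genotype(
    genotype: np.ndarray, hap: np.ndarray, policy: str = "blank"
) -> np.ndarray:
    """Derive the second haplotype of an individual from one haplotype and
    the genotype.

    At a homozygous SNP the complement is forced by the genotype alone; at a
    heterozygous SNP it is the opposite allele of ``hap``; where the genotype
    is missing (or heterozygous with ``hap`` unphased) it stays missing.

    A homozygous genotype that contradicts ``hap`` (e.g. genotype 0 with
    allele 1) is a conflict.  ``policy="blank"`` (default) sets the
    conflicting positions to missing in the output, tolerating isolated
    genotyping errors; ``policy="raise"`` raises
    :class:`~lrhap.exceptions.PhaseConflictError` listing the positions.
    """
    g = np.asarray(genotype, dtype=np.int8)
    h = np.asarray(hap, dtype=np.int8)
    if g.shape != h.shape:
        raise ValidationError("genotype and haplotype slices differ in length")
    out = np.full(g.shape, MISSING, dtype=np.int8)
    out[g == 0] = 0
    out[g == 2] = 1
    het_known = (g == 1) & (h != MISSING)
    out[het_known] = 1 - h[het_known]
    conflict = ((g == 0) & (h == 1)) | ((g == 2) & (h == 0))
    if conflict.any():
        if policy == "raise":
            raise PhaseConflictError(np.flatnonzero(conflict))
        out[conflict] = MISSING
    return out


@dataclass
class LibraryEntry:
    """One (possibly partial) haplotype in a per-core library."""

    alleles: np.ndarray  # int8 over the core, {0, 1, MISSING}
    count: int = 0
    carriers: set = field(default_factory=set)  # {(individual_index, gamete_slot)}

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)

    @property
    def observed(self) -> np.ndarray:
        return self.alleles != MISSING


class CoreLibrary:
    """Haplotype library for a single core.

    Entries are held in a dense int8 matrix for fast matching; rows are
    never reordered, only appended or tombstoned (merged-away entries are
    marked dead so that entry identifiers stay stable within a maintenance
    round).
    """

    def __init__(self, core_length: int):
        self.core_length = int(core_length)
        self._buf = np.empty((16, self.core_length), dtype=np.int8)
        self._n = 0
        self.counts: list[int] = []
        self.carriers: list[set] = []
        self._alive: list[bool] = []
        self.mutations = 0  # bumped on any structural change (add/kill/detach)
        # carrier gamete -> entry id, for detach-on-update bookkeeping
        self._carrier_entry: dict[tuple[int, int], int] = {}

    @property
    def _alleles(self) -> np.ndarray:
        """Dense (n_total, core_length) allele matrix (dead rows included)."""
        return self._buf[: self._n]

    # -- basic accessors -------------------------------------------------
    @property
    def n_entries(self) -> int:
        return sum(self._alive)

    def entry_ids(self) -> list[int]:
        return [e for e, alive in enumerate(self._alive) if alive]

    def alleles(self, entry_id: int) -> np.ndarray:
        return self._buf[entry_id]

    def is_alive(self, entry_id: int) -> bool:
        return self._alive[entry_id]

    def alleles_matrix(self) -> np.ndarray:
        """Dense (n_entries, core_length) view of the live entries."""
        return self._alleles[np.asarray(self._alive, dtype=bool)]

    # -- mutation --------------------------------------------------------
    def add(self, alleles: np.ndarray, count: int = 1, carriers=()) -> int:
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.shape != (self.core_length,):
            raise ValidationError("entry length does not match the core")
        if self._n == self._buf.shape[0]:
            grown = np.empty((2 * self._buf.shape[0], self.core_length), dtype=np.int8)
            grown[: self._n] = self._buf
            self._buf = grown
        self._buf[self._n] = alleles
        self._n += 1
        self.counts.append(int(count))
        carriers = set(carriers)
        self.carriers.append(carriers)
        self._alive.append(True)
        self.mutations += 1
        eid = len(self.counts) - 1
        for c in carriers:
            self._carrier_entry[c] = eid
        return eid

    def kill(self, entry_id: int) -> None:
        self._alive[entry_id] = False
        self.mutations += 1
        for c in self.carriers[entry_id]:
            self._carrier_entry.pop(c, None)

    def detach_carrier(self, carrier: tuple[int, int]) -> None:
        """Remove a carrier gamete from its current entry, if any."""
        eid = self._carrier_entry.pop(carrier, None)
        if eid is None:
            return
        self.carriers[eid].discard(carrier)
        self.counts[eid] = max(0, self.counts[eid] - 1)
        self.mutations += 1
        if self.counts[eid] == 0 and not self.carriers[eid]:
            self._alive[eid] = False

    def entries(self) -> list[LibraryEntry]:
        return [
            LibraryEntry(self._alleles[e].copy(), self.counts[e], set(self.carriers[e]))
            for e in self.entry_ids()
        ]


class HaplotypeLibrary:
    """Per-core haplotype library for a whole chromosome."""

    def __init__(self, cores):
        from .types import Core  # local to avoid import cycle in docs builds

        self.cores: list[Core] = list(cores)
        self.per_core: list[CoreLibrary] = [CoreLibrary(len(c)) for c in self.cores]

    def __getitem__(self, core_index: int) -> CoreLibrary:
        return self.per_core[core_index]

    def __len__(self) -> int:
        return len(self.per_core)
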