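"""Bit-plane encoding of genotypes and haplotypes.

Genotype rows are stored as three disjoint bit planes over SNP index
(homozygous reference, homozygous alternate, missing; heterozygous is
implied by no plane being set), packed into fixed-width unsigned words.
Pairwise statistics such as opposing-homozygote and shared-marker counts
then reduce to bitwise AND/OR plus population counts over whole words,
which is what makes all-against-all surrogate searches affordable.

The word width is an internal constant (:data:`DEFAULT_BLOCK_BITS`) and
must not affect any result; 32-bit blocks are supported for testing that
claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .types import MISSING, Core, GenotypeMatrix

DEFAULT_BLOCK_BITS: int = 64

_WORD_DTYPE = {32: np.uint32, 64: np.uint64}


def _pack_bits(bits: np.ndarray, block_bits: int) -> np.ndarray:
    """Pack a boolean array (..., n) into (..., n_words) little-endian words."""
    bits = np.asarray(bits, dtype=bool)
    n = bits.shape[-1]
    n_words = -(-n // block_bits) if n else 1
    pad = n_words * block_bits - n
    if pad:
        bits = np.concatenate(
            [bits, np.zeros(bits.shape[:-1] + (pad,), dtype=bool)], axis=-1
        )
    packed = np.packbits(bits, axis=-1, bitorder="little")
    return packed.view(_WORD_DTYPE[block_bits])


def _unpack_bits(words: np.ndarray, n: int, block_bits: int) -> np.ndarray:
    bits = np.unpackbits(words.view(np.uint8), axis=-1, bitorder="little")
    return bits[..., :n].astype(bool)


def popcount(words: np.ndarray) -> np.ndarray:
    """Population count per word (vectorised)."""
    return np.bitwise_count(words)


@dataclass
class PackedGenotypes:
    """Bit-plane representation of a :class:`~lrhap.types.GenotypeMatrix`.

    The three planes are pairwise disjoint; ``unpack(pack(G)) == G``.
    """

    ids: list[str]
    hom_ref: np.ndarray  # (n_individuals, n_words)
    hom_alt: np.ndarray
    missing: np.ndarray
    n_snps: int
    block_bits: int = DEFAULT_BLOCK_BITS

    @property
    def n_individuals(self) -> int:
        return self.hom_ref.shape[0]

    @property
    def n_words(self) -> int:
        return self.hom_ref.shape[1]


def pack(matrix: GenotypeMatrix, block_bits: int = DEFAULT_BLOCK_BITS) -> PackedGenotypes:
    """Encode a genotype matrix as three disjoint bit planes per individual."""
    if block_bits not in _WORD_DTYPE:
        raise ValidationError(f"unsupported block width {block_bits}")
    codes = matrix.codes
    return PackedGenotypes(
        ids=list(matrix.ids),
        hom_ref=_pack_bits(codes == 0, block_bits),
        hom_alt=_pack_bits(codes == 2, block_bits),
        missing=_pack_bits(codes == MISSING, block_bits),
        n_snps=matrix.n_snps,
        block_bits=block_bits,
    )


def unpack(packed: PackedGenotypes) -> GenotypeMatrix:
    """Inverse of :func:`pack`."""
    n, b = packed.n_snps, packed.block_bits
    hr = _unpack_bits(packed.hom_ref, n, b)
    ha = _unpack_bits(packed.hom_alt, n, b)
    mi = _unpack_bits(packed.missing, n, b)
    codes = np.ones(hr.shape, dtype=np.int8)  # heterozygous unless a plane is set
    codes[hr] = 0
    codes[ha] = 2
    codes[mi] = MISSING
    return GenotypeMatrix(ids=list(packed.ids), codes=codes)


def core_word_mask(n_snps: int, core: Core, block_bits: int = DEFAULT_BLOCK_BITS) -> np.ndarray:
    """Word mask selecting the bits of ``core`` within an ``n_snps`` row."""
    bits = np.zeros(n_snps, dtype=bool)
    bits[core.start : core.end] = True
    return _pack_bits(bits, block_bits)


def opposing_and_shared(
    packed: PackedGenotypes, i: int, j: int, core: Core
) -> tuple[int, int]:
    """Opposing-homozygote and shared-marker counts for one pair over a core.

    ``n_opposing`` counts core SNPs where one individual is homozygous
    reference and the other homozygous alternate; ``n_shared`` counts core
    SNPs where both genotypes are observed.
    """
    mask = core_word_mask(packed.n_snps, core, packed.block_bits)
    opp = (packed.hom_ref[i] & packed.hom_alt[j]) | (packed.hom_alt[i] & packed.hom_ref[j])
    shared = ~(packed.missing[i] | packed.missing[j]) & mask
    return int(popcount(opp & mask).sum()), int(popcount(shared).sum())


def pairwise_opposing_shared(
    codes: np.ndarray, block_bits: int = DEFAULT_BLOCK_BITS, chunk: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs opposing/shared counts for a core-sliced code matrix.

    Parameters
    ----------
    codes
        ``(m, core_length)`` int8 genotype codes (already sliced to the core).

    Returns
    -------
    (n_opposing, n_shared)
        Two symmetric ``(m, m)`` int32 matrices.
    """
    codes = np.asarray(codes, dtype=np.int8)
    m = codes.shape[0]
    hr = _pack_bits(codes == 0, block_bits)
    ha = _pack_bits(codes == 2, block_bits)
    nm = _pack_bits(codes != MISSING, block_bits)
    n_opp = np.empty((m, m), dtype=np.int32)
    n_shr = np.empty((m, m), dtype=np.int32)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        opp = (hr[lo:hi, None, :] & ha[None, :, :]) | (ha[lo:hi, None, :] & hr[None, :, :])
        n_opp[lo:hi] = popcount(opp).sum(axis=-1, dtype=np.int32)
        n_shr[lo:hi] = popcount(nm[lo:hi, None, :] & nm[None, :, :]).sum(
            axis=-1, dtype=np.int32
        )
    return n_opp, n_shr


def pack_haplotypes(
    haps: np.ndarray, block_bits: int = DEFAULT_BLOCK_BITS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pack allele rows in {0, 1, MISSING} into (is_zero, is_one, observed) planes.

    Used by the haplotype-library matcher: with planes of two haplotypes,
    co-observed count = popcount(obs_a & obs_b) and mismatches =
    popcount((is0_a & is1_b) | (is1_a & is0_b)).
    """
    haps = np.atleast_2d(np.asarray(haps, dtype=np.int8))
    is0 = _pack_bits(haps == 0, block_bits)
    is1 = _pack_bits(haps == 1, block_bits)
    obs = _pack_bits(haps != MISSING, block_bits)
    return is0, is1, obs
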