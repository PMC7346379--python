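"""Numba kernels for the hot inner loops of long-range phasing."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lrp_vote_kernel(
    codes,            # (m, L) int8, core-sliced genotype codes, -1 = missing
    indptr,           # (m+1,) int64 CSR row pointers of the surrogate graph
    indices,          # int64 CSR column indices (ascending within a row)
    edge_sides,       # int8 aligned with indices: 1 paternal, 2 maternal, 0 unknown
    max_surrogates,   # int
    max_depth,        # int
    cons_frac,        # float
    out,              # (m, 2, L) int8, prefilled -1; filled with voted alleles
):
    """Consensus voting over surrogate chains.

    For each individual, side and votable SNP (heterozygous or missing
    genotype), chains i - s1 - ... - sd are walked breadth-first: the first
    link fixes the side, intermediates must be non-homozygous at the SNP,
    and the first homozygous individual terminates a chain and votes its
    allele.  Deeper chains are explored only when the current depth yields
    no vote at all (remote surrogates attach to either of an intermediate's
    haplotypes, so their votes are noisier and are used as a fallback
    only).  At most ``max_surrogates`` chains vote (ties within a depth
    resolved by ascending index).  The allele is set when the plurality
    share reaches ``cons_frac``; ties stay missing.
    """
    m, L = codes.shape
    visited = np.full(m, -1, dtype=np.int64)
    frontier = np.empty(m, dtype=np.int64)
    nxt = np.empty(m, dtype=np.int64)
    base = np.empty(m, dtype=np.int64)
    stamp = 0
    for i in range(m):
        for side in range(1, 3):
            nb = 0
            for p in range(indptr[i], indptr[i + 1]):
                if edge_sides[p] == side:
                    base[nb] = indices[p]
                    nb += 1
            if nb == 0:
                continue
            for j in range(L):
                c = codes[i, j]
                if c != 1 and c != -1:
                    continue  # homozygous: forced by genotype, no vote needed
                stamp += 1
                visited[i] = stamp
                nf = 0
                for k in range(nb):
                    frontier[nf] = base[k]
                    visited[base[k]] = stamp
                    nf += 1
                v0 = 0
                v1 = 0
                used = 0
                depth = 1
                while nf > 0 and used == 0 and depth <= max_depth:
                    nn = 0
                    stop = False
                    for k in range(nf):
                        s = frontier[k]
                        cs = codes[s, j]
                        if cs == 0:
                            v0 += 1
                            used += 1
                        elif cs == 2:
                            v1 += 1
                            used += 1
                        else:
                            nxt[nn] = s  # het/missing: may extend the chain
                            nn += 1
                        if used >= max_surrogates:
                            stop = True
                            break
                    if stop or used > 0:
                        break
                    # expand the non-homozygous frontier one level
                    nf2 = 0
                    for k in range(nn):
                        s = nxt[k]
                        for p in range(indptr[s], indptr[s + 1]):
                            t = indices[p]
                            if visited[t] != stamp:
                                visited[t] = stamp
                                frontier[nf2] = t
                                nf2 += 1
                    nf = nf2
                    depth += 1
                tot = v0 + v1
                if tot >= 1:
                    if v0 > v1 and v0 >= cons_frac * tot:
                        out[i, side - 1, j] = 0
                    elif v1 > v0 and v1 >= cons_frac * tot:
                        out[i, side - 1, j] = 1


@njit(cache=True, inline="always")
def _popcount64(x):
    x = x - ((x >> 1) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + ((x >> 2) & np.uint64(0x3333333333333333))
    x = (x + (x >> 4)) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (x * np.uint64(0x0101010101010101)) >> 56


@njit(cache=True)
def match_one_kernel(h0, h1, ho, e0, e1, eo, alive, min_match, max_mm, out):
    """Match one packed haplotype against all library entry planes.

    out[e] = entry e is live, co-observed >= min_match and mismatches <= max_mm.
    """
    n_entries, n_words = e0.shape
    for e in range(n_entries):
        if not alive[e]:
            out[e] = False
            continue
        co = 0
        mm = 0
        for k in range(n_words):
            co += _popcount64(eo[e, k] & ho[k])
            mm += _popcount64((e0[e, k] & h1[k]) | (e1[e, k] & h0[k]))
        out[e] = (co >= min_match) and (mm <= max_mm)


@njit(cache=True)
def pack_row_kernel(h, out0, out1, outo):
    """Pack one int8 allele row ({0,1,-1}) into 64-bit planes."""
    out0[:] = np.uint64(0)
    out1[:] = np.uint64(0)
    outo[:] = np.uint64(0)
    for j in range(h.shape[0]):
        w = j // 64
        bit = np.uint64(1) << np.uint64(j % 64)
        if h[j] == 0:
            out0[w] |= bit
            outo[w] |= bit
        elif h[j] == 1:
            out1[w] |= bit
            outo[w] |= bit


@njit(cache=True)
def pair_counts_kernel(codes, i, j, out):
    """Per-SNP loop oracle for opposing/shared counts (kept for reference use)."""
    n_opp = 0
    n_shr = 0
    for k in range(codes.shape[1]):
        a = codes[i, k]
        b = codes[j, k]
        if a != -1 and b != -1:
            n_shr += 1
            if (a == 0 and b == 2) or (a == 2 and b == 0):
                n_opp += 1
    out[0] = n_opp
    out[1] = n_shr
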