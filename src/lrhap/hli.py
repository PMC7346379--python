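"""Haplotype library imputation (HLI) with partial haplotypes.

After long-range phasing, each gamete's partially phased haplotype is
matched against a per-core library of known haplotypes.  Two haplotypes
are identified as the same when they are observed together at enough
positions (``min_match_alleles``) and disagree at no more than
``library_cluster_mismatches`` of them.  Matching entries fill the
gamete's missing alleles by unanimous consensus, the genotype complements
the other gamete, and the extended haplotype is fed back into the library
— merging entries that the new evidence reveals to be the same haplotype,
even when no two of them overlap each other directly.  The process
iterates to a fixed point.
"""

from __future__ import annotations

import numpy as np

from ._kernels import match_one_kernel, pack_row_kernel
from .bits import pack_haplotypes, popcount
from .exceptions import ValidationError
from .haplotypes import CoreLibrary, HaplotypeLibrary, complement_from_genotype
from .types import MISSING, Core, PhasingParams


class _PackedLibrary:
    """Bit-plane cache over a CoreLibrary, refreshed when the library mutates."""

    def __init__(self, lib: CoreLibrary):
        self.lib = lib
        self._alive_at = -1
        self._alive = np.zeros(0, dtype=bool)
        self._refresh()

    def alive(self) -> np.ndarray:
        if self._alive_at != self.lib.mutations:
            self._alive = np.asarray(self.lib._alive, dtype=bool)
            self._alive_at = self.lib.mutations
        return self._alive

    def _refresh(self) -> None:
        i0, i1, ob = pack_haplotypes(
            self.lib._alleles if len(self.lib.counts) else
            np.empty((0, self.lib.core_length), dtype=np.int8)
        )
        cap = max(16, 2 * i0.shape[0])
        self._b0 = np.zeros((cap, i0.shape[1]), dtype=i0.dtype)
        self._b1 = np.zeros_like(self._b0)
        self._bo = np.zeros_like(self._b0)
        self._b0[: i0.shape[0]] = i0
        self._b1[: i1.shape[0]] = i1
        self._bo[: ob.shape[0]] = ob
        self._n_packed = len(self.lib.counts)

    def planes(self):
        n = len(self.lib.counts)
        if self._n_packed < n:
            # allele rows are immutable once added, so pack only the new ones
            new0, new1, newo = pack_haplotypes(self.lib._alleles[self._n_packed : n])
            if n > self._b0.shape[0]:
                for name in ("_b0", "_b1", "_bo"):
                    old = getattr(self, name)
                    grown = np.zeros((max(2 * old.shape[0], n), old.shape[1]), old.dtype)
                    grown[: self._n_packed] = old[: self._n_packed]
                    setattr(self, name, grown)
            self._b0[self._n_packed : n] = new0
            self._b1[self._n_packed : n] = new1
            self._bo[self._n_packed : n] = newo
            self._n_packed = n
        elif self._n_packed != n:
            self._refresh()
        return self._b0[:n], self._b1[:n], self._bo[:n]


def match_haplotype(
    h: np.ndarray, lib: CoreLibrary, params: PhasingParams,
    packed: _PackedLibrary | None = None,
) -> list[int]:
    """Identifiers of library entries identified as the same haplotype as ``h``.

    An entry matches iff the number of positions where both are observed is
    at least ``min_match_alleles`` and they disagree at no more than
    ``library_cluster_mismatches`` of those positions.
    """
    if not lib.counts:
        return []
    if packed is None:
        packed = _PackedLibrary(lib)
    e0, e1, eo = packed.planes()
    if e0.dtype == np.uint64:
        h = np.ascontiguousarray(h, dtype=np.int8)
        n_words = e0.shape[1]
        h0 = np.empty(n_words, dtype=np.uint64)
        h1 = np.empty(n_words, dtype=np.uint64)
        ho = np.empty(n_words, dtype=np.uint64)
        pack_row_kernel(h, h0, h1, ho)
        out = np.empty(e0.shape[0], dtype=np.bool_)
        match_one_kernel(
            h0, h1, ho, e0, e1, eo, packed.alive(),
            params.min_match_alleles, params.library_cluster_mismatches, out,
        )
        return [int(e) for e in np.flatnonzero(out)]
    h0, h1, ho = pack_haplotypes(np.asarray(h, dtype=np.int8))
    co = popcount(eo & ho).sum(axis=1)
    mm = popcount((e0 & h1) | (e1 & h0)).sum(axis=1)
    hits = (
        (co >= params.min_match_alleles)
        & (mm <= params.library_cluster_mismatches)
        & packed.alive()
    )
    return [int(e) for e in np.flatnonzero(hits)]


def _match_gametes_bulk(
    haps2d: np.ndarray, packed: _PackedLibrary, params: PhasingParams,
    chunk: int = 128,
) -> np.ndarray:
    """Boolean (n_gametes, n_entries) match matrix for many gametes at once."""
    e0, e1, eo = packed.planes()
    alive = packed.alive()
    h0, h1, ho = pack_haplotypes(haps2d)
    g = haps2d.shape[0]
    out = np.zeros((g, e0.shape[0]), dtype=bool)
    for lo in range(0, g, chunk):
        hi = min(lo + chunk, g)
        co = popcount(ho[lo:hi, None, :] & eo[None, :, :]).sum(axis=-1)
        mm = popcount(
            (h0[lo:hi, None, :] & e1[None, :, :]) | (h1[lo:hi, None, :] & e0[None, :, :])
        ).sum(axis=-1)
        out[lo:hi] = (
            (co >= params.min_match_alleles)
            & (mm <= params.library_cluster_mismatches)
            & alive[None, :]
        )
    return out


def _pairwise_conflict_free(lib: CoreLibrary, entry_ids: list[int]) -> bool:
    for a in range(len(entry_ids)):
        ha = lib.alleles(entry_ids[a])
        for b in range(a + 1, len(entry_ids)):
            hb = lib.alleles(entry_ids[b])
            both = (ha != MISSING) & (hb != MISSING)
            if np.any(ha[both] != hb[both]):
                return False
    return True


def merge_library_entries(
    lib: CoreLibrary, entry_ids: list[int], h: np.ndarray | None = None
) -> int:
    """Merge entries (optionally together with a new haplotype ``h``) into one.

    The merged entry is observed on the union of the sources' observed
    positions, carrier sets are united and counts summed.  Sources must be
    pairwise conflict-free at co-observed positions.
    """
    if not _pairwise_conflict_free(lib, entry_ids):
        raise ValidationError("cannot merge library entries with opposing alleles")
    sources = [lib.alleles(e) for e in entry_ids]
    if h is not None:
        h = np.asarray(h, dtype=np.int8)
        for src in sources:
            both = (src != MISSING) & (h != MISSING)
            if np.any(src[both] != h[both]):
                raise ValidationError("new haplotype conflicts with an entry it matches")
        sources = sources + [h]
    stack = np.stack(sources)
    merged = np.full(lib.core_length, MISSING, dtype=np.int8)
    for allele in (0, 1):
        merged[(stack == allele).any(axis=0)] = allele
    carriers = set()
    count = 0
    for e in entry_ids:
        carriers |= lib.carriers[e]
        count += lib.counts[e]
        lib.kill(e)
    return lib.add(merged, count=count, carriers=carriers)


def update_library(
    lib: CoreLibrary,
    h: np.ndarray,
    carrier: tuple[int, int],
    genotyped: np.ndarray,
    params: PhasingParams,
    packed: _PackedLibrary | None = None,
    matches: list[int] | None = None,
) -> int | None:
    """Submit a candidate haplotype for its carrier gamete to the library.

    The haplotype is rejected when fewer than ``min_phased_frac_library`` of
    the carrier's genotyped core SNPs are phased.  Otherwise it is matched:
    no match inserts a new entry; mutually compatible matches are merged
    with the candidate; matches that conflict with each other cannot be the
    same haplotype, so the candidate is inserted untouched alongside them.

    Returns the entry id now carrying the gamete, or None if rejected.
    """
    h = np.asarray(h, dtype=np.int8)
    genotyped = np.asarray(genotyped, dtype=bool)
    n_geno = int(genotyped.sum())
    if n_geno == 0:
        return None
    phased_frac = float(((h != MISSING) & genotyped).sum()) / n_geno
    if phased_frac < params.min_phased_frac_library:
        return None
    lib.detach_carrier(carrier)
    if matches is None:
        matches = match_haplotype(h, lib, params, packed)
    else:
        matches = [e for e in matches if lib.is_alive(e)]
    if not matches:
        return lib.add(h, count=1, carriers={carrier})
    if len(matches) == 1:
        # fast path: the candidate adds nothing beyond its one matching
        # entry, so merging would reproduce that entry — just attach
        ent = lib.alleles(matches[0])
        obs_h = h != MISSING
        if (ent[obs_h] != MISSING).all() and (ent[obs_h] == h[obs_h]).all():
            eid = matches[0]
            lib.carriers[eid].add(carrier)
            lib.counts[eid] += 1
            lib._carrier_entry[carrier] = eid
            lib.mutations += 1
            return eid
    if _pairwise_conflict_free(lib, matches):
        eid = merge_library_entries(lib, matches, h)
        lib.carriers[eid].add(carrier)
        lib.counts[eid] += 1
        lib._carrier_entry[carrier] = eid
        return eid
    return lib.add(h, count=1, carriers={carrier})


def maintain_library(lib: CoreLibrary, params: PhasingParams, start_row: int = 0) -> bool:
    """Merge pairs of entries that the match rule identifies as one haplotype.

    Repeats until no two live entries are both co-observed at
    ``min_match_alleles`` positions and within the mismatch allowance.
    Entry rows are immutable once added, so if the invariant held for rows
    below ``start_row``, only pairs involving newer rows need checking
    (merges append rows, which are then checked in turn).  Returns True if
    anything was merged.
    """
    changed = False
    while True:
        n_rows = len(lib.counts)
        if start_row >= n_rows:
            return changed
        all_ids = lib.entry_ids()
        new_ids = [e for e in all_ids if e >= start_row]
        if len(all_ids) < 2 or not new_ids:
            return changed
        a0, a1, ao = pack_haplotypes(lib._alleles[all_ids])
        sel = [k for k, e in enumerate(all_ids) if e >= start_row]
        n0, n1, no = a0[sel], a1[sel], ao[sel]
        co = popcount(no[:, None, :] & ao[None, :, :]).sum(axis=-1)
        mm = popcount(
            (n0[:, None, :] & a1[None, :, :]) | (n1[:, None, :] & a0[None, :, :])
        ).sum(axis=-1)
        hits = (co >= params.min_match_alleles) & (mm <= params.library_cluster_mismatches)
        pos = {e: k for k, e in enumerate(all_ids)}
        for k, e in enumerate(new_ids):
            # mask the self-pair
            hits[k, pos[e]] = False
        merged_any = False
        for a, b in np.argwhere(hits):
            ea, eb = new_ids[a], all_ids[b]
            if ea == eb or not (lib.is_alive(ea) and lib.is_alive(eb)):
                continue
            if _pairwise_conflict_free(lib, [ea, eb]):
                merge_library_entries(lib, [ea, eb])
                merged_any = True
                changed = True
        start_row = n_rows
        if not merged_any and len(lib.counts) == n_rows:
            return changed


def hli_phase_core(
    codes_core: np.ndarray,
    haps_core: np.ndarray,
    lib: CoreLibrary,
    params: PhasingParams,
) -> tuple[np.ndarray, CoreLibrary]:
    """Iterate HLI over one core until no new allele is phased.

    Parameters
    ----------
    codes_core
        ``(m, L)`` genotype codes over the core.
    haps_core
        ``(m, 2, L)`` partially phased alleles from LRP; modified in place.

    The per-pass phased-allele count is non-decreasing and the loop
    terminates (alleles are only ever added, and each pass without an
    added allele or library change is the last).
    """
    m, L = codes_core.shape
    n_gametes = 2 * m
    haps = haps_core
    packed = _PackedLibrary(lib)
    # last state each gamete was submitted to the library with; all-missing
    # sentinel forces the initial submission sweep
    last_sub = np.full((m, 2, L), MISSING, dtype=np.int8)
    # incremental match cache: entry rows are immutable, so a gamete whose
    # haplotype has not changed only needs matching against rows added since
    # it was last matched (match_upto); a changed gamete rematches from 0
    match_mat = np.zeros((n_gametes, max(16, 2 * len(lib.counts))), dtype=bool)
    match_upto = np.zeros(n_gametes, dtype=np.int64)
    # fill work is only re-attempted for gametes that gained a match or
    # whose pair changed since the last attempt (fills are monotone: a
    # stale skip can only defer a fill to a pass where a trigger fires)
    changed_last = np.zeros(n_gametes, dtype=bool)
    # a preloaded library may not satisfy the no-two-entries-match invariant
    maintain_library(lib, params)
    maintained_upto = len(lib.counts)
    max_passes = int((haps == MISSING).sum() + len(lib.counts) + 2)
    for _ in range(max_passes):
        n_phased_before = int((haps != MISSING).sum())
        mutations_before = lib.mutations
        n_rows = len(lib.counts)

        # fill stage: match incomplete gametes against rows added since each
        # was last matched, then fill unanimous alleles (genotype-consistent
        # and not claiming the opposite gamete's allele at a het SNP)
        if n_rows:
            if n_rows > match_mat.shape[1]:
                grown = np.zeros((n_gametes, 2 * n_rows), dtype=bool)
                grown[:, : match_mat.shape[1]] = match_mat
                match_mat = grown
            flat = haps.reshape(n_gametes, L)
            pending = np.flatnonzero((flat == MISSING).any(axis=1))
            stale = pending[match_upto[pending] < n_rows]
            gained = np.zeros(n_gametes, dtype=bool)
            e0, e1, eo = packed.planes()
            for upto in np.unique(match_upto[stale]):
                grp = stale[match_upto[stale] == upto]
                h0, h1, ho = pack_haplotypes(np.ascontiguousarray(flat[grp]))
                ne0, ne1, neo = e0[upto:n_rows], e1[upto:n_rows], eo[upto:n_rows]
                for lo in range(0, grp.size, 128):
                    hi = min(lo + 128, grp.size)
                    co = popcount(ho[lo:hi, None, :] & neo[None, :, :]).sum(axis=-1)
                    mm = popcount(
                        (h0[lo:hi, None, :] & ne1[None, :, :])
                        | (h1[lo:hi, None, :] & ne0[None, :, :])
                    ).sum(axis=-1)
                    new = (co >= params.min_match_alleles) & (
                        mm <= params.library_cluster_mismatches
                    )
                    match_mat[grp[lo:hi], upto:n_rows] = new
                    gained[grp[lo:hi]] = new.any(axis=1)
            match_upto[stale] = n_rows
            alive = packed.alive()
            partner = np.arange(n_gametes) ^ 1
            refill = pending[
                gained[pending] | changed_last[pending] | changed_last[partner[pending]]
            ]
            for gidx in refill:
                rows = np.flatnonzero(match_mat[gidx, : alive.size] & alive)
                if rows.size == 0:
                    continue
                i, slot = divmod(int(gidx), 2)
                g = codes_core[i]
                h = haps[i, slot]
                other = haps[i, 1 - slot]
                missing_before = h == MISSING
                mat = lib._alleles[rows]
                any0 = (mat == 0).any(axis=0)
                any1 = (mat == 1).any(axis=0)
                het = g == 1
                f0 = missing_before & any0 & ~any1 & (g != 2) & ~(het & (other == 0))
                f1 = missing_before & any1 & ~any0 & (g != 0) & ~(het & (other == 1))
                if f0.any() or f1.any():
                    h[f0] = 0
                    h[f1] = 1

        # complement + clash guard for every changed individual
        changed = (haps != last_sub).any(axis=(1, 2))
        for i in np.flatnonzero(changed):
            g = codes_core[i]
            for slot in (0, 1):
                comp = complement_from_genotype(g, haps[i, slot])
                other = haps[i, 1 - slot]
                fill = (other == MISSING) & (comp != MISSING)
                other[fill] = comp[fill]
            clash = (g == 1) & (haps[i, 0] != MISSING) & (haps[i, 0] == haps[i, 1])
            if clash.any():
                haps[i, 0][clash] = MISSING
                haps[i, 1][clash] = MISSING

        # library submission, gamete by gamete against the live library (so
        # that duplicate haplotypes merge as they are discovered); a gamete
        # is (re)submitted only when it differs from its last submitted state
        sub_flat = haps.reshape(n_gametes, L)
        sub_gidx = np.flatnonzero(
            (sub_flat != last_sub.reshape(n_gametes, L)).any(axis=1)
        )
        changed_last[:] = False
        changed_last[sub_gidx] = True
        for gidx in sub_gidx:
            i, slot = divmod(int(gidx), 2)
            g = codes_core[i]
            update_library(
                lib, haps[i, slot].copy(), (i, slot), g != MISSING, params, packed
            )
            last_sub[i, slot] = haps[i, slot]
            # the gamete's haplotype changed: invalidate its cache
            match_mat[gidx, :] = False
            match_upto[gidx] = 0
        if lib.mutations != mutations_before:
            maintain_library(lib, params, start_row=maintained_upto)
            maintained_upto = len(lib.counts)
        n_phased_after = int((haps != MISSING).sum())
        if n_phased_after == n_phased_before and lib.mutations == mutations_before:
            break
    return haps, lib


def hli_phase(
    codes: np.ndarray,
    haps: np.ndarray,
    cores: list[Core],
    library: HaplotypeLibrary,
    params: PhasingParams,
) -> tuple[np.ndarray, HaplotypeLibrary]:
    """Run HLI over every core of a chromosome (haps modified in place)."""
    for k, core in enumerate(cores):
        hli_phase_core(
            np.ascontiguousarray(codes[:, core.slice()]),
            haps[:, :, core.slice()],
            library[k],
            params,
        )
    return haps, library
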