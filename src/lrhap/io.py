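"""Readers and writers for the plain-text file formats.

Formats (all whitespace-delimited, one record per line):

* genotypes   — ``ID g1 ... gN`` with g in {0,1,2,9}; 9 = missing
* pedigree    — ``ID SIRE DAM``; 0 = unknown parent
* phase       — two lines per individual (gamete 1 then gamete 2),
                ``ID a1 ... aN`` with 9 = unphased
* library     — versioned header, then ``CORE_INDEX ALLELESTRING COUNT``
* array map   — which SNP indices each array covers and which array each
                individual was genotyped on

A minimal phased-VCF export (via pysam) is provided as an output-only path.
"""

from __future__ import annotations

import numpy as np

from .exceptions import FormatError, ValidationError
from .haplotypes import HaplotypeLibrary
from .types import DISK_MISSING, MISSING, UNKNOWN_PARENT, Core, GenotypeMatrix, Pedigree

_LIBRARY_MAGIC = "#lrhap-library v1"
_ARRAYS_MAGIC = "#lrhap-arrays v1"


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, missing_code: int = DISK_MISSING) -> GenotypeMatrix:
    """Read a genotype file (``ID g1 ... gN``; ``missing_code`` = missing)."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    valid = {0, 1, 2, missing_code}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            ids.append(tokens[0])
            try:
                codes = [int(t) for t in tokens[1:]]
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer genotype code") from exc
            bad = [c for c in codes if c not in valid]
            if bad:
                raise FormatError(
                    f"line {lineno}: genotype code {bad[0]} outside "
                    f"{{0, 1, 2, {missing_code}}}"
                )
            row = np.asarray(codes, dtype=np.int8)
            row[row == missing_code] = MISSING
            if rows and len(row) != len(rows[0]):
                raise FormatError(
                    f"line {lineno}: {len(row)} SNPs but previous lines have {len(rows[0])}"
                )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: empty genotype file")
    return GenotypeMatrix(ids=ids, codes=np.vstack(rows))


def write_genotypes(matrix: GenotypeMatrix, path, missing_code: int = DISK_MISSING) -> None:
    codes = matrix.codes.copy()
    codes_out = codes.astype(np.int64)
    codes_out[codes == MISSING] = missing_code
    with open(path, "w") as fh:
        for ident, row in zip(matrix.ids, codes_out):
            fh.write(ident + " " + " ".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def read_pedigree(path) -> Pedigree:
    """Read a three-column pedigree (``ID SIRE DAM``; ``0`` = unknown)."""
    records: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 3:
                raise FormatError(f"line {lineno}: expected 3 columns, got {len(tokens)}")
            ident, sire, dam = tokens
            if ident in (sire, dam):
                raise ValidationError(f"line {lineno}: {ident!r} listed as its own parent")
            records.append((ident, sire, dam))
    listed = [r[0] for r in records]
    if len(set(listed)) != len(listed):
        raise ValidationError(f"{path}: duplicate individual in pedigree")
    index = {ident: k for k, ident in enumerate(listed)}
    ids = list(listed)
    external: list[str] = []
    for _, sire, dam in records:
        for parent in (sire, dam):
            if parent != "0" and parent not in index:
                index[parent] = len(ids)
                ids.append(parent)
                external.append(parent)
    n = len(ids)
    sire_idx = np.full(n, UNKNOWN_PARENT, dtype=np.int64)
    dam_idx = np.full(n, UNKNOWN_PARENT, dtype=np.int64)
    for k, (_, sire, dam) in enumerate(records):
        if sire != "0":
            sire_idx[k] = index[sire]
        if dam != "0":
            dam_idx[k] = index[dam]
    ext = np.zeros(n, dtype=bool)
    ext[len(listed):] = True
    return Pedigree(ids=ids, sire=sire_idx, dam=dam_idx, external_founder=ext)


def write_pedigree(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for k, ident in enumerate(pedigree.ids):
            if pedigree.external_founder[k]:
                continue
            s = pedigree.sire[k]
            d = pedigree.dam[k]
            fh.write(
                f"{ident} "
                f"{pedigree.ids[s] if s != UNKNOWN_PARENT else 0} "
                f"{pedigree.ids[d] if d != UNKNOWN_PARENT else 0}\n"
            )


# ---------------------------------------------------------------------------
# phase
# ---------------------------------------------------------------------------

def write_phase(ids, haplotypes: np.ndarray, path) -> None:
    """Write phased haplotypes: two lines per individual, 9 = unphased."""
    haps = np.asarray(haplotypes, dtype=np.int8)
    if haps.ndim != 3 or haps.shape[0] != len(ids) or haps.shape[1] != 2:
        raise ValidationError("haplotypes must have shape (n_individuals, 2, n_snps)")
    out = haps.astype(np.int64)
    out[haps == MISSING] = DISK_MISSING
    with open(path, "w") as fh:
        for ident, pair in zip(ids, out):
            for gamete in pair:
                fh.write(ident + " " + " ".join(map(str, gamete)) + "\n")


def read_phase(path) -> tuple[list[str], np.ndarray]:
    """Inverse of :func:`write_phase`: returns (ids, (n, 2, n_snps) alleles)."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    row_ids: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            row_ids.append(tokens[0])
            row = np.asarray([int(t) for t in tokens[1:]], dtype=np.int8)
            bad = ~np.isin(row, (0, 1, DISK_MISSING))
            if bad.any():
                raise FormatError(f"line {lineno}: allele outside {{0, 1, {DISK_MISSING}}}")
            row[row == DISK_MISSING] = MISSING
            rows.append(row)
    if len(rows) % 2:
        raise FormatError(f"{path}: odd number of lines ({len(rows)}); expected two per individual")
    for k in range(0, len(rows), 2):
        if row_ids[k] != row_ids[k + 1]:
            raise FormatError(
                f"{path}: gamete lines {k + 1}/{k + 2} belong to different individuals"
            )
        ids.append(row_ids[k])
    haps = np.stack([np.stack(rows[k : k + 2]) for k in range(0, len(rows), 2)])
    return ids, haps


# ---------------------------------------------------------------------------
# haplotype library
# ---------------------------------------------------------------------------

def save_library(library: HaplotypeLibrary, path) -> None:
    """Persist a library as text.  Carrier sets are not persisted."""
    with open(path, "w") as fh:
        fh.write(_LIBRARY_MAGIC + "\n")
        for k, core in enumerate(library.cores):
            fh.write(f"#core {k} {core.start} {core.end}\n")
        for k in range(len(library)):
            lib = library[k]
            for eid in lib.entry_ids():
                alleles = lib.alleles(eid)
                s = "".join(
                    str(DISK_MISSING) if a == MISSING else str(a) for a in alleles
                )
                fh.write(f"{k} {s} {lib.counts[eid]}\n")


def load_library(path) -> HaplotypeLibrary:
    """Inverse of :func:`save_library`; loaded entries have empty carrier sets."""
    cores: list[Core] = []
    entries: list[tuple[int, str, int]] = []
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _LIBRARY_MAGIC:
            raise FormatError(f"{path}: not a library file (bad header {magic!r})")
        for lineno, line in enumerate(fh, start=2):
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0] == "#core":
                cores.append(Core(int(tokens[2]), int(tokens[3])))
                continue
            if len(tokens) != 3:
                raise FormatError(f"line {lineno}: expected 'CORE ALLELES COUNT'")
            entries.append((int(tokens[0]), tokens[1], int(tokens[2])))
    library = HaplotypeLibrary(cores)
    for core_index, allele_string, count in entries:
        bad = set(allele_string) - {"0", "1", str(DISK_MISSING)}
        if bad:
            raise FormatError(f"allele character {bad.pop()!r} outside {{0, 1, {DISK_MISSING}}}")
        alleles = np.asarray(
            [MISSING if ch == str(DISK_MISSING) else int(ch) for ch in allele_string],
            dtype=np.int8,
        )
        library[core_index].add(alleles, count=count, carriers=())
    return library


# ---------------------------------------------------------------------------
# array-membership map
# ---------------------------------------------------------------------------

def write_array_map(arrays, assignment: dict, path) -> None:
    """Write array SNP sets and per-individual array assignment.

    ``arrays`` is a list of SNP-index iterables; ``assignment`` maps
    individual identifier -> array index.
    """
    with open(path, "w") as fh:
        fh.write(_ARRAYS_MAGIC + "\n")
        for k, snps in enumerate(arrays):
            fh.write(f"array {k} " + " ".join(map(str, sorted(snps))) + "\n")
        for ident, k in assignment.items():
            fh.write(f"assign {ident} {k}\n")


def read_array_map(path) -> tuple[list[np.ndarray], dict]:
    arrays: dict[int, np.ndarray] = {}
    assignment: dict[str, int] = {}
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _ARRAYS_MAGIC:
            raise FormatError(f"{path}: not an array-map file")
        for lineno, line in enumerate(fh, start=2):
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0] == "array":
                arrays[int(tokens[1])] = np.asarray(tokens[2:], dtype=np.int64)
            elif tokens[0] == "assign":
                assignment[tokens[1]] = int(tokens[2])
            else:
                raise FormatError(f"line {lineno}: unknown record {tokens[0]!r}")
    return [arrays[k] for k in sorted(arrays)], assignment


# ---------------------------------------------------------------------------
# optional SNP map (name, position in Morgans)
# ---------------------------------------------------------------------------

def write_snp_map(names, positions, path) -> None:
    with open(path, "w") as fh:
        for name, pos in zip(names, positions):
            fh.write(f"{name} {pos:.8f}\n")


def read_snp_map(path) -> tuple[list[str], np.ndarray]:
    names: list[str] = []
    positions: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 2:
                raise FormatError(f"line {lineno}: expected 'NAME POSITION'")
            names.append(tokens[0])
            positions.append(float(tokens[1]))
    pos = np.asarray(positions)
    if (np.diff(pos) < 0).any():
        raise ValidationError(f"{path}: SNP positions must be non-decreasing")
    return names, pos


# ---------------------------------------------------------------------------
# VCF export (output only)
# ---------------------------------------------------------------------------

def export_vcf(ids, haplotypes: np.ndarray, genotypes: GenotypeMatrix, path,
               contig: str = "1") -> None:
    """Export phased genotypes as VCF via pysam.

    GT is written with ``|`` where both alleles are phased, with ``/`` from
    the raw genotype where unphased, and ``./.`` where the genotype is
    missing.  Positions are 1-based SNP indices (no physical map is claimed).
    """
    import pysam

    haps = np.asarray(haplotypes, dtype=np.int8)
    n, _, n_snps = haps.shape
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={n_snps}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for ident in ids:
        header.add_sample(ident)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j in range(n_snps):
            rec = vcf.new_record(
                contig=contig, start=j, stop=j + 1, alleles=("A", "B"), id=f"snp{j}"
            )
            for k, ident in enumerate(ids):
                a, b = haps[k, :, j]
                g = genotypes.codes[k, j]
                if a != MISSING and b != MISSING:
                    rec.samples[ident]["GT"] = (int(a), int(b))
                    rec.samples[ident].phased = True
                elif g == MISSING:
                    rec.samples[ident]["GT"] = (None, None)
                else:
                    gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(g)]
                    rec.samples[ident]["GT"] = gt
                    rec.samples[ident].phased = False
            vcf.write(rec)
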