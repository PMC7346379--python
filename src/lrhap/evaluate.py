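"""Phasing-accuracy statistics against simulation truth.

Three statistics are reported: the percentage of correctly phased, of
unphased, and of incorrectly phased alleles, either over all loci or (the
usual choice, since only these are informative) over heterozygous loci.
Because cores are phased independently of each other, the inferred pair
is aligned to the true pair per core: both assignments are scored and the
better one kept, so a global gamete swap within a core costs nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .types import MISSING, Core, GenotypeMatrix


@dataclass
class PhasingStats:
    """Correct / unphased / incorrect allele counts and percentages."""

    scope: str                 # "all" or "heterozygous"
    n_correct: int
    n_unphased: int
    n_incorrect: int

    @property
    def total(self) -> int:
        return self.n_correct + self.n_unphased + self.n_incorrect

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.total if self.total else 0.0

    @property
    def percent_correct(self) -> float:
        return self._pct(self.n_correct)

    @property
    def percent_unphased(self) -> float:
        return self._pct(self.n_unphased)

    @property
    def percent_incorrect(self) -> float:
        return self._pct(self.n_incorrect)

    def as_row(self) -> dict:
        return {
            "scope": self.scope,
            "percent_correct": self.percent_correct,
            "percent_unphased": self.percent_unphased,
            "percent_incorrect": self.percent_incorrect,
            "n_correct": self.n_correct,
            "n_unphased": self.n_unphased,
            "n_incorrect": self.n_incorrect,
        }


def phasing_statistics(
    inferred: np.ndarray,
    truth: np.ndarray,
    genotypes: GenotypeMatrix | None,
    cores: list[Core],
    scope: str = "heterozygous",
    snp_scope: str = "all",
    rows: np.ndarray | None = None,
) -> PhasingStats:
    """Score inferred haplotypes against the truth.

    Parameters
    ----------
    inferred, truth
        ``(n, 2, n_snps)`` allele arrays; inferred may contain MISSING.
    genotypes
        Observed (possibly masked) genotypes; required when
        ``snp_scope="genotyped"``, which restricts scoring to each
        individual's own genotyped SNPs.  ``snp_scope="all"`` scores every
        SNP, including those the individual's array does not cover.
    scope
        ``"heterozygous"`` scores only SNPs where the *true* genotype is
        heterozygous; ``"all"`` scores every SNP in the SNP scope.
    rows
        Optional subset of individuals (row indices) to score.
    """
    inferred = np.asarray(inferred, dtype=np.int8)
    truth = np.asarray(truth, dtype=np.int8)
    if inferred.shape != truth.shape:
        raise ValidationError(
            f"inferred {inferred.shape} and truth {truth.shape} shapes differ"
        )
    if scope not in ("all", "heterozygous"):
        raise ValidationError(f"unknown scope {scope!r}")
    if snp_scope not in ("all", "genotyped"):
        raise ValidationError(f"unknown snp_scope {snp_scope!r}")
    if rows is not None:
        inferred = inferred[rows]
        truth = truth[rows]
    mask = np.ones(inferred.shape[::2], dtype=bool)  # (n, n_snps)
    if scope == "heterozygous":
        mask &= truth.sum(axis=1) == 1
    if snp_scope == "genotyped":
        if genotypes is None:
            raise ValidationError("snp_scope='genotyped' requires genotypes")
        codes = genotypes.codes[rows] if rows is not None else genotypes.codes
        if codes.shape != mask.shape:
            raise ValidationError("genotypes do not match the haplotype arrays")
        mask &= codes != MISSING

    n_correct = n_incorrect = n_unphased = 0
    for core in cores:
        sl = core.slice()
        inf = inferred[:, :, sl]
        tru = truth[:, :, sl]
        m = mask[:, sl]
        phased = inf != MISSING
        # orientation 0: slot k vs true slot k; orientation 1: swapped
        cor = np.empty((2,) + m.shape[:1], dtype=np.int64)
        inc = np.empty_like(cor)
        for o, t in enumerate((tru, tru[:, ::-1, :])):
            eq = phased & (inf == t) & m[:, None, :]
            ne = phased & (inf != t) & m[:, None, :]
            cor[o] = eq.sum(axis=(1, 2))
            inc[o] = ne.sum(axis=(1, 2))
        best = np.argmax(cor, axis=0)
        pick_cor = cor[best, np.arange(cor.shape[1])]
        pick_inc = inc[best, np.arange(cor.shape[1])]
        n_correct += int(pick_cor.sum())
        n_incorrect += int(pick_inc.sum())
        n_unphased += int((2 * m.sum(axis=1) - pick_cor - pick_inc).sum())
    return PhasingStats(
        scope=scope, n_correct=n_correct, n_unphased=n_unphased, n_incorrect=n_incorrect
    )


def aggregate_stats(stats_list: list[PhasingStats]) -> PhasingStats:
    """Unweighted mean of group percentages (counts are summed for reference).

    Returns a stats object whose percentage properties equal the arithmetic
    means across groups; since a plain count triple cannot represent an
    arbitrary percentage mean, the mean percentages are attached explicitly.
    """
    if not stats_list:
        raise ValidationError("cannot aggregate an empty list of statistics")
    scopes = {s.scope for s in stats_list}
    if len(scopes) != 1:
        raise ValidationError(f"cannot aggregate mixed scopes {scopes}")
    agg = PhasingStats(
        scope=stats_list[0].scope,
        n_correct=sum(s.n_correct for s in stats_list),
        n_unphased=sum(s.n_unphased for s in stats_list),
        n_incorrect=sum(s.n_incorrect for s in stats_list),
    )
    mean = {
        "percent_correct": float(np.mean([s.percent_correct for s in stats_list])),
        "percent_unphased": float(np.mean([s.percent_unphased for s in stats_list])),
        "percent_incorrect": float(np.mean([s.percent_incorrect for s in stats_list])),
    }

    class _Aggregated(PhasingStats):
        percent_correct = property(lambda self: mean["percent_correct"])
        percent_unphased = property(lambda self: mean["percent_unphased"])
        percent_incorrect = property(lambda self: mean["percent_incorrect"])

    return _Aggregated(agg.scope, agg.n_correct, agg.n_unphased, agg.n_incorrect)


def grouped_stats(
    inferred: np.ndarray,
    truth: np.ndarray,
    genotypes: GenotypeMatrix | None,
    cores: list[Core],
    groups: np.ndarray,
    scope: str = "heterozygous",
    snp_scope: str = "all",
) -> tuple[dict, PhasingStats]:
    """Per-group statistics (e.g. per breed or per generation) plus their
    unweighted average."""
    groups = np.asarray(groups)
    per_group = {}
    for g in np.unique(groups):
        rows = np.flatnonzero(groups == g)
        per_group[g] = phasing_statistics(
            inferred, truth, genotypes, cores, scope=scope, snp_scope=snp_scope, rows=rows
        )
    return per_group, aggregate_stats(list(per_group.values()))


def concat_core_results(parts) -> np.ndarray:
    """Concatenate per-core phase outputs into a whole-chromosome phase.

    ``parts`` is an iterable of ``(Core, haplotypes)`` with haplotypes of
    shape ``(n, 2, len(core))``.  Input order is irrelevant (parts are
    sorted by core start); gaps or overlaps raise a validation error naming
    the offending interval.
    """
    parts = sorted(parts, key=lambda p: p[0].start)
    if not parts:
        raise ValidationError("no core results to concatenate")
    expected = 0
    for core, haps in parts:
        if core.start > expected:
            raise ValidationError(f"missing core output covering [{expected}, {core.start})")
        if core.start < expected:
            raise ValidationError(f"overlapping core output at [{core.start}, {core.end})")
        if haps.shape[2] != len(core):
            raise ValidationError(f"core [{core.start}, {core.end}) has wrong width")
        expected = core.end
    n = parts[0][1].shape[0]
    out = np.concatenate([h for _, h in parts], axis=2)
    if out.shape[0] != n or any(h.shape[0] != n for _, h in parts):
        raise ValidationError("core outputs cover different individual sets")
    return out
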