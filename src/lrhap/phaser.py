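"""Scikit-learn style estimator wrapping the phasing pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import ValidationError
from .haplotypes import HaplotypeLibrary
from .pipeline import phase_dataset
from .types import DISK_MISSING, MISSING, GenotypeMatrix, Pedigree, PhasingParams


class LongRangePhaser(BaseEstimator):
    """Haplotype phasing by long-range phasing plus haplotype library
    imputation.

    The estimator is transductive: :meth:`fit` phases the genotype matrix
    it is given and stores the result; :meth:`transform` returns the phased
    alleles for that same matrix.  Genotype codes are 0/1/2 with 9 (or -1)
    for missing, one row per individual, one column per SNP.

    Parameters mirror the method's tuning knobs; see
    :class:`~lrhap.types.PhasingParams` for their meaning and defaults.

    Attributes
    ----------
    haplotypes_ : ndarray of shape (n_individuals, 2, n_snps)
        Phased alleles in {0, 1}, -1 where unphased.
    library_ : HaplotypeLibrary
        The per-core haplotype library built during fitting.
    cores_ : list of Core
        The core tiling of the chromosome.
    """

    def __init__(
        self,
        core_length: int = 500,
        subset_size: int = 5000,
        max_surrogates: int = 10,
        surrogate_disagree_frac: float = 0.10,
        min_shared_markers: int = 100,
        min_phased_frac_library: float = 0.80,
        min_match_alleles: int = 200,
        library_cluster_mismatches: int = 0,
        max_surrogate_depth: int = 10,
        consensus_agreement_frac: float = 0.9,
        random_state: int = 0,
    ):
        self.core_length = core_length
        self.subset_size = subset_size
        self.max_surrogates = max_surrogates
        self.surrogate_disagree_frac = surrogate_disagree_frac
        self.min_shared_markers = min_shared_markers
        self.min_phased_frac_library = min_phased_frac_library
        self.min_match_alleles = min_match_alleles
        self.library_cluster_mismatches = library_cluster_mismatches
        self.max_surrogate_depth = max_surrogate_depth
        self.consensus_agreement_frac = consensus_agreement_frac
        self.random_state = random_state

    def _params(self) -> PhasingParams:
        return PhasingParams(
            core_length=self.core_length,
            subset_size=self.subset_size,
            max_surrogates=self.max_surrogates,
            surrogate_disagree_frac=self.surrogate_disagree_frac,
            min_shared_markers=self.min_shared_markers,
            min_phased_frac_library=self.min_phased_frac_library,
            min_match_alleles=self.min_match_alleles,
            library_cluster_mismatches=self.library_cluster_mismatches,
            max_surrogate_depth=self.max_surrogate_depth,
            consensus_agreement_frac=self.consensus_agreement_frac,
            rng_seed=self.random_state,
        )

    @staticmethod
    def _as_matrix(X) -> GenotypeMatrix:
        if isinstance(X, GenotypeMatrix):
            return X
        codes = np.asarray(X, dtype=np.int8).copy()
        codes[codes == DISK_MISSING] = MISSING
        ids = [str(k) for k in range(codes.shape[0])]
        return GenotypeMatrix(ids=ids, codes=codes)

    def fit(self, X, y=None, pedigree: Pedigree | None = None,
            library: HaplotypeLibrary | None = None):
        """Phase ``X`` and store the result.

        ``pedigree`` (optional) improves paternal/maternal side assignment;
        ``library`` (optional) seeds HLI with haplotypes from a previous run.
        """
        matrix = self._as_matrix(X)
        haps, cores, lib = phase_dataset(
            matrix, pedigree, self._params(), library_in=library
        )
        self.n_features_in_ = matrix.n_snps
        self.ids_ = list(matrix.ids)
        self.haplotypes_ = haps
        self.cores_ = cores
        self.library_ = lib
        return self

    def transform(self, X=None) -> np.ndarray:
        """Return the phased alleles for the fitted matrix, stacked as
        ``(n_individuals, 2 * n_snps)`` (gamete 1 columns then gamete 2)."""
        if not hasattr(self, "haplotypes_"):
            raise ValidationError("LongRangePhaser is not fitted")
        if X is not None:
            matrix = self._as_matrix(X)
            if matrix.n_snps != self.n_features_in_ or matrix.n_individuals != len(self.ids_):
                raise ValidationError(
                    "transform only returns phase for the matrix passed to fit"
                )
        n = self.haplotypes_.shape[0]
        return self.haplotypes_.reshape(n, -1)

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).transform()

    def phased_fraction(self) -> float:
        """Fraction of alleles phased in the fitted matrix."""
        if not hasattr(self, "haplotypes_"):
            raise ValidationError("LongRangePhaser is not fitted")
        return float((self.haplotypes_ != MISSING).mean())
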