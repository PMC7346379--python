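"""Exception hierarchy for lrhap."""


class LrhapError(Exception):
    """Base class for all lrhap errors."""


class FormatError(LrhapError):
    """A file on disk does not follow the expected text format."""


class ValidationError(LrhapError):
    """Inputs violate a structural invariant (e.g. a cyclic pedigree)."""


class ParameterError(LrhapError):
    """A parameter value is outside its valid range."""


class PhaseConflictError(LrhapError):
    """A haplotype contradicts the genotype at one or more positions.

    ``positions`` holds the 0-based SNP indices of the conflicts.
    """

    def __init__(self, positions):
        self.positions = list(positions)
        super().__init__(
            f"haplotype conflicts with homozygous genotype at positions {self.positions}"
        )


class SimulationError(LrhapError):
    """The population simulation cannot satisfy the requested output."""
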