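"""Named exceptions raised across the package.

Every error a caller may want to catch by category has its own class; all
inherit from :class:`RibosimError` so blanket handling stays possible.
"""


class RibosimError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RibosimError, ValueError):
    """A scalar or table argument violates a documented precondition."""


class InvalidCodonError(InvalidInputError):
    """A codon is not a sense codon over ACGT/U."""


class DegenerateCodonError(RibosimError):
    """A codon has zero total cognate arrival frequency."""


class TableConstructionError(RibosimError):
    """A codon rate table cannot be built (e.g. a codon with no cognate)."""


class InvalidCDSError(InvalidInputError):
    """A coding sequence fails validation (length, alphabet, internal stop)."""


class InvalidProfileError(InvalidInputError):
    """A per-codon dwell-time profile is malformed or non-positive."""


class InvalidEditError(InvalidInputError):
    """A point mutation is out of range or introduces an internal stop."""


class CollisionError(RibosimError):
    """A halt-mode simulation stopped at a ribosome collision."""

    def __init__(self, time: float, blocked_sites: list[int]):
        self.time = time
        self.blocked_sites = list(blocked_sites)
        super().__init__(
            f"ribosome collision at t={time:.6g} s; "
            f"blocked active sites (1-based codons): {self.blocked_sites}"
        )


class UndefinedLoadError(RibosimError):
    """Ribosome load is undefined (zero transcript copies)."""


class DerivationError(RibosimError):
    """A per-gene parameter cannot be derived (e.g. codon missing from table)."""


class ConfigurationError(RibosimError):
    """Unknown organism or malformed configuration."""


class UndefinedCorrelationError(RibosimError):
    """Rank correlation is undefined (constant input vector)."""


class GenerationError(RibosimError):
    """A synthetic fixture request is infeasible."""
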