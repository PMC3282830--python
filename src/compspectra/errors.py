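"""Exception hierarchy for compspectra.

All package-specific failures derive from :class:`CompspectraError` so callers
(and the CLI) can catch one base class.
"""


class CompspectraError(Exception):
    """Base class for all compspectra errors."""


class AlignmentShapeError(CompspectraError):
    """Sequences of unequal length, or an empty/degenerate alignment."""


class DuplicateTaxonError(CompspectraError):
    """Two rows carry the same taxon label."""


class CharacterError(CompspectraError):
    """A symbol outside the declared alphabet, with taxon and column named."""

    def __init__(self, taxon: str, column: int, symbol: str):
        self.taxon = taxon
        self.column = column  # 1-based
        self.symbol = symbol
        super().__init__(
            f"unknown character {symbol!r} for taxon {taxon!r} at column {column}"
        )


class AlphabetError(CompspectraError):
    """Operation requested on an alphabet it is not defined for."""


class AllMissingError(CompspectraError):
    """A taxon has zero counted (unambiguous, non-gap, non-missing) sites."""


class AmbiguousMappingError(CompspectraError):
    """Two source taxa of one alignment map to the same OTU."""


class PartitionError(CompspectraError):
    """Invalid partition/charset definition (out of bounds, bad overlap...)."""


class ConfigurationError(CompspectraError):
    """Invalid run configuration (groups, hypotheses, frames, drop specs)."""


class EmptyAlignmentError(CompspectraError):
    """A masking or subsetting operation removed every column."""
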