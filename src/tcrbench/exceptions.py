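"""Exception hierarchy for tcrbench.

All package-specific errors derive from :class:`TcrBenchError` so callers can
catch one base class at CLI boundaries.
"""


class TcrBenchError(Exception):
    """Base class for all tcrbench errors."""


class EmptySequenceError(TcrBenchError, ValueError):
    """A sequence was empty after whitespace stripping."""


class InvalidResidueError(TcrBenchError, ValueError):
    """A sequence contains a character outside the 20-letter amino-acid alphabet.

    Attributes
    ----------
    residue : str
        The first offending character (left-to-right scan).
    position : int
        0-based position of the offending character.
    """

    def __init__(self, seq: str, residue: str, position: int):
        self.seq = seq
        self.residue = residue
        self.position = position
        super().__init__(
            f"invalid residue {residue!r} at position {position} in sequence {seq!r}"
        )


class MissingColumnError(TcrBenchError, KeyError):
    """An input table lacks a required column."""


class MissingFieldError(TcrBenchError, KeyError):
    """A requested field is not populated in the table."""


class EmptyPositivesError(TcrBenchError, ValueError):
    """Negative generation was asked to run on an empty positive set."""


class NoEligiblePeptidesError(TcrBenchError, ValueError):
    """The hard split's eligible peptide set P_{l,u} is empty."""


class EmptyHistogramError(TcrBenchError, ValueError):
    """A class histogram with no entries cannot be summarised."""


class SingleClassError(TcrBenchError, ValueError):
    """Rank metrics require both classes to be present."""


class SequenceTooLongError(TcrBenchError, ValueError):
    """A sequence exceeds the encoder's fixed maximum length."""


class UnknownAlleleError(TcrBenchError, KeyError):
    """An MHC allele has no pseudo-sequence in the supplied map."""


class ConfigError(TcrBenchError, ValueError):
    """A configuration object is internally inconsistent or infeasible."""


class EmptyListError(TcrBenchError, ValueError):
    """An aggregate was requested over zero reports."""
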