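"""Amino-acid alphabet and sequence validation.

The package is strict about residues: only the 20 standard amino acids are
accepted (uppercase). Ambiguity codes (B, J, Z, X), the rare residues O and U,
and stop/gap characters ('*', '-', '.') are rejected rather than silently
coerced, because a single bad residue would otherwise propagate into substitution
-matrix encodings as a KeyError far from its origin.
"""

from __future__ import annotations

from .exceptions import EmptySequenceError, InvalidResidueError

#: The 20 standard residues in fixed alphabetical order. This ordering also
#: defines the column layout of substitution-matrix encodings.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)

#: Residue -> column index in the fixed alphabetical layout.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def validate_sequence(seq: str, kind: str = "peptide") -> str:
    """Validate and normalise an amino-acid sequence.

    Parameters
    ----------
    seq : str
        Raw sequence; surrounding whitespace is stripped and case is ignored.
    kind : {"peptide", "cdr3"}
        Only used in error messages.

    Returns
    -------
    str
        The uppercased sequence.

    Raises
    ------
    EmptySequenceError
        If the sequence is empty after stripping.
    InvalidResidueError
        At the first (left-to-right) character outside ``AMINO_ACIDS``.
    """
    s = seq.strip().upper()
    if not s:
        raise EmptySequenceError(f"empty {kind} sequence")
    for i, ch in enumerate(s):
        if ch not in _AA_SET:
            raise InvalidResidueError(s, ch, i)
    return s


def is_valid_sequence(seq: str) -> bool:
    """Return True iff ``validate_sequence`` would accept ``seq``."""
    s = seq.strip().upper()
    return bool(s) and all(ch in _AA_SET for ch in s)
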