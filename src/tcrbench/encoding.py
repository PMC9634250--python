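"""BLOSUM sequence encoding and MHC pseudo-sequence attachment.

Each residue is represented by its substitution-score vector against the 20
standard residues (BLOSUM50 by default, via Biopython's canonical matrices),
and sequences are right-padded with constant rows to a fixed per-field length.
The default maximum lengths mirror the dataset builder's filter bounds, so no
post-filter sequence can overflow; the MHC pseudo-sequence slot defaults to 34
positions (the NetMHCpan-style convention), but the allele -> pseudo-sequence
map itself is always user-supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .exceptions import ConfigError, SequenceTooLongError, UnknownAlleleError
from .sequences import AMINO_ACIDS, validate_sequence
from .types import SampleTable


@dataclass(frozen=True)
class EncodingConfig:
    matrix: str = "BLOSUM50"
    max_len_peptide: int = 15
    max_len_cdr3b: int = 23
    max_len_cdr3a: int = 21
    max_len_pseudo: int = 34
    pad_value: float = 0.0

    def max_len_for(self, field: str) -> int:
        try:
            return {
                "peptide": self.max_len_peptide,
                "cdr3b": self.max_len_cdr3b,
                "cdr3a": self.max_len_cdr3a,
                "pseudo": self.max_len_pseudo,
            }[field]
        except KeyError:
            raise ConfigError(f"no maximum length defined for field {field!r}")


@lru_cache(maxsize=4)
def residue_score_matrix(name: str = "BLOSUM50") -> np.ndarray:
    """20x20 substitution-score array in fixed alphabetical residue order."""
    mat = substitution_matrices.load(name)
    out = np.empty((20, 20), dtype=np.float32)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a, b]
    return out


def blosum_encode(seq: str, max_len: int, cfg: EncodingConfig = EncodingConfig()) -> np.ndarray:
    """Encode one sequence as a (max_len, 20) matrix.

    Row i (i < len(seq)) is residue i's substitution-score vector; rows beyond
    the sequence are filled with ``cfg.pad_value``.
    """
    s = validate_sequence(seq)
    if len(s) > max_len:
        raise SequenceTooLongError(f"sequence of length {len(s)} exceeds max_len={max_len}")
    scores = residue_score_matrix(cfg.matrix)
    out = np.full((max_len, 20), cfg.pad_value, dtype=np.float32)
    idx = [AMINO_ACIDS.index(ch) for ch in s]
    out[: len(s)] = scores[idx]
    return out


def encode_table(
    table: SampleTable,
    fields: tuple[str, ...] = ("peptide", "cdr3b"),
    cfg: EncodingConfig = EncodingConfig(),
) -> np.ndarray:
    """Flattened, concatenated per-field encodings: shape (n_rows, sum(max_len)*20).

    Vectorised over rows: each field's unique sequences are encoded once.
    Empty optional values encode as all-padding blocks.
    """
    blocks = []
    scores = residue_score_matrix(cfg.matrix)
    for field in fields:
        col = "pseudo" if field == "pseudo" else field
        if col not in table.df.columns:
            raise ConfigError(f"table has no column {col!r}")
        max_len = cfg.max_len_for(field)
        values = table.df[col].to_numpy()
        uniq, inverse = np.unique(values, return_inverse=True)
        enc = np.empty((len(uniq), max_len * 20), dtype=np.float32)
        for k, s in enumerate(uniq):
            if s == "":
                enc[k] = cfg.pad_value
            else:
                enc[k] = blosum_encode(s, max_len, cfg).ravel()
        blocks.append(enc[inverse])
    return np.concatenate(blocks, axis=1) if blocks else np.empty((len(table), 0), np.float32)


def read_mhc_pseudo_map(path) -> dict[str, str]:
    """Two-column TSV (allele, pseudo-sequence) -> dict."""
    df = pd.read_csv(Path(path), sep="\t", header=None, names=["allele", "pseudo"], dtype=str)
    return dict(zip(df["allele"].str.strip(), df["pseudo"].str.strip()))


def attach_pseudo_sequence(
    table: SampleTable,
    mhc_map: dict[str, str],
    drop_missing: bool = False,
) -> tuple[SampleTable, int]:
    """Add a ``pseudo`` column holding each row's MHC pseudo-sequence.

    Class I and II alleles are treated identically — the map is the only
    authority. Rows whose allele is absent from the map are dropped (and
    counted) when ``drop_missing`` is set, otherwise raise.

    Returns (table_with_pseudo, n_dropped).
    """
    validated = {k: validate_sequence(v) for k, v in mhc_map.items()}
    alleles = table.df["mhc"]
    mapped = alleles.map(validated)
    missing = mapped.isna() & (alleles != "")
    missing |= alleles == ""
    n_missing = int(missing.sum())
    if n_missing and not drop_missing:
        bad = sorted(set(alleles[missing]))[:5]
        raise UnknownAlleleError(f"alleles without pseudo-sequence: {bad}")
    df = table.df[~missing.values].copy()
    df["pseudo"] = mapped[~missing.values].values
    return table.with_df(df), n_missing
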