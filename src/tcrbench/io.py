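"""CSV/TSV readers and writers for sample tables.

The on-disk schema is the canonical column set of :mod:`tcrbench.types`
(comma-separated by default, tab-separated for ``.tsv``; UTF-8; header
mandatory). Missing optional values serialise as empty cells. Extra columns
round-trip untouched.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import pandas as pd

from .exceptions import MissingColumnError, TcrBenchError
from .sequences import validate_sequence
from .types import PEP_CDR3B, SampleTable, Setting


@dataclass
class ReadReport:
    """Summary of a read: how many rows were dropped and why."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    drop_reasons: Counter = field(default_factory=Counter)


def _sep_for(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_samples(
    path,
    setting: Setting = PEP_CDR3B,
    *,
    sep: Optional[str] = None,
    cdr3_transform: Optional[Callable[[str], str]] = None,
) -> tuple[SampleTable, ReadReport]:
    """Read a sample table, validating sequences row by row.

    Rows whose peptide/CDR3 sequences fail validation are dropped and counted
    in the returned :class:`ReadReport` rather than aborting the read — source
    exports routinely contain a few malformed rows.

    Parameters
    ----------
    path
        CSV (or TSV, sniffed by extension) file with a header row.
    setting
        Identity declaration; its fields plus ``label`` must be present.
    cdr3_transform
        Optional hook applied to CDR3α/β strings *before* validation
        (e.g. a trimming/homogenisation rule). Off by default.

    Raises
    ------
    MissingColumnError
        If a required column is absent.
    FileNotFoundError
        If the path does not exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)

    required = set(setting.identity_fields) | {"label"}
    missing = required - set(df.columns)
    if missing:
        raise MissingColumnError(f"missing required column(s): {sorted(missing)}")

    report = ReadReport(n_read=len(df))
    keep_mask = []
    seq_cols = [c for c in ("peptide", "cdr3b", "cdr3a") if c in df.columns]
    for i in range(len(df)):
        ok = True
        for col in seq_cols:
            raw = df.iat[i, df.columns.get_loc(col)]
            if col == "cdr3a" and raw.strip() == "":
                continue  # optional field genuinely absent
            try:
                if cdr3_transform is not None and col in ("cdr3a", "cdr3b"):
                    raw = cdr3_transform(raw)
                df.iat[i, df.columns.get_loc(col)] = validate_sequence(raw, kind=col)
            except TcrBenchError as exc:
                report.drop_reasons[f"{col}:{type(exc).__name__}"] += 1
                ok = False
                break
        if ok:
            try:
                lab = int(df.iat[i, df.columns.get_loc("label")])
                if lab not in (0, 1):
                    raise ValueError
                df.iat[i, df.columns.get_loc("label")] = lab
            except ValueError:
                report.drop_reasons["label:invalid"] += 1
                ok = False
        keep_mask.append(ok)

    kept = df[pd.Series(keep_mask, index=df.index)]
    report.n_kept = len(kept)
    report.n_dropped = report.n_read - report.n_kept
    return SampleTable(kept, setting), report


def write_samples(table: SampleTable, path, *, sep: Optional[str] = None) -> None:
    """Write a table so that ``read_samples`` round-trips it field-for-field."""
    path = Path(path)
    df = table.df.copy()
    df.to_csv(
        path,
        sep=_sep_for(path, sep),
        index=False,
        quoting=csv.QUOTE_MINIMAL,
    )


def trim_cdr3_flanks(seq: str, prefix: str = "C", suffix: str = "F") -> str:
    """A simple, optional CDR3 homogenisation rule: strip one conserved
    flanking residue from each end when present (C... ...F by IMGT convention).

    Provided as an opt-in ``cdr3_transform`` hook; not applied by default and
    no particular convention is asserted by the package.
    """
    s = seq.strip().upper()
    if len(s) > 2 and s.startswith(prefix) and s.endswith(suffix):
        return s[1:-1]
    return s
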