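"""Core data model: binding samples, settings, and the pandas-backed table.

A *sample* is one (peptide, CDR3β[, CDR3α][, MHC][, V/(D)/J genes]) tuple with
a binary binding label. A *setting* declares which fields define tuple
identity — the two settings used throughout are (peptide, cdr3b) and
(peptide, cdr3b, cdr3a, mhc) — and drives deduplication and uniqueness checks.

``SampleTable`` wraps a :class:`pandas.DataFrame` with a canonical column set;
extra columns (e.g. a source database quality score) are carried through
untouched so generic column filters can use them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigError

#: Canonical column order for serialisation. ``label`` is int (0/1); every
#: other column is a string, with "" for a missing optional value.
CANONICAL_COLUMNS: list[str] = [
    "peptide",
    "cdr3b",
    "cdr3a",
    "mhc",
    "va",
    "ja",
    "vb",
    "db",
    "jb",
    "label",
    "source",
    "negative_origin",
]

_IDENTITY_UNIVERSE = ("peptide", "cdr3b", "cdr3a", "mhc")

#: Valid provenance tags for negatives. Positives carry "".
NEGATIVE_ORIGINS = ("", "NA", "RN")


@dataclass(frozen=True)
class Setting:
    """Declares which fields define tuple identity.

    Must contain ``peptide`` and ``cdr3b``; may add ``cdr3a`` and/or ``mhc``.
    """

    identity_fields: tuple[str, ...] = ("peptide", "cdr3b")

    def __post_init__(self):
        fields_ = tuple(self.identity_fields)
        object.__setattr__(self, "identity_fields", fields_)
        if "peptide" not in fields_ or "cdr3b" not in fields_:
            raise ConfigError("a setting must include peptide and cdr3b")
        unknown = set(fields_) - set(_IDENTITY_UNIVERSE)
        if unknown:
            raise ConfigError(f"unknown identity fields: {sorted(unknown)}")
        if len(set(fields_)) != len(fields_):
            raise ConfigError("duplicate identity fields")

    @property
    def name(self) -> str:
        return "paired_mhc" if set(self.identity_fields) >= {"cdr3a", "mhc"} else "pep_cdr3b"

    @classmethod
    def from_name(cls, name: str) -> "Setting":
        if name in ("pep_cdr3b", "peptide_cdr3b"):
            return PEP_CDR3B
        if name in ("paired_mhc", "peptide_cdr3b_cdr3a_mhc"):
            return PAIRED_MHC
        raise ConfigError(f"unknown setting name {name!r}")


#: The (peptide, CDR3β) setting.
PEP_CDR3B = Setting(("peptide", "cdr3b"))
#: The (peptide, CDR3β, CDR3α, MHC) setting.
PAIRED_MHC = Setting(("peptide", "cdr3b", "cdr3a", "mhc"))


@dataclass
class BindingSample:
    """One TCR-peptide/-pMHC tuple with a binary binding label."""

    peptide: str
    cdr3b: str
    label: int
    cdr3a: str = ""
    mhc: str = ""
    va: str = ""
    ja: str = ""
    vb: str = ""
    db: str = ""
    jb: str = ""
    source: str = ""
    negative_origin: str = ""

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ConfigError(f"label must be 0 or 1, got {self.label!r}")
        if self.negative_origin not in NEGATIVE_ORIGINS:
            raise ConfigError(f"negative_origin must be one of {NEGATIVE_ORIGINS}")
        if self.label == 1 and self.negative_origin != "":
            raise ConfigError("positive samples carry no negative_origin")


def _normalise_df(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with all canonical columns present and typed."""
    out = df.copy()
    for col in CANONICAL_COLUMNS:
        if col not in out.columns:
            out[col] = 0 if col == "label" else ""
    for col in CANONICAL_COLUMNS:
        if col == "label":
            out[col] = out[col].astype(int)
        else:
            out[col] = out[col].fillna("").astype(str)
    # canonical columns first, extras after, original extra order preserved
    extras = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    return out[CANONICAL_COLUMNS + extras].reset_index(drop=True)


@dataclass
class SampleTable:
    """An ordered collection of binding samples with a declared setting."""

    df: pd.DataFrame
    setting: Setting = field(default_factory=lambda: PEP_CDR3B)

    def __post_init__(self):
        self.df = _normalise_df(self.df)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_samples(
        cls, samples: Iterable[BindingSample], setting: Setting = PEP_CDR3B
    ) -> "SampleTable":
        rows = [vars(s) for s in samples]
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        return cls(df, setting)

    @classmethod
    def empty(cls, setting: Setting = PEP_CDR3B) -> "SampleTable":
        return cls(pd.DataFrame(columns=CANONICAL_COLUMNS), setting)

    # -- dunder -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[BindingSample]:
        for row in self.df[CANONICAL_COLUMNS].itertuples(index=False):
            yield BindingSample(**row._asdict())

    def __eq__(self, other) -> bool:
        if not isinstance(other, SampleTable):
            return NotImplemented
        if self.setting != other.setting:
            return False
        a = self.df[CANONICAL_COLUMNS].reset_index(drop=True)
        b = other.df[CANONICAL_COLUMNS].reset_index(drop=True)
        return a.equals(b)

    # -- helpers ----------------------------------------------------------
    def with_df(self, df: pd.DataFrame) -> "SampleTable":
        """New table with the same setting and a replacement frame."""
        return SampleTable(df, self.setting)

    def take(self, indices) -> "SampleTable":
        """Positional row selection (order of ``indices`` preserved)."""
        return self.with_df(self.df.iloc[np.asarray(indices, dtype=int)])

    def identity_key(self, with_label: bool = False) -> pd.Series:
        """One string key per row over the setting's identity fields."""
        cols = list(self.setting.identity_fields) + (["label"] if with_label else [])
        parts = [self.df[c].astype(str) for c in cols]
        key = parts[0]
        for p in parts[1:]:
            key = key + "|" + p
        return key

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    @property
    def n_pos(self) -> int:
        return int((self.df["label"] == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.df["label"] == 0).sum())

    def positives(self) -> "SampleTable":
        return self.with_df(self.df[self.df["label"] == 1])

    def negatives(self, origin: Optional[str] = None) -> "SampleTable":
        mask = self.df["label"] == 0
        if origin is not None:
            mask &= self.df["negative_origin"] == origin
        return self.with_df(self.df[mask])

    def negative_scope(self) -> str:
        """Which negative families the table contains: RN, NA, RN+NA or none."""
        origins = set(self.df.loc[self.df["label"] == 0, "negative_origin"])
        has_rn = "RN" in origins
        has_na = bool(origins - {"RN"})  # NA or unknown-origin assay negatives
        if has_rn and has_na:
            return "RN+NA"
        if has_rn:
            return "RN"
        if has_na:
            return "NA"
        return "none"


def concat_tables(tables: Iterable[SampleTable], setting: Optional[Setting] = None) -> SampleTable:
    """Concatenate tables row-wise; the first table's setting wins by default."""
    tables = list(tables)
    if not tables:
        raise ConfigError("need at least one table to concatenate")
    setting = setting or tables[0].setting
    df = pd.concat([t.df for t in tables], ignore_index=True, sort=False)
    return SampleTable(df, setting)


__all__ = [
    "BindingSample",
    "SampleTable",
    "Setting",
    "PEP_CDR3B",
    "PAIRED_MHC",
    "CANONICAL_COLUMNS",
    "concat_tables",
]
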