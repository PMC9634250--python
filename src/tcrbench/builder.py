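"""Benchmark dataset assembly.

Pipeline, in the order the dataset is built: pool positive and assay-negative
(NA) samples, filter by sequence length, deduplicate per setting, then generate
randomised-mismatch (RN) negatives by recombining components of the surviving
positive tuples.

RN negatives pair the peptide (or pMHC complex, when an MHC allele is present)
of one positive row with CDR3 sequences drawn from other positive rows. Any
recombination that shares its (peptide, CDR3β) with a positive is discarded —
that pair might genuinely bind. RN negatives are *presumed* non-binding; a
small false-negative rate is inherent to the construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigError, EmptyPositivesError, MissingFieldError
from .types import PEP_CDR3B, SampleTable, Setting, concat_tables


@dataclass(frozen=True)
class LengthFilterConfig:
    """Sequence-length bounds.

    ``peptide_max`` is an exclusive upper bound (keep ``len < peptide_max``);
    the CDR3 bounds are inclusive ranges. CDR3α bounds only apply to rows where
    the field is populated.
    """

    peptide_max: int = 16
    cdr3a_min: int = 7
    cdr3a_max: int = 21
    cdr3b_min: int = 9
    cdr3b_max: int = 23

    def __post_init__(self):
        if min(self.peptide_max, self.cdr3a_min, self.cdr3b_min) <= 0:
            raise ConfigError("length bounds must be positive")
        if self.cdr3a_min > self.cdr3a_max or self.cdr3b_min > self.cdr3b_max:
            raise ConfigError("min length exceeds max length")


@dataclass(frozen=True)
class RNConfig:
    """Randomised-negative generation parameters.

    ratio
        Negatives per positive (target count = round(ratio * n_positives)).
    pairing_mode
        "joint": the whole TCR block (cdr3a, cdr3b and gene alleles) is taken
        from one donor row, preserving real chain pairing. "independent": the
        β block and α block come from independently drawn donors.
    """

    ratio: float = 2.0
    seed: int = 0
    pairing_mode: str = "joint"
    max_draw_factor: int = 50  # rejection-sampling cap, in multiples of target

    def __post_init__(self):
        if self.ratio <= 0:
            raise ConfigError("ratio must be > 0")
        if self.pairing_mode not in ("joint", "independent"):
            raise ConfigError("pairing_mode must be 'joint' or 'independent'")


@dataclass
class DedupReport:
    n_in: int = 0
    n_out: int = 0
    n_duplicates_removed: int = 0
    n_conflict_keys: int = 0  # identity keys observed with both labels
    conflict_policy: str = "drop"


@dataclass
class RNReport:
    target: int = 0
    n_generated: int = 0
    shortfall: bool = False


@dataclass
class BuildReport:
    """Counts from the full assembly pipeline (one entry per stage)."""

    n_input: int = 0
    n_after_length_filter: int = 0
    dedup: DedupReport = field(default_factory=DedupReport)
    rn: Optional[RNReport] = None
    n_final: int = 0

    def to_dict(self) -> dict:
        d = {
            "n_input": self.n_input,
            "n_after_length_filter": self.n_after_length_filter,
            "n_duplicates_removed": self.dedup.n_duplicates_removed,
            "n_conflict_keys": self.dedup.n_conflict_keys,
            "conflict_policy": self.dedup.conflict_policy,
            "n_final": self.n_final,
        }
        if self.rn is not None:
            d.update(
                rn_target=self.rn.target,
                rn_generated=self.rn.n_generated,
                rn_shortfall=self.rn.shortfall,
            )
        return d


# ---------------------------------------------------------------------------


def filter_by_length(table: SampleTable, cfg: LengthFilterConfig = LengthFilterConfig()) -> SampleTable:
    """Keep rows whose sequences fall within the configured length bounds.

    Order-preserving; rows with an empty CDR3α are not subject to the α bounds.
    """
    df = table.df
    pep_len = df["peptide"].str.len()
    b_len = df["cdr3b"].str.len()
    a_len = df["cdr3a"].str.len()
    mask = (pep_len < cfg.peptide_max) & (b_len >= cfg.cdr3b_min) & (b_len <= cfg.cdr3b_max)
    has_a = a_len > 0
    mask &= ~has_a | ((a_len >= cfg.cdr3a_min) & (a_len <= cfg.cdr3a_max))
    return table.with_df(df[mask])


def filter_by_column(table: SampleTable, column: str, min_value: float) -> SampleTable:
    """Generic numeric column filter (e.g. a source quality score >= 1).

    Rows whose value is missing or non-numeric are dropped.
    """
    if column not in table.df.columns:
        raise MissingFieldError(column)
    vals = pd.to_numeric(table.df[column], errors="coerce")
    return table.with_df(table.df[vals >= min_value])


def deduplicate(
    table: SampleTable,
    setting: Optional[Setting] = None,
    conflict_policy: str = "drop",
) -> tuple[SampleTable, DedupReport]:
    """Drop duplicate rows under (identity fields, label), keeping the first.

    Identity keys that occur with *both* labels are contradictions between
    sources; ``conflict_policy`` decides their fate:

    - ``"drop"`` (default): remove every row of a conflicted key;
    - ``"keep_positive"``: keep the (deduplicated) positive row;
    - ``"keep_first"``: keep whichever label appeared first.
    """
    if conflict_policy not in ("drop", "keep_positive", "keep_first"):
        raise ConfigError(f"unknown conflict_policy {conflict_policy!r}")
    setting = setting or table.setting
    work = SampleTable(table.df, setting)
    report = DedupReport(n_in=len(work), conflict_policy=conflict_policy)
    if len(work) == 0:
        return work, report

    key = work.identity_key(with_label=False)
    key_label = key + "|" + work.df["label"].astype(str)
    first_of_pair = ~key_label.duplicated(keep="first")
    report.n_duplicates_removed = int((~first_of_pair).sum())
    df = work.df[first_of_pair]
    key = key[first_of_pair]

    labels_per_key = df.groupby(key.values, sort=False)["label"].nunique()
    conflicted = set(labels_per_key[labels_per_key > 1].index)
    report.n_conflict_keys = len(conflicted)
    if conflicted:
        in_conflict = key.isin(conflicted)
        if conflict_policy == "drop":
            df = df[~in_conflict.values]
        elif conflict_policy == "keep_positive":
            df = df[(~in_conflict.values) | (df["label"] == 1)]
        else:  # keep_first
            keep = ~key.duplicated(keep="first")
            df = df[(~in_conflict.values) | keep.values]
    out = SampleTable(df, setting)
    report.n_out = len(out)
    return out, report


def generate_rn_negatives(
    positives: SampleTable, cfg: RNConfig = RNConfig()
) -> tuple[SampleTable, RNReport]:
    """Generate presumed-non-binding samples by random recombination.

    Each negative takes its peptide block (peptide plus MHC, preserving the
    pMHC complex) from a positive *row* — so frequent epitopes receive
    proportionally many negatives — and its TCR block from the positives'
    unique TCR clonotypes, per ``cfg.pairing_mode``. TCR donors are the
    *unique* (CDR3α, CDR3β, gene) blocks, not rows: a clonotype is one
    receptor however many entries it has, and drawing clonotypes uniformly
    keeps a CDR3's appearance rate among negatives independent of how many
    peptides it binds. Candidates sharing (peptide, cdr3b) with any positive
    are rejected; output rows are unique under the table's setting. Sampling
    is with replacement over donors, rejection-filtered, and capped at
    ``cfg.max_draw_factor`` x target draws before declaring a shortfall.

    Deterministic for a fixed seed and input.
    """
    n = len(positives)
    if n == 0:
        raise EmptyPositivesError("cannot generate RN negatives from zero positives")
    if not (positives.df["label"] == 1).all():
        raise ConfigError("RN generation expects an all-positive table")

    rng = np.random.default_rng(cfg.seed)
    target = int(round(cfg.ratio * n))
    report = RNReport(target=target)

    df = positives.df.reset_index(drop=True)
    forbidden = set(zip(df["peptide"], df["cdr3b"]))
    identity_fields = list(positives.setting.identity_fields)

    pep_block = ["peptide", "mhc"]
    beta_block = ["cdr3b", "vb", "db", "jb"]
    alpha_block = ["cdr3a", "va", "ja"]
    tcr_pool = df[beta_block + alpha_block].drop_duplicates().reset_index(drop=True)
    beta_pool = df[beta_block].drop_duplicates().reset_index(drop=True)
    alpha_pool = df[alpha_block].drop_duplicates().reset_index(drop=True)

    seen: set[tuple] = set()
    chunks: list[pd.DataFrame] = []
    n_kept = 0
    draws_left = cfg.max_draw_factor * max(target, 1)
    while n_kept < target and draws_left > 0:
        m = min(max(2 * (target - n_kept), 64), draws_left)
        draws_left -= m
        pep_idx = rng.integers(0, n, size=m)
        cand = df.loc[pep_idx, pep_block].reset_index(drop=True)
        if cfg.pairing_mode == "joint":
            tcr_idx = rng.integers(0, len(tcr_pool), size=m)
            cand = pd.concat([cand, tcr_pool.loc[tcr_idx].reset_index(drop=True)], axis=1)
        else:
            beta_idx = rng.integers(0, len(beta_pool), size=m)
            alpha_idx = rng.integers(0, len(alpha_pool), size=m)
            cand = pd.concat(
                [
                    cand,
                    beta_pool.loc[beta_idx].reset_index(drop=True),
                    alpha_pool.loc[alpha_idx].reset_index(drop=True),
                ],
                axis=1,
            )
        cand["label"] = 0
        cand["source"] = "RN"
        cand["negative_origin"] = "RN"
        keep_rows = []
        for row in cand.itertuples(index=False):
            rd = row._asdict()
            if (rd["peptide"], rd["cdr3b"]) in forbidden:
                continue
            ident = tuple(rd[f] for f in identity_fields)
            if ident in seen:
                continue
            seen.add(ident)
            keep_rows.append(rd)
            n_kept += 1
            if n_kept >= target:
                break
        if keep_rows:
            chunks.append(pd.DataFrame(keep_rows))

    if chunks:
        out_df = pd.concat(chunks, ignore_index=True)
    else:
        out_df = pd.DataFrame(columns=["peptide", "cdr3b", "label"])
    report.n_generated = len(out_df)
    report.shortfall = report.n_generated < target
    return SampleTable(out_df, positives.setting), report


def assemble_dataset(
    positives: SampleTable,
    na_negatives: Optional[SampleTable] = None,
    rn_cfg: Optional[RNConfig] = None,
    filter_cfg: LengthFilterConfig = LengthFilterConfig(),
    setting: Setting = PEP_CDR3B,
    conflict_policy: str = "drop",
) -> tuple[SampleTable, BuildReport]:
    """Run the full assembly pipeline.

    Order: concatenate positives and NA negatives -> length filter ->
    per-setting deduplication -> RN generation on the filtered, deduplicated
    positives (so the 2x target counts post-filter positives) -> final
    deduplication of the combined table.

    The output's ``negative_origin`` column makes the NA-only, RN-only and
    NA+RN negative subsets recoverable.
    """
    report = BuildReport()
    pos = SampleTable(positives.df, setting)
    if not (pos.df["label"] == 1).all():
        raise ConfigError("positives table contains non-positive rows")
    parts = [pos]
    if na_negatives is not None and len(na_negatives) > 0:
        na = SampleTable(na_negatives.df, setting)
        if not (na.df["label"] == 0).all():
            raise ConfigError("na_negatives table contains non-negative rows")
        na_df = na.df.copy()
        na_df.loc[na_df["negative_origin"] == "", "negative_origin"] = "NA"
        parts.append(SampleTable(na_df, setting))
    table = concat_tables(parts, setting)
    report.n_input = len(table)

    table = filter_by_length(table, filter_cfg)
    report.n_after_length_filter = len(table)

    table, report.dedup = deduplicate(table, setting, conflict_policy)

    if rn_cfg is not None:
        pos_clean = table.positives()
        rn_table, report.rn = generate_rn_negatives(pos_clean, rn_cfg)
        table = concat_tables([table, rn_table], setting)
        table, _ = deduplicate(table, setting, conflict_policy)

    report.n_final = len(table)
    return table, report
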