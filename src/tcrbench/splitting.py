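"""Random and hard train/test splits, plus split audits.

The *random split* (RS) samples test rows uniformly without replacement. It
guarantees that test *tuples* are unseen, but test peptides and CDR3s usually
also occur in training rows paired with other partners — the leakage channel
this package exists to expose.

The *hard split* (HS) groups by peptide: it samples peptides without
replacement from the eligible set P_{l,u} (peptides occurring in at least l
and at most u tuples), assigns all of each sampled peptide's rows to the test
set, and stops at the first iteration where the test set reaches the minimum
test fraction. Test peptides are therefore never observed at training time;
test TCRs may be (by design — only the peptide is grouped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .exceptions import ConfigError, NoEligiblePeptidesError
from .types import SampleTable


@dataclass(frozen=True)
class HardSplitConfig:
    """Hard-split parameters.

    min_test_frac
        The test budget is a *minimum*: the loop stops at the first peptide
        whose inclusion reaches it, so the achieved fraction can exceed it.
    l, u
        Inclusive bounds on per-peptide tuple counts for eligibility.
        Reference values: 500/10,000 for the (peptide, cdr3b) setting and
        100/5,000 for the paired+MHC setting.
    """

    min_test_frac: float = 0.15
    l: int = 500
    u: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_test_frac < 1):
            raise ConfigError("min_test_frac must be in (0, 1)")
        if not (1 <= self.l <= self.u):
            raise ConfigError("need 1 <= l <= u")


@dataclass
class SplitResult:
    """Train/test partition with full provenance for reproduction."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    test_peptides: list[str]
    method: str  # "RS" or "HS"
    negative_scope: str
    seed: int
    config: dict = field(default_factory=dict)
    underfilled: bool = False

    @property
    def test_fraction(self) -> float:
        n = len(self.train_indices) + len(self.test_indices)
        return len(self.test_indices) / n if n else 0.0


@dataclass
class SplitAudit:
    """Leakage audit of a split.

    ``n_shared_peptides`` must be 0 for any hard split; the CDR3 overlap
    counts are informational (the hard split deliberately allows them).
    """

    n_shared_peptides: int
    shared_peptides: list[str]
    n_shared_cdr3b: int
    n_shared_cdr3a: int
    test_fraction: float
    per_test_peptide: pd.DataFrame  # columns: peptide, n_pos, n_neg


def random_split(table: SampleTable, test_frac: float = 0.2, seed: int = 0) -> SplitResult:
    """Uniform split: round(test_frac * n) test rows, sampled without
    replacement; deterministic per seed."""
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_test = int(round(test_frac * n))
    if n_test == 0 or n_test == n:
        raise ValueError(f"test_frac={test_frac} yields an empty train or test set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = np.sort(perm[:n_test])
    train = np.sort(perm[n_test:])
    return SplitResult(
        train_indices=train,
        test_indices=test,
        test_peptides=[],
        method="RS",
        negative_scope=table.negative_scope(),
        seed=seed,
        config={"test_frac": test_frac},
    )


def eligible_test_peptides(table: SampleTable, l: int, u: float) -> set[str]:
    """P_{l,u}: peptides observed in at least l and at most u rows."""
    counts = table.df["peptide"].value_counts()
    return set(counts[(counts >= l) & (counts <= u)].index)


def hard_split(table: SampleTable, cfg: HardSplitConfig) -> SplitResult:
    """Group-by-peptide split with a minimum test budget.

    Eligible peptides are materialised in lexicographic order and shuffled by
    the seeded generator, so results are platform-independent. If P_{l,u} is
    exhausted before the budget is met, the accumulated test set is returned
    with ``underfilled=True``.
    """
    n = len(table)
    eligible = sorted(eligible_test_peptides(table, cfg.l, cfg.u))
    if not eligible:
        raise NoEligiblePeptidesError(
            f"no peptide occurs between l={cfg.l} and u={cfg.u} times"
        )
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(eligible))
    budget = cfg.min_test_frac * n

    peptide_col = table.df["peptide"]
    chosen: list[str] = []
    n_test = 0
    underfilled = True
    for i in order:
        pep = eligible[i]
        chosen.append(pep)
        n_test += int((peptide_col == pep).sum())
        if n_test >= budget:
            underfilled = False
            break

    test_mask = peptide_col.isin(chosen).to_numpy()
    test = np.flatnonzero(test_mask)
    train = np.flatnonzero(~test_mask)
    return SplitResult(
        train_indices=train,
        test_indices=test,
        test_peptides=chosen,
        method="HS",
        negative_scope=table.negative_scope(),
        seed=cfg.seed,
        config={"min_test_frac": cfg.min_test_frac, "l": cfg.l, "u": cfg.u},
        underfilled=underfilled,
    )


def audit_split(table: SampleTable, split: SplitResult) -> SplitAudit:
    """Quantify peptide/CDR3 sharing between the two sides of a split."""
    n = len(table)
    all_idx = np.concatenate([split.train_indices, split.test_indices])
    if len(all_idx) != n or (np.sort(all_idx) != np.arange(n)).any():
        raise IndexError("split indices do not partition the table")

    train_df = table.df.iloc[split.train_indices]
    test_df = table.df.iloc[split.test_indices]

    def shared(col: str) -> set[str]:
        a = set(train_df[col]) - {""}
        b = set(test_df[col]) - {""}
        return a & b

    shared_pep = shared("peptide")
    per_pep = (
        test_df.groupby("peptide")["label"]
        .agg(n_pos=lambda s: int((s == 1).sum()), n_neg=lambda s: int((s == 0).sum()))
        .reset_index()
        .sort_values("peptide", ignore_index=True)
        if len(test_df)
        else pd.DataFrame(columns=["peptide", "n_pos", "n_neg"])
    )
    return SplitAudit(
        n_shared_peptides=len(shared_pep),
        shared_peptides=sorted(shared_pep),
        n_shared_cdr3b=len(shared("cdr3b")),
        n_shared_cdr3a=len(shared("cdr3a")),
        test_fraction=len(split.test_indices) / n if n else 0.0,
        per_test_peptide=per_pep,
    )
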