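"""Leakage diagnostics: class histograms, disjointness, memorization oracle.

The central observation these tools quantify: when every CDR3 sequence occurs
in only one class (binding xor non-binding — the situation with assay-derived
negatives), a classifier can reach near-perfect random-split test performance
by memorizing CDR3 identities while ignoring the peptide entirely. The
*memorization oracle* makes that ceiling executable: it scores a sample purely
from its CDR3's training-set label frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyHistogramError, MissingFieldError
from .types import SampleTable

_HISTOGRAM_FIELDS = ("peptide", "cdr3b", "cdr3a")


@dataclass
class ClassHistogram:
    """Per-unique-sequence positive/negative occurrence counts for one field."""

    field: str
    entries: dict[str, tuple[int, int]]  # sequence -> (pos_count, neg_count)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        """Sorted by total count descending — the usual rank-frequency view."""
        df = pd.DataFrame(
            [(s, p, n) for s, (p, n) in self.entries.items()],
            columns=["sequence", "pos_count", "neg_count"],
        )
        df["total"] = df["pos_count"] + df["neg_count"]
        return df.sort_values(["total", "sequence"], ascending=[False, True], ignore_index=True)


def class_histogram(table: SampleTable, field: str) -> ClassHistogram:
    """Count positive and negative occurrences of each unique sequence.

    Rows with an empty value for ``field`` are excluded (an absent optional
    field is not a sequence).
    """
    if field not in _HISTOGRAM_FIELDS:
        raise MissingFieldError(f"field must be one of {_HISTOGRAM_FIELDS}, got {field!r}")
    df = table.df[table.df[field] != ""]
    entries: dict[str, tuple[int, int]] = {}
    if len(df):
        grouped = df.groupby(field)["label"].agg(
            pos=lambda s: int((s == 1).sum()), neg=lambda s: int((s == 0).sum())
        )
        entries = {seq: (int(r.pos), int(r.neg)) for seq, r in grouped.iterrows()}
    return ClassHistogram(field=field, entries=entries)


def disjointness_fraction(hist: ClassHistogram) -> float:
    """Fraction of unique sequences seen in BOTH classes.

    0.0 means the class histograms are fully disjoint — the memorization
    regime; values > 0 indicate sequences with mixed labels (typical of
    recombination-generated negatives, which reuse positive CDR3s).
    """
    if len(hist) == 0:
        raise EmptyHistogramError("histogram has no entries")
    mixed = sum(1 for p, n in hist.entries.values() if p > 0 and n > 0)
    return mixed / len(hist)


def memorization_oracle(
    train: SampleTable,
    test: SampleTable,
    field: str = "cdr3b",
    smoothing: float = 1.0,
) -> np.ndarray:
    """Score test rows from training-set label frequencies of one field.

    score(row) = (pos_count(seq) + a*pi) / (total_count(seq) + a), where pi is
    the training positive rate and a the pseudo-count; an unseen sequence
    scores exactly pi. The peptide column is never read — by design, so the
    oracle's performance is attributable to sequence memorization alone.

    Returns one score in [0, 1] per test row, order-aligned.
    """
    if len(train) == 0:
        raise ValueError("train table is empty")
    if field not in _HISTOGRAM_FIELDS:
        raise MissingFieldError(f"field must be one of {_HISTOGRAM_FIELDS}, got {field!r}")
    a = float(smoothing)
    pi = train.n_pos / len(train)
    hist = class_histogram(train, field)
    scores = np.empty(len(test), dtype=float)
    for i, seq in enumerate(test.df[field].to_numpy()):
        pos, neg = hist.entries.get(seq, (0, 0))
        tot = pos + neg
        scores[i] = (pos + a * pi) / (tot + a) if (tot + a) > 0 else pi
    return scores
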