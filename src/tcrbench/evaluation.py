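"""Metric suite: AUROC/AUPR/F1/precision/recall/accuracy, per-peptide AUROC,
and aggregation over repeated splits.

Conventions: AUROC is the Mann-Whitney probability that a random positive
outscores a random negative, ties counted 1/2 (what ``roc_auc_score``
computes); AUPR is the step-wise, non-interpolated integral (what
``average_precision_score`` computes); thresholded metrics use a fixed 0.5
cut. Aggregates report the arithmetic mean and the *population* standard
deviation, with k recorded so the sample version can be recovered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .exceptions import EmptyListError, SingleClassError
from .types import SampleTable

_METRICS = ("auroc", "aupr", "f1", "precision", "recall", "accuracy")


@dataclass
class EvalReport:
    auroc: Optional[float]
    aupr: Optional[float]
    f1: float
    precision: float
    recall: float
    accuracy: float
    n_pos: int
    n_neg: int
    threshold: float = 0.5
    per_peptide: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {m: getattr(self, m) for m in _METRICS}
        d.update(n_pos=self.n_pos, n_neg=self.n_neg, threshold=self.threshold)
        return d


@dataclass
class AggregateReport:
    mean: dict[str, float]
    std: dict[str, float]  # population (ddof=0)
    k: int


def compute_metrics(
    labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
    allow_single_class: bool = False,
) -> EvalReport:
    """Compute the full metric suite for one split.

    Rank metrics (AUROC, AUPR) require both classes; with
    ``allow_single_class=True`` they come back as None instead of raising,
    while the thresholded metrics are still computed.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    single = n_pos == 0 or n_neg == 0
    if single and not allow_single_class:
        raise SingleClassError("AUROC/AUPR need both classes present")

    pred = (s >= threshold).astype(int)
    report = EvalReport(
        auroc=None if single else float(roc_auc_score(y, s)),
        aupr=None if single else float(average_precision_score(y, s)),
        f1=float(f1_score(y, pred, zero_division=0)),
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        accuracy=float(accuracy_score(y, pred)),
        n_pos=n_pos,
        n_neg=n_neg,
        threshold=threshold,
    )
    return report


@dataclass
class PeptideAUROC:
    auroc: Optional[float]  # None when only one class is present
    n_pos: int
    n_neg: int


def peptide_specific_auroc(test: SampleTable, scores: Sequence[float]) -> dict[str, PeptideAUROC]:
    """AUROC within each test peptide's rows.

    No cross-peptide score pairs are compared, so the global AUROC generally
    differs from any average of these. Peptides with a single class present
    map to ``auroc=None`` and must be excluded from averages (use
    :func:`mean_peptide_auroc`).
    """
    s = np.asarray(scores, dtype=float)
    if len(s) != len(test):
        raise ValueError("scores must align with test rows")
    out: dict[str, PeptideAUROC] = {}
    df = test.df
    for pep, idx in df.groupby("peptide").groups.items():
        y = df.loc[idx, "label"].to_numpy()
        n_pos = int((y == 1).sum())
        n_neg = int((y == 0).sum())
        if n_pos == 0 or n_neg == 0:
            out[pep] = PeptideAUROC(None, n_pos, n_neg)
        else:
            pos = df.index.get_indexer(idx)
            out[pep] = PeptideAUROC(float(roc_auc_score(y, s[pos])), n_pos, n_neg)
    return out


def mean_peptide_auroc(per_peptide: dict[str, PeptideAUROC]) -> tuple[Optional[float], int]:
    """Unweighted mean over peptides with a computable AUROC; (mean, n_used)."""
    vals = [v.auroc for v in per_peptide.values() if v.auroc is not None]
    return (float(np.mean(vals)) if vals else None, len(vals))


def aggregate_over_splits(reports: Sequence[EvalReport]) -> AggregateReport:
    """Mean and population std of each metric over repeated splits.

    Metrics that are None in any report (single-class rank metrics) are
    aggregated over the reports where they exist.
    """
    if not reports:
        raise EmptyListError("no reports to aggregate")
    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    for m in _METRICS:
        vals = [getattr(r, m) for r in reports if getattr(r, m) is not None]
        if vals:
            mean[m] = float(np.mean(vals))
            std[m] = float(np.std(vals))  # population, ddof=0
    return AggregateReport(mean=mean, std=std, k=len(reports))
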