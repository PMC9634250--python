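"""A small reference classifier with validation-AUROC model selection.

The scorer is a one-hidden-layer feed-forward network on flattened,
concatenated BLOSUM encodings plus (by default) a pairwise peptide x CDR3β
similarity map — the inner product between every peptide position's and every
CDR3β position's substitution-score vectors. The similarity map is the
standard inductive bias for interaction prediction: it expresses
residue-level complementarity between the two chains without reference to
residue identity, which is what allows a *pairing* rule learned on training
peptides to transfer to unseen ones. The raw flattened encodings, in turn,
let the model memorize sequence identities — the leakage channel the
benchmark measures.

The model is intentionally modest: minutes-scale CPU training. Its role is a
probe — any score it achieves under a random split but loses under a hard
split quantifies leakage-driven optimism, and the memorization oracle bounds
how much of its random-split score needs no peptide information at all.

Training protocol: an internal stratified validation split is carved from the
provided training table; after every epoch the validation AUROC is computed
and the weights of the best epoch (first epoch in case of ties) are the ones
returned. Early stopping on validation patience only shortens training — the
selected weights are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .encoding import EncodingConfig, encode_table
from .exceptions import ConfigError, SingleClassError
from .types import SampleTable


@dataclass(frozen=True)
class TrainConfig:
    """Training knobs.

    val_frac is the internal stratified validation fraction (selection is by
    validation AUROC, never by training loss). ``patience`` epochs without a
    new validation best stop training early; set to None to always run
    ``max_epochs``.
    """

    max_epochs: int = 1000
    val_frac: float = 0.2
    seed: int = 0
    hidden: int = 128
    lr: float = 1e-3
    batch_size: int = 256
    weight_decay: float = 1e-4
    patience: Optional[int] = 20
    feature_scale: float = 5.0  # raw BLOSUM scores are divided by this
    interaction_features: bool = True  # peptide x cdr3b similarity map

    def __post_init__(self):
        if not (0 < self.val_frac < 1):
            raise ConfigError("val_frac must be in (0, 1)")
        if self.max_epochs < 1 or self.hidden < 1:
            raise ConfigError("max_epochs and hidden must be >= 1")


@dataclass
class TrainHistory:
    val_auroc: list[float] = field(default_factory=list)
    best_epoch: int = -1  # 0-based
    n_epochs_run: int = 0


def build_features(
    table: SampleTable,
    fields: Sequence[str],
    enc: EncodingConfig,
    cfg: TrainConfig,
) -> np.ndarray:
    """Model input: scaled flattened encodings, plus the peptide x CDR3β
    similarity map when both fields are present and enabled."""
    X = encode_table(table, tuple(fields), enc) / cfg.feature_scale
    if cfg.interaction_features and "peptide" in fields and "cdr3b" in fields:
        offsets = {}
        pos = 0
        for f in fields:
            size = enc.max_len_for(f) * 20
            offsets[f] = (pos, pos + size)
            pos += size
        lp, lc = enc.max_len_for("peptide"), enc.max_len_for("cdr3b")
        Ep = X[:, offsets["peptide"][0] : offsets["peptide"][1]].reshape(-1, lp, 20)
        Ec = X[:, offsets["cdr3b"][0] : offsets["cdr3b"][1]].reshape(-1, lc, 20)
        # /4 keeps pairwise products on the same numeric footing as the raw
        # encodings; much smaller and the interaction pathway trains too
        # slowly to compete with sequence memorization
        sim = np.einsum("npk,nqk->npq", Ep, Ec, optimize=True) / 4.0
        X = np.concatenate([X, sim.reshape(len(X), -1).astype(np.float32)], axis=1)
    return X


class BaselineScorer:
    """Fitted feed-forward scorer; use :func:`predict` or ``.score_table``."""

    def __init__(self, weights, fields, enc: EncodingConfig, cfg: TrainConfig, history: TrainHistory):
        self.weights = weights  # (W1, b1, w2, b2) float32 arrays
        self.fields = tuple(fields)
        self.enc = enc
        self.cfg = cfg
        self.history = history

    def score_features(self, X: np.ndarray) -> np.ndarray:
        W1, b1, w2, b2 = self.weights
        h = np.maximum(X @ W1 + b1, 0.0)
        z = h @ w2 + b2
        return 1.0 / (1.0 + np.exp(-z.ravel()))

    def score_table(self, table: SampleTable) -> np.ndarray:
        if len(table) == 0:
            return np.empty(0, dtype=float)
        X = build_features(table, self.fields, self.enc, self.cfg)
        return self.score_features(X)


def _forward_backward(X, y, weights, grads):
    """BCE loss gradient for one minibatch; returns loss."""
    W1, b1, w2, b2 = weights
    h_pre = X @ W1 + b1
    h = np.maximum(h_pre, 0.0)
    z = h @ w2 + b2
    p = 1.0 / (1.0 + np.exp(-z.ravel()))
    m = len(y)
    dz = (p - y)[:, None] / m
    grads[2][:] = h.T @ dz
    grads[3][:] = dz.sum(axis=0)
    dh = dz @ w2.T
    dh[h_pre <= 0] = 0.0
    grads[0][:] = X.T @ dh
    grads[1][:] = dh.sum(axis=0)
    eps = 1e-12
    return float(-(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).mean())


def train_baseline(
    train: SampleTable,
    cfg: TrainConfig = TrainConfig(),
    enc: EncodingConfig = EncodingConfig(),
    fields: Sequence[str] = ("peptide", "cdr3b"),
) -> BaselineScorer:
    """Fit the baseline scorer with per-epoch validation-AUROC checkpointing.

    Deterministic for a fixed (table, cfg, enc): initialisation, the
    stratified validation split and minibatch shuffling all derive from
    ``cfg.seed``.
    """
    y_all = train.labels.astype(np.float32)
    if len(np.unique(y_all)) < 2:
        raise SingleClassError("training table must contain both classes")

    X_all = build_features(train, tuple(fields), enc, cfg)
    idx = np.arange(len(y_all))
    tr_idx, va_idx = train_test_split(
        idx, test_size=cfg.val_frac, stratify=y_all, random_state=cfg.seed % (2**32)
    )
    Xtr, ytr = X_all[tr_idx], y_all[tr_idx]
    Xva, yva = X_all[va_idx], y_all[va_idx]

    rng = np.random.default_rng(cfg.seed)
    d = X_all.shape[1]
    W1 = (rng.standard_normal((d, cfg.hidden)) * np.sqrt(2.0 / d)).astype(np.float32)
    b1 = np.zeros(cfg.hidden, dtype=np.float32)
    w2 = (rng.standard_normal((cfg.hidden, 1)) * np.sqrt(1.0 / cfg.hidden)).astype(np.float32)
    b2 = np.zeros(1, dtype=np.float32)
    weights = [W1, b1, w2, b2]
    grads = [np.zeros_like(w) for w in weights]
    m1 = [np.zeros_like(w) for w in weights]
    m2 = [np.zeros_like(w) for w in weights]

    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = TrainHistory()
    best_auroc = -np.inf
    best_weights = [w.copy() for w in weights]
    since_best = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(ytr))
        for start in range(0, len(ytr), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            _forward_backward(Xtr[batch], ytr[batch], weights, grads)
            t += 1
            lr_t = cfg.lr * np.sqrt(1 - beta2**t) / (1 - beta1**t)
            for k in range(4):
                g = grads[k] + cfg.weight_decay * weights[k]
                m1[k] = beta1 * m1[k] + (1 - beta1) * g
                m2[k] = beta2 * m2[k] + (1 - beta2) * g * g
                weights[k] -= (lr_t * m1[k] / (np.sqrt(m2[k]) + eps)).astype(np.float32)

        # validation AUROC for model selection
        h = np.maximum(Xva @ weights[0] + weights[1], 0.0)
        p = 1.0 / (1.0 + np.exp(-(h @ weights[2] + weights[3]).ravel()))
        auroc = float(roc_auc_score(yva, p))
        history.val_auroc.append(auroc)
        history.n_epochs_run = epoch + 1
        if auroc > best_auroc:  # strict: ties keep the earlier epoch
            best_auroc = auroc
            history.best_epoch = epoch
            best_weights = [w.copy() for w in weights]
            since_best = 0
        else:
            since_best += 1
            if cfg.patience is not None and since_best >= cfg.patience:
                break

    return BaselineScorer(best_weights, fields, enc, cfg, history)


def predict(scorer: BaselineScorer, table: SampleTable) -> np.ndarray:
    """One score in [0, 1] per row, order-aligned; inputs are not mutated."""
    return scorer.score_table(table)
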