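"""Frozen-encoder transfer learning: feature extraction, MLP head, 5-fold CV.

The pre-trained encoder acts purely as a feature extractor: its weights are
frozen, views are encoded in eval mode (deterministic) and [CLS]-pooled to
the polymer representation h. A single-hidden-layer MLP regression head
(hidden size equal to the input width, ReLU, dropout 0.1) is then trained on
h with AdamW (lr 1e-3, no weight decay) under an l2 loss, for at most 500
epochs with early stopping (monitor active after epoch 50, patience 50,
best-epoch weights restored). Performance is reported as held-out RMSE and
R² under seeded 5-fold cross-validation.

An enumeration stress test replaces every input SMILES with a randomized
rendering of the same molecule before feature extraction, probing the
representation's invariance to non-canonical input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold

from . import nn
from .encoder import EmbeddingMatrix, EncoderCheckpoint, weight_checksum
from .polymer_smiles import PolymerSmiles, enumerate_smiles

logger = logging.getLogger("polycontrast")


@dataclass
class TransferConfig:
    """Downstream-regression protocol parameters (frozen heuristics, untuned)."""

    hidden_size: int | None = None   # None -> equal to the input feature width
    head_dropout: float = 0.1
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    max_epochs: int = 500
    early_stop_start: int = 50
    patience: int = 50
    folds: int = 5
    seed: int = 0
    batch_size: int = 64           # minibatch size for head training

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if self.patience < 1:
            raise ValueError("patience must be at least 1")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def rmse(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Root-mean-square error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("y and yhat must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (SS_tot about mean(y))."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must be equal-length vectors of size >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for constant observations")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def extract_features(checkpoint: EncoderCheckpoint,
                     polymers: Sequence[PolymerSmiles],
                     batch_size: int = 256) -> EmbeddingMatrix:
    """Deterministic pooled representations h from a frozen encoder."""
    encoder = checkpoint.build_encoder()
    blocks: list[np.ndarray] = []
    for start in range(0, len(polymers), batch_size):
        chunk = list(polymers[start:start + batch_size])
        token_level, _ = encoder.encode_tensor(chunk, train_mode=False)
        blocks.append(token_level.data[:, 0, :])
    if not blocks:
        return EmbeddingMatrix(np.zeros((0, checkpoint.config.hidden_dim)), "pooled_h")
    return EmbeddingMatrix(np.vstack(blocks), "pooled_h")


# ---------------------------------------------------------------------------
# Regression head
# ---------------------------------------------------------------------------


class RegressionHead(nn.Module):
    """affine -> ReLU -> dropout -> affine(1)."""

    def __init__(self, in_dim: int, hidden: int, dropout_p: float,
                 rng: np.random.Generator):
        self.fc1 = nn.Linear(in_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, 1, rng)
        self.dropout_p = dropout_p

    def __call__(self, x: nn.Tensor, train: bool,
                 rng: np.random.Generator) -> nn.Tensor:
        h = nn.dropout(self.fc1(x).relu(), self.dropout_p, train, rng)
        return self.fc2(h).reshape(x.shape[0])


@dataclass
class FitRecord:
    best_epoch: int
    best_val_loss: float
    stopped_epoch: int


def fit_head(X: np.ndarray, y: np.ndarray, config: TransferConfig,
             rng: np.random.Generator, X_val: np.ndarray | None = None,
             y_val: np.ndarray | None = None) -> tuple[RegressionHead, FitRecord]:
    """Train the MLP head with full-batch AdamW and early stopping.

    Validation l2 loss (on ``X_val``; falls back to the training set when no
    validation split is supplied) is monitored from ``early_stop_start``
    onward; training stops after ``patience`` monitored epochs without
    improvement, and the best-epoch weights are restored.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0] or X.ndim != 2:
        raise ValueError("X must be (n, d) with one label per row")
    if X_val is None:
        X_val, y_val = X, y
    hidden = config.hidden_size or X.shape[1]
    head = RegressionHead(X.shape[1], hidden, config.head_dropout, rng)
    opt = nn.AdamW(head.parameters(), lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    Xv = nn.Tensor(np.asarray(X_val, dtype=float))
    yv = np.asarray(y_val, dtype=float)
    n = X.shape[0]
    bs = min(config.batch_size, n)

    best_loss = np.inf
    best_epoch = 0
    best_state = head.state_dict()
    stale = 0
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            pred = head(nn.Tensor(X[idx]), train=True, rng=rng)
            resid = pred - nn.Tensor(y[idx])
            loss = (resid * resid).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()

        val_pred = head(Xv, train=False, rng=rng).data
        val_loss = float(np.mean((val_pred - yv) ** 2))
        if val_loss < best_loss:
            best_loss = val_loss
            best_epoch = epoch
            best_state = head.state_dict()
            stale = 0
        elif epoch > config.early_stop_start:
            stale += 1
            if stale >= config.patience:
                break
    head.load_state_dict(best_state)
    return head, FitRecord(best_epoch=best_epoch, best_val_loss=best_loss,
                           stopped_epoch=epoch)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class TransferReport:
    """Per-fold held-out RMSE/R² plus arithmetic means and fold assignments."""

    fold_rmse: list
    fold_r2: list
    fold_assignments: list         # held-out index arrays, one per fold
    seed: int
    fit_records: list = field(default_factory=list)

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))

    def to_dict(self) -> dict:
        return {
            "fold_rmse": [float(v) for v in self.fold_rmse],
            "fold_r2": [float(v) for v in self.fold_r2],
            "mean_rmse": self.mean_rmse,
            "mean_r2": self.mean_r2,
            "fold_assignments": [list(map(int, idx)) for idx in self.fold_assignments],
            "seed": self.seed,
        }


def fold_splits(n: int, config: TransferConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffled K-fold partition (a disjoint cover of 0..n-1)."""
    kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    return [(tr, va) for tr, va in kf.split(np.arange(n))]


def cross_validate(features, y: Sequence[float],
                   config: TransferConfig) -> TransferReport:
    """K-fold CV of the MLP head on fixed features.

    ``features`` is an :class:`EmbeddingMatrix` or plain (n, d) array — e.g.
    encoder representations or raw structural descriptors. The held-out fold
    supplies both the early-stopping monitor and the reported metrics.

    Features and target are z-scored on each training fold before the head
    is fitted (the head's fixed learning rate presumes unit-scale inputs);
    predictions are mapped back to label units, so RMSE/R² are reported on
    the original scale.
    """
    X = np.asarray(getattr(features, "values", features), dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < config.folds:
        raise ValueError(f"need at least {config.folds} samples for {config.folds}-fold CV")
    report = TransferReport([], [], [], seed=config.seed)
    for fold_i, (tr, va) in enumerate(fold_splits(X.shape[0], config)):
        rng = np.random.default_rng(config.seed * 10007 + fold_i)
        x_mu, x_sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        x_sd[x_sd == 0.0] = 1.0
        y_mu, y_sd = y[tr].mean(), y[tr].std()
        if y_sd == 0.0:
            y_sd = 1.0
        Xs = (X - x_mu) / x_sd
        ys = (y - y_mu) / y_sd
        head, record = fit_head(Xs[tr], ys[tr], config, rng,
                                X_val=Xs[va], y_val=ys[va])
        pred = head(nn.Tensor(Xs[va]), train=False, rng=rng).data * y_sd + y_mu
        report.fold_rmse.append(rmse(y[va], pred))
        report.fold_r2.append(r_squared(y[va], pred))
        report.fold_assignments.append(va)
        report.fit_records.append(record)
    return report


def run_transfer(polymers: Sequence[PolymerSmiles], y: Sequence[float],
                 checkpoint: EncoderCheckpoint, config: TransferConfig,
                 enumerate_inputs: bool = False,
                 enum_seed: int = 0) -> TransferReport:
    """Full frozen-encoder protocol: extract h, then cross-validate the head.

    With ``enumerate_inputs`` every SMILES is replaced by an enumerated
    variant of the same molecule before encoding (robustness stress test);
    the encoder weights are verifiably untouched either way.
    """
    encoder = checkpoint.build_encoder()
    before = weight_checksum(encoder)
    inputs = list(polymers)
    if enumerate_inputs:
        enum_rng = np.random.default_rng(enum_seed)
        inputs = [enumerate_smiles(s, enum_rng) for s in inputs]
    features = extract_features(checkpoint, inputs)
    report = cross_validate(features, y, config)
    after = weight_checksum(checkpoint.build_encoder())
    if before != after:
        raise RuntimeError("frozen-encoder contract violated: weights changed")
    return report
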