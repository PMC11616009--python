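"""NT-Xent contrastive objective and the pre-training loop.

The normalised temperature-scaled cross-entropy (NT-Xent) loss for a
positive pair (i, j) in a batch of 2N views is

    l(i, j) = -log[ exp(sim(z_i, z_j)/tau) / sum_{k != i} exp(sim(z_i, z_k)/tau) ]

with sim(u, v) the cosine similarity and the sum running over the other
2N - 1 views (the 2(N-1) cross-anchor views act as implicit negatives).
The batch loss is the symmetrised mean over all 2N directed terms,
(1/2N) * sum_pairs [l(i, j) + l(j, i)].

Training follows the SimCLR recipe: fresh augmented views every epoch, a
projector on top of the pooled representation, AdamW with global
gradient-norm clipping. Defaults mirror the published regime (tau = 0.05,
lr 1e-5, max grad norm 1.0); a desk-scale run from random init typically
wants a larger learning rate (see docs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .augmentations import AugmentationSpec, make_positive_pairs
from .encoder import (
    EncoderCheckpoint,
    PolymerEncoder,
    Projector,
    set_implicit_dropout,
)
from .polymer_smiles import PolymerSmiles, canonicalize

logger = logging.getLogger("polycontrast")


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def cosine_sim(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity u·v / (|u||v|); undefined for zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


def _check_tau(tau: float) -> None:
    if tau <= 0.0:
        raise ValueError(f"temperature must be positive, got {tau}")


def nt_xent_pair_loss(Z: np.ndarray, i: int, j: int, tau: float = 0.05) -> float:
    """Directed NT-Xent loss l(i, j) for one positive pair in a 2N-row batch."""
    _check_tau(tau)
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 views in the batch")
    if i == j:
        raise ValueError("a positive pair needs two distinct rows")
    Zn = Z / np.linalg.norm(Z, axis=1, keepdims=True)
    sims = Zn @ Zn[i] / tau                     # sim(z_i, z_k)/tau for all k
    others = np.delete(sims, i)                 # indicator skips k == i
    shift = others.max()
    log_denom = shift + math.log(np.exp(others - shift).sum())
    return float(log_denom - sims[j])


def nt_xent_loss_tensor(Z: nn.Tensor, pairing: Sequence[tuple[int, int]],
                        tau: float = 0.05) -> nn.Tensor:
    """Differentiable symmetrised NT-Xent over a (2N, d) projection batch."""
    _check_tau(tau)
    n2 = Z.shape[0]
    norms = (Z * Z).sum(axis=1, keepdims=True).pow(0.5)
    Zn = Z / norms
    S = (Zn @ Zn.swapaxes(0, 1)) * (1.0 / tau)
    S = S + nn.Tensor(np.where(np.eye(n2, dtype=bool), -1e9, 0.0))  # skip k == i
    lse = nn.logsumexp_last(S).reshape(n2)
    rows = np.array([p[0] for p in pairing] + [p[1] for p in pairing])
    cols = np.array([p[1] for p in pairing] + [p[0] for p in pairing])
    return (lse[rows] - S[(rows, cols)]).mean()


def nt_xent_batch_loss(Z, pairing: Sequence[tuple[int, int]],
                       tau: float = 0.05) -> float:
    """Symmetrised batch NT-Xent: mean of l(i,j) and l(j,i) over all N pairs.

    Vectorised float64 computation (the training loop uses the
    differentiable float32 twin :func:`nt_xent_loss_tensor`).
    """
    _check_tau(tau)
    Z = np.asarray(getattr(Z, "values", Z), dtype=np.float64)
    n2 = Z.shape[0]
    pairing = list(pairing)
    if n2 != 2 * len(pairing):
        raise ValueError("batch must hold 2N views for N positive pairs")
    Zn = Z / np.linalg.norm(Z, axis=1, keepdims=True)
    S = (Zn @ Zn.T) / tau
    np.fill_diagonal(S, -np.inf)                # indicator: skip k == i
    shift = S.max(axis=1, keepdims=True)
    lse = (shift + np.log(np.exp(S - shift).sum(axis=1, keepdims=True))).ravel()
    rows = np.array([p[0] for p in pairing] + [p[1] for p in pairing])
    cols = np.array([p[1] for p in pairing] + [p[0] for p in pairing])
    return float(np.mean(lse[rows] - S[rows, cols]))


# ---------------------------------------------------------------------------
# Configuration & trajectory
# ---------------------------------------------------------------------------


def checkpoint_schedule(early_every: float = 0.02, early_until: float = 0.20,
                        late_every: float = 0.20) -> list[float]:
    """Epoch-fraction checkpoint cadence: dense early, sparse late.

    Default: every 2% of total epochs for the first 20%, then every 20%
    (fractions 0.02 … 0.20 and 0.40 … 1.00; 14 checkpoints).
    """
    early = np.round(np.arange(early_every, early_until + 1e-9, early_every), 10)
    late = np.round(np.arange(early_until + late_every, 1.0 + 1e-9, late_every), 10)
    return [float(f) for f in np.concatenate([early, late])]


@dataclass
class ContrastiveConfig:
    """Hyperparameters of contrastive pre-training."""

    temperature: float = 0.05
    learning_rate: float = 1e-5
    weight_decay: float = 0.0
    max_grad_norm: float = 1.0
    batch_size: int = 32           # anchors per batch (N); views per batch = 2N
    epochs: int = 10
    seed: int = 0
    checkpoint_cadence: list = field(default_factory=checkpoint_schedule)
    canonicalize_first: bool = True
    mixed_precision: bool = False  # accepted for config compatibility; the
                                   # float64 engine ignores it with a warning

    def __post_init__(self):
        if self.temperature <= 0.0:
            raise ValueError("temperature must be positive")
        if self.max_grad_norm <= 0.0:
            raise ValueError("max_grad_norm must be positive")


@dataclass
class TrainTrajectory:
    """Per-step losses and checkpoint snapshots of one pre-training run."""

    step_losses: list = field(default_factory=list)       # (epoch_fraction, loss)
    grad_norms: list = field(default_factory=list)        # pre-clip global norms
    checkpoints: list = field(default_factory=list)       # (fraction, EncoderCheckpoint)
    initial_checkpoint: EncoderCheckpoint | None = None

    @property
    def losses(self) -> list[float]:
        return [loss for _, loss in self.step_losses]

    def epoch_mean_losses(self, steps_per_epoch: int) -> list[float]:
        vals = self.losses
        return [float(np.mean(vals[i:i + steps_per_epoch]))
                for i in range(0, len(vals), steps_per_epoch)]


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def train_contrastive(corpus: Sequence[PolymerSmiles], spec_a: AugmentationSpec,
                      spec_b: AugmentationSpec, encoder: PolymerEncoder,
                      projector: Projector, config: ContrastiveConfig,
                      checkpoint_dir: str | Path | None = None,
                      ) -> tuple[EncoderCheckpoint, TrainTrajectory]:
    """Minimise NT-Xent over fresh positive-pair batches; fully seeded.

    Each step: build a positive-pair batch (re-augmented every epoch),
    encode in training mode, [CLS]-pool, project, compute the symmetrised
    NT-Xent, clip the global gradient norm and take an AdamW step.
    Checkpoints are captured at the epoch fractions in
    ``config.checkpoint_cadence``.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("pre-training corpus is empty")
    if spec_a.implicit_dropout != spec_b.implicit_dropout:
        raise ValueError("implicit dropout must be enabled or disabled for both branches")
    if config.mixed_precision:
        logger.warning("mixed precision is not supported by the float64 engine; ignoring")

    if config.canonicalize_first:
        corpus = [canonicalize(s) for s in corpus]

    set_implicit_dropout(encoder, spec_a.implicit_dropout)
    master = np.random.default_rng(config.seed)
    aug_rng = np.random.default_rng(master.integers(2**31))
    shuffle_rng = np.random.default_rng(master.integers(2**31))
    encoder.seed_dropout(int(master.integers(2**31)))

    params = list(encoder.parameters()) + list(projector.parameters())
    opt = nn.AdamW(params, lr=config.learning_rate,
                   weight_decay=config.weight_decay)

    n = len(corpus)
    steps_per_epoch = max(1, n // config.batch_size + (1 if n % config.batch_size >= 2 else 0))
    total_steps = steps_per_epoch * config.epochs
    ckpt_steps = {}
    for frac in sorted(config.checkpoint_cadence):
        step = min(total_steps, max(1, math.ceil(frac * total_steps)))
        ckpt_steps.setdefault(step, []).append(frac)

    traj = TrainTrajectory()
    traj.initial_checkpoint = EncoderCheckpoint.capture(encoder, projector,
                                                        epoch_fraction=0.0)
    ckpt_dir = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt_dir is not None:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
        traj.initial_checkpoint.save(ckpt_dir / "ckpt_f0.0000.npz")

    step = 0
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            anchors = [corpus[i] for i in order[start:start + config.batch_size]]
            if len(anchors) < 2:
                continue  # NT-Xent needs at least one negative
            batch = make_positive_pairs(anchors, spec_a, spec_b, aug_rng)
            token_level, _ = encoder.encode_tensor(batch.views, train_mode=True)
            h = encoder.pool_tensor(token_level)
            z = projector(h)
            loss = nt_xent_loss_tensor(z, batch.pairing, config.temperature)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite NT-Xent loss at step {step}; offending views: "
                    f"{batch.views[:4]}...")
            opt.zero_grad()
            loss.backward()
            norm = nn.clip_grad_norm(params, config.max_grad_norm)
            opt.step()
            step += 1
            frac_now = step / total_steps
            traj.step_losses.append((frac_now, float(loss.data)))
            traj.grad_norms.append(norm)
            for frac in ckpt_steps.get(step, []):
                ckpt = EncoderCheckpoint.capture(encoder, projector,
                                                 epoch_fraction=frac)
                traj.checkpoints.append((frac, ckpt))
                if ckpt_dir is not None:
                    ckpt.save(ckpt_dir / f"ckpt_f{frac:.4f}.npz")

    final = EncoderCheckpoint.capture(encoder, projector, epoch_fraction=1.0)
    return final, traj
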