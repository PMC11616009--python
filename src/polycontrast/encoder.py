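"""Transformer encoder f(·), [CLS] pooling, projector g(·), implicit dropout.

The encoder is a compact, randomly initialised transformer over SMILES
tokens. A ``[CLS]`` position is prepended by the encoder's own preprocessing
(augmentations never see it) and its final-layer embedding is the pooled
polymer representation h (default width 600). During contrastive
pre-training a two-layer MLP projector maps h to the latent vector z
(default width 128) where similarities are computed; downstream consumers
use h, never z.

Implicit augmentation is the encoder's own dropout: with it enabled, the
hidden-state and attention-probability dropout rates are both 0.1, so two
training-mode passes over the same view give different embeddings; disabled,
both rates are 0 and encoding is deterministic.

The encoder is an ordinary interface — any object exposing the same
``encode_tensor``/``encode`` surface (e.g. a wrapper around a large
pretrained checkpoint) can be substituted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .polymer_smiles import DEFAULT_TOKENIZER, Tokenizer

logger = logging.getLogger("polycontrast")

CHECKPOINT_FORMAT_VERSION = 1

PAD, CLS, UNK, MASK = "[PAD]", "[CLS]", "[UNK]", "[MASK]"
SPECIAL_TOKENS = (PAD, CLS, UNK, MASK)


@dataclass
class EncoderConfig:
    """Hyperparameters of the desk-scale reference encoder.

    hidden_dim is the width of the pooled representation h; projection_dim
    the width of z. hidden_dropout / attention_dropout are the implicit-
    augmentation rates (0.1 when enabled, 0.0 when disabled).
    """

    hidden_dim: int = 600
    n_layers: int = 2
    n_heads: int = 4
    ff_dim: int | None = None
    hidden_dropout: float = 0.1
    attention_dropout: float = 0.1
    max_len: int = 128
    projection_dim: int = 128
    residual_gain: float = 4.0

    def __post_init__(self):
        if self.ff_dim is None:
            self.ff_dim = 2 * self.hidden_dim


@dataclass
class EmbeddingMatrix:
    """An n×d (or batch×len×d token-level) real array with a role tag."""

    values: np.ndarray
    role: str  # one of {"token_level", "pooled_h", "projected_z"}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


class Vocabulary:
    """Token-to-id map with reserved special tokens."""

    def __init__(self, tokens: Sequence[str]):
        self.itos = list(SPECIAL_TOKENS) + [t for t in tokens if t not in SPECIAL_TOKENS]
        self.stoi = {t: i for i, t in enumerate(self.itos)}

    def __len__(self) -> int:
        return len(self.itos)

    def ids(self, tokens: Sequence[str]) -> list[int]:
        unk = self.stoi[UNK]
        return [self.stoi.get(t, unk) for t in tokens]

    @classmethod
    def build(cls, corpus: Sequence[str], tokenizer: Tokenizer = DEFAULT_TOKENIZER) -> "Vocabulary":
        seen: dict[str, None] = {}
        for s in corpus:
            for t in tokenizer.tokenize(s):
                seen.setdefault(t, None)
        return cls(sorted(seen))

    def to_json(self) -> str:
        return json.dumps(self.itos)

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        itos = json.loads(payload)
        vocab = cls.__new__(cls)
        vocab.itos = list(itos)
        vocab.stoi = {t: i for i, t in enumerate(vocab.itos)}
        return vocab


class PolymerEncoder(nn.Module):
    """Small transformer encoder over SMILES token streams."""

    def __init__(self, config: EncoderConfig, vocab: Vocabulary, seed: int = 0,
                 tokenizer: Tokenizer = DEFAULT_TOKENIZER):
        self.config = config
        self.vocab = vocab
        self.tokenizer = tokenizer
        init_rng = np.random.default_rng(seed)
        d = config.hidden_dim
        self.token_emb = nn.Embedding(len(vocab), d, init_rng)
        self.pos_emb = nn.Embedding(config.max_len, d, init_rng)
        self.emb_ln = nn.LayerNorm(d)
        self.layers = [nn.TransformerLayer(d, config.n_heads, config.ff_dim, init_rng)
                       for _ in range(config.n_layers)]
        # Post-norm stacks start collapsed: the constant [CLS] residual swamps
        # the content-dependent signal, so a fresh encoder maps every input to
        # nearly the same pooled vector. Boosting the residual-branch output
        # projections at init keeps distinct inputs distinguishable.
        for layer in self.layers:
            layer.attn.wo.weight.data *= config.residual_gain
            layer.ffn.fc2.weight.data *= config.residual_gain
        self.dropout_rng = np.random.default_rng(seed + 1)

    # -- preprocessing -----------------------------------------------------

    def seed_dropout(self, seed: int) -> None:
        self.dropout_rng = np.random.default_rng(seed)

    def prepare_batch(self, views: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Tokenize, prepend [CLS], pad; returns (ids, pad_mask)."""
        cls_id = self.vocab.stoi[CLS]
        pad_id = self.vocab.stoi[PAD]
        seqs: list[list[int]] = []
        truncated = 0
        for v in views:
            ids = [cls_id] + self.vocab.ids(self.tokenizer.tokenize(v))
            if len(ids) > self.config.max_len:
                ids = ids[: self.config.max_len]
                truncated += 1
            seqs.append(ids)
        if truncated:
            logger.warning("truncated %d over-length sequence(s) to max_len=%d",
                           truncated, self.config.max_len)
        L = max(len(s) for s in seqs)
        ids = np.full((len(seqs), L), pad_id, dtype=np.int64)
        mask = np.zeros((len(seqs), L), dtype=bool)
        for i, s in enumerate(seqs):
            ids[i, : len(s)] = s
            mask[i, : len(s)] = True
        return ids, mask

    # -- forward -----------------------------------------------------------

    def encode_tensor(self, views: Sequence[str], train_mode: bool) -> tuple[nn.Tensor, np.ndarray]:
        """Differentiable token-level encoding; returns (B, L, D) tensor + mask."""
        ids, mask = self.prepare_batch(views)
        B, L = ids.shape
        x = self.token_emb(ids) + self.pos_emb(np.arange(L))
        x = self.emb_ln(x)
        hd, ad = self.config.hidden_dropout, self.config.attention_dropout
        x = nn.dropout(x, hd, train_mode, self.dropout_rng)
        for layer in self.layers:
            x = layer(x, mask, hd, ad, train_mode, self.dropout_rng)
        return x, mask

    def pool_tensor(self, token_level: nn.Tensor) -> nn.Tensor:
        """[CLS] pooling: the first-position vector of each sequence."""
        return token_level[:, 0, :]


def encode(views: Sequence[str], model: PolymerEncoder,
           train_mode: bool = False) -> EmbeddingMatrix:
    """Encode views to token-level embeddings (eval mode is deterministic)."""
    if len(views) == 0:
        d = model.config.hidden_dim
        return EmbeddingMatrix(np.zeros((0, 0, d)), "token_level")
    out, _ = model.encode_tensor(views, train_mode)
    return EmbeddingMatrix(out.data, "token_level")


def pool_cls(token_level: EmbeddingMatrix) -> EmbeddingMatrix:
    """Extract the [CLS]-position (first) vector from each sequence."""
    if token_level.role != "token_level":
        raise ValueError(f"expected token_level embeddings, got {token_level.role}")
    return EmbeddingMatrix(token_level.values[:, 0, :], "pooled_h")


def encode_pooled(views: Sequence[str], model: PolymerEncoder,
                  train_mode: bool = False) -> EmbeddingMatrix:
    """Convenience: encode then [CLS]-pool to the polymer representation h."""
    return pool_cls(encode(views, model, train_mode))


class Projector(nn.Module):
    """Two-layer MLP g(·): affine → ReLU → affine, h (hidden_dim) → z (128)."""

    def __init__(self, hidden_dim: int, projection_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.fc1 = nn.Linear(hidden_dim, hidden_dim, rng)
        self.fc2 = nn.Linear(hidden_dim, projection_dim, rng)
        self.in_dim = hidden_dim
        self.out_dim = projection_dim

    def __call__(self, h: nn.Tensor) -> nn.Tensor:
        return self.fc2(self.fc1(h).relu())


def project(h: EmbeddingMatrix | np.ndarray, projector: Projector) -> EmbeddingMatrix:
    """Map pooled representations h to latent vectors z."""
    values = h.values if isinstance(h, EmbeddingMatrix) else np.asarray(h, dtype=float)
    if values.ndim != 2 or values.shape[1] != projector.in_dim:
        raise ValueError(
            f"expected (n, {projector.in_dim}) pooled input, got {values.shape}")
    z = projector(nn.Tensor(values))
    return EmbeddingMatrix(z.data, "projected_z")


def set_implicit_dropout(model: PolymerEncoder, enabled: bool) -> PolymerEncoder:
    """Toggle implicit augmentation: both dropout rates 0.1 (on) or 0.0 (off).

    Weights are untouched; the same model object is returned.
    """
    rate = 0.1 if enabled else 0.0
    model.config.hidden_dropout = rate
    model.config.attention_dropout = rate
    return model


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


@dataclass
class EncoderCheckpoint:
    """A single-file snapshot: encoder weights + config + vocabulary.

    The projector state is carried alongside during pre-training so a run can
    be resumed or inspected; transfer learning ignores it.
    """

    config: EncoderConfig
    vocab: Vocabulary
    encoder_state: dict
    projector_state: dict | None = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def capture(cls, encoder: PolymerEncoder, projector: Projector | None = None,
                **meta) -> "EncoderCheckpoint":
        cfg = EncoderConfig(**asdict(encoder.config))
        return cls(config=cfg, vocab=encoder.vocab,
                   encoder_state=encoder.state_dict(),
                   projector_state=projector.state_dict() if projector else None,
                   meta=dict(meta))

    def build_encoder(self, tokenizer: Tokenizer = DEFAULT_TOKENIZER) -> PolymerEncoder:
        enc = PolymerEncoder(EncoderConfig(**asdict(self.config)), self.vocab,
                             tokenizer=tokenizer)
        enc.load_state_dict(self.encoder_state)
        return enc

    def build_projector(self) -> Projector | None:
        if self.projector_state is None:
            return None
        proj = Projector(self.config.hidden_dim, self.config.projection_dim)
        proj.load_state_dict(self.projector_state)
        return proj

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"enc:{k}": v for k, v in self.encoder_state.items()}
        if self.projector_state is not None:
            arrays.update({f"proj:{k}": v for k, v in self.projector_state.items()})
        header = json.dumps({
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": asdict(self.config),
            "vocab": self.vocab.itos,
            "meta": self.meta,
        })
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "EncoderCheckpoint":
        with np.load(Path(path)) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            if header.get("format_version") != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(f"unsupported checkpoint version in {path}")
            enc_state = {k[4:]: data[k] for k in data.files if k.startswith("enc:")}
            proj_state = {k[5:]: data[k] for k in data.files if k.startswith("proj:")}
        return cls(config=EncoderConfig(**header["config"]),
                   vocab=Vocabulary.from_json(json.dumps(header["vocab"])),
                   encoder_state=enc_state,
                   projector_state=proj_state or None,
                   meta=header.get("meta", {}))


def weight_checksum(module: nn.Module) -> float:
    """Order-stable checksum of all parameters (freeze-contract checks)."""
    return float(sum(float(np.abs(p).sum()) for _, p in
                     sorted((n, p.data) for n, p in module.named_parameters())))
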