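"""Explicit SMILES augmentations and positive-pair batch construction.

Four view-generating modes are supported: ``original`` (identity),
``enumeration`` (a randomized re-rendering of the same molecular graph),
``masking`` (replace a fraction of tokens with a mask token) and ``drop``
(delete a fraction of tokens). Masking and drop operate on the token stream,
so their outputs need not be chemically valid SMILES — downstream encoders
consume raw token streams.

A positive-pair batch holds 2N views of N anchor molecules: view ``i`` and
view ``N + i`` derive from anchor ``i`` through the two branch recipes; all
cross-anchor view pairs are implicit negatives and are never materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .polymer_smiles import (
    PolymerSmiles,
    detokenize,
    enumerate_smiles,
    tokenize,
    validate,
)

MODES = ("original", "enumeration", "masking", "drop")

#: Mask token default — a bracket "atom" so the regex tokenizer keeps it atomic
#: and it can never collide with a chemical token.
DEFAULT_MASK_TOKEN = "[MASK]"


@dataclass(frozen=True)
class AugmentationSpec:
    """One branch's view recipe.

    ratio is the fraction of tokens affected by masking/drop (ignored for
    original/enumeration); implicit_dropout asks the encoder to keep its
    stochastic dropout active while encoding views built from this spec.
    """

    mode: str = "original"
    ratio: float = 0.10
    mask_token: str = DEFAULT_MASK_TOKEN
    protect_stars: bool = False
    implicit_dropout: bool = False

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown augmentation mode {self.mode!r}; choose from {MODES}")
        if not (0.0 <= self.ratio < 1.0):
            raise ValueError(f"ratio must lie in [0, 1), got {self.ratio}")

    def with_implicit(self, enabled: bool) -> "AugmentationSpec":
        return replace(self, implicit_dropout=enabled)


def _n_affected(n_eligible: int, ratio: float, n_total: int) -> int:
    """Number of tokens to touch: max(1, round(ratio * n)) for ratio > 0.

    Rounding is half-away-from-zero; the minimum-one rule keeps the
    augmentation from degenerating to a no-op on short repeat units. The
    count is clamped to the eligible pool (relevant with protected tokens).
    """
    if ratio <= 0.0:
        return 0
    k = max(1, int(np.floor(ratio * n_total + 0.5)))
    return min(k, n_eligible)


def _eligible_indices(tokens: Sequence[str], protect_stars: bool) -> np.ndarray:
    if protect_stars:
        return np.asarray([i for i, t in enumerate(tokens) if t not in ("[*]", "*")],
                          dtype=int)
    return np.arange(len(tokens))


def apply_drop(tokens: Sequence[str], ratio: float, rng: np.random.Generator,
               protect_stars: bool = False) -> list[str]:
    """Delete ``max(1, round(ratio·n))`` tokens, preserving survivor order."""
    if not tokens:
        raise ValueError("cannot drop tokens from an empty sequence")
    if ratio >= 1.0:
        raise ValueError(f"drop ratio must be < 1, got {ratio}")
    pool = _eligible_indices(tokens, protect_stars)
    k = _n_affected(len(pool), ratio, len(tokens))
    if k == 0:
        return list(tokens)
    removed = set(rng.choice(pool, size=k, replace=False).tolist())
    return [t for i, t in enumerate(tokens) if i not in removed]


def apply_mask(tokens: Sequence[str], ratio: float, mask_token: str,
               rng: np.random.Generator, protect_stars: bool = False) -> list[str]:
    """Replace ``max(1, round(ratio·n))`` tokens with ``mask_token``; length kept."""
    if not tokens:
        raise ValueError("cannot mask tokens in an empty sequence")
    if ratio >= 1.0:
        raise ValueError(f"mask ratio must be < 1, got {ratio}")
    pool = _eligible_indices(tokens, protect_stars)
    k = _n_affected(len(pool), ratio, len(tokens))
    out = list(tokens)
    if k == 0:
        return out
    for i in rng.choice(pool, size=k, replace=False).tolist():
        out[i] = mask_token
    return out


def make_view(x: PolymerSmiles, spec: AugmentationSpec, rng: np.random.Generator) -> str:
    """Produce one augmented view of an anchor molecule."""
    if spec.mode == "original":
        return x
    if spec.mode == "enumeration":
        return enumerate_smiles(x, rng)
    tokens = tokenize(x)
    if spec.mode == "masking":
        out = apply_mask(tokens, spec.ratio, spec.mask_token, rng, spec.protect_stars)
    else:  # drop
        out = apply_drop(tokens, spec.ratio, rng, spec.protect_stars)
    return detokenize(out)


@dataclass
class PositivePairBatch:
    """2N ordered views of N anchors; views (i, N+i) are the positive pairs."""

    views: list
    anchors: list
    spec_a: AugmentationSpec
    spec_b: AugmentationSpec
    pairing: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.anchors)
        if len(self.views) != 2 * n:
            raise ValueError("batch must hold exactly 2N views for N anchors")
        if not self.pairing:
            self.pairing = [(i, n + i) for i in range(n)]

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def make_positive_pairs(anchors: Sequence[PolymerSmiles], spec_a: AugmentationSpec,
                        spec_b: AugmentationSpec,
                        rng: np.random.Generator) -> PositivePairBatch:
    """Build the contrastive batch: branch-A views then branch-B views.

    Aborts (raises) if any anchor fails chemical validation — pre-training
    corpora are expected to be validated up front, so a bad anchor here is a
    programming error, not data noise.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("anchors must be non-empty")
    for x in anchors:
        report = validate(x)
        if not report.valid_smiles:
            raise ValueError(f"invalid anchor SMILES {x!r}: {report.errors}")
    views_a = [make_view(x, spec_a, rng) for x in anchors]
    views_b = [make_view(x, spec_b, rng) for x in anchors]
    return PositivePairBatch(views=views_a + views_b, anchors=anchors,
                             spec_a=spec_a, spec_b=spec_b)
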