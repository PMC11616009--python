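"""Alignment and uniformity diagnostics for learnt representations.

Alignment is the mean squared Euclidean distance between embeddings of
known positive pairs,

    L_align = E_{(x, x+)} || f(x) - f(x+) ||^2,

and uniformity is the log of the mean Gaussian potential over all embedding
pairs on the unit hypersphere,

    L_uniform = log E_{x, y iid} exp(-t || f(x) - f(y) ||^2),    t = 2.

Lower is better for both: low alignment means positive views map close
together; low uniformity means the embedding cloud spreads over the sphere
and so preserves more information. Rows are L2-normalised before either
metric by default (the unit-hypersphere framing); both metrics are computed
on the pooled representation h, not the projected z, so models without a
projector can be compared on the same footing.

The evaluation protocol builds positive pairs by enumerating each polymer
once — a semantics-preserving augmentation — and traces both metrics across
pre-training checkpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.special import logsumexp

from .encoder import EmbeddingMatrix, EncoderCheckpoint
from .polymer_smiles import PolymerSmiles, canonicalize, enumerate_smiles

logger = logging.getLogger("polycontrast")

#: Gaussian-potential sharpness in the uniformity metric.
DEFAULT_T = 2.0
#: Above this many embeddings, uniformity subsamples pairs (seeded, logged).
EXACT_PAIR_LIMIT = 5000


def _as_array(E) -> np.ndarray:
    values = getattr(E, "values", E)
    return np.asarray(values, dtype=float)


def _l2_normalize(E: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(E, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError("cannot L2-normalise zero rows")
    return E / norms


def alignment(E1, E2, normalize: bool = True) -> float:
    """Mean squared distance between paired rows of E1 and E2."""
    A, B = _as_array(E1), _as_array(E2)
    if A.shape != B.shape:
        raise ValueError(f"paired matrices must match in shape: {A.shape} vs {B.shape}")
    if A.shape[0] == 0:
        raise ValueError("alignment of an empty pair set is undefined")
    if normalize:
        A, B = _l2_normalize(A), _l2_normalize(B)
    return float(np.mean(np.sum((A - B) ** 2, axis=1)))


def uniformity(E, t: float = DEFAULT_T, normalize: bool = True,
               exact_limit: int = EXACT_PAIR_LIMIT,
               rng: np.random.Generator | None = None) -> float:
    """log mean Gaussian potential over unordered distinct row pairs.

    Exact up to ``exact_limit`` rows; beyond that a seeded subsample of the
    same number of pairs is used and the subsample size is logged.
    """
    X = _as_array(E)
    n = X.shape[0]
    if n < 2:
        raise ValueError("uniformity needs at least two embeddings")
    if normalize:
        X = _l2_normalize(X)
    if n > exact_limit:
        rng = rng if rng is not None else np.random.default_rng(0)
        m = exact_limit * (exact_limit - 1) // 2
        i = rng.integers(0, n, size=m)
        j = rng.integers(0, n, size=m)
        keep = i != j
        logger.info("uniformity: subsampling %d of %d pairs", int(keep.sum()),
                    n * (n - 1) // 2)
        sq = np.sum((X[i[keep]] - X[j[keep]]) ** 2, axis=1)
    else:
        sq = pdist(X, metric="sqeuclidean")
    return float(logsumexp(-t * sq) - np.log(sq.size))


@dataclass
class EvalPairSet:
    """Originals and one enumerated (semantics-preserving) positive each."""

    originals: list
    positives: list

    def __post_init__(self):
        if len(self.originals) != len(self.positives):
            raise ValueError("originals and positives must have equal length")

    def __len__(self) -> int:
        return len(self.originals)

    def check_semantics(self) -> bool:
        """True iff every pair shares a canonical form (same molecular graph)."""
        return all(canonicalize(a) == canonicalize(b)
                   for a, b in zip(self.originals, self.positives))


def build_eval_pairs(polymers: Sequence[PolymerSmiles],
                     rng: np.random.Generator) -> EvalPairSet:
    """Augment each polymer once by enumeration to form evaluation pairs."""
    originals = list(polymers)
    positives = [enumerate_smiles(s, rng) for s in originals]
    return EvalPairSet(originals, positives)


@dataclass
class MetricReport:
    alignment_loss: float
    uniformity_loss: float
    n_pairs: int
    embedding_role: str = "pooled_h"
    normalize: bool = True

    def to_dict(self) -> dict:
        return {
            "alignment_loss": self.alignment_loss,
            "uniformity_loss": self.uniformity_loss,
            "n_pairs": self.n_pairs,
            "embedding_role": self.embedding_role,
            "normalize": self.normalize,
        }


def evaluate_pairs(checkpoint: EncoderCheckpoint, pairs: EvalPairSet,
                   t: float = DEFAULT_T, normalize: bool = True,
                   batch_size: int = 256) -> MetricReport:
    """Alignment and uniformity of one checkpoint on an evaluation pair set.

    Both sides are encoded in eval mode (deterministic) and [CLS]-pooled;
    uniformity is taken over the union of both sides' embeddings.
    """
    from .transfer import extract_features  # deferred: avoids import cycle

    H1 = extract_features(checkpoint, pairs.originals, batch_size=batch_size).values
    H2 = extract_features(checkpoint, pairs.positives, batch_size=batch_size).values
    return MetricReport(
        alignment_loss=alignment(H1, H2, normalize=normalize),
        uniformity_loss=uniformity(np.vstack([H1, H2]), t=t, normalize=normalize),
        n_pairs=len(pairs),
        normalize=normalize,
    )


def metric_trajectory(checkpoints: Iterable, pairs: EvalPairSet,
                      t: float = DEFAULT_T, normalize: bool = True) -> pd.DataFrame:
    """Trace (epoch_fraction, alignment, uniformity) across checkpoints.

    ``checkpoints`` may mix (fraction, EncoderCheckpoint) tuples, checkpoint
    objects carrying an ``epoch_fraction`` meta entry, and file paths.
    Unloadable entries are skipped with a warning.
    """
    rows = []
    for entry in checkpoints:
        try:
            if isinstance(entry, tuple):
                frac, ckpt = entry
            else:
                ckpt = entry
                if isinstance(ckpt, (str, Path)):
                    ckpt = EncoderCheckpoint.load(ckpt)
                frac = float(ckpt.meta.get("epoch_fraction", np.nan))
            report = evaluate_pairs(ckpt, pairs, t=t, normalize=normalize)
        except Exception as exc:  # corrupt checkpoint: skip, keep tracing
            logger.warning("skipping checkpoint %r: %s", entry, exc)
            continue
        rows.append({"epoch_fraction": float(frac),
                     "alignment": report.alignment_loss,
                     "uniformity": report.uniformity_loss})
    return pd.DataFrame(rows, columns=["epoch_fraction", "alignment", "uniformity"])
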