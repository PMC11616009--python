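"""Two-step augmentation-combination selection over the explicit grid.

Step 1 pre-trains one model per unordered pair of explicit augmentation
modes (original, enumeration, masking, drop — 10 pairs including the
Original–Original no-augmentation baseline), evaluates each by frozen-
encoder transfer on every downstream task, and counts on how many tasks
each combination strictly beats the baseline's mean R². Step 2 re-runs the
top-tier combinations (wins ≥ n_tasks − 1 by default) with implicit dropout
enabled in both branches.

Fairness contract: every combination trains from the same encoder/projector
initialisation and seed on the same corpus, and every task is evaluated
with identical cross-validation fold assignments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .augmentations import MODES, AugmentationSpec
from .encoder import EncoderConfig, PolymerEncoder, Projector, Vocabulary
from .pretrain import ContrastiveConfig, train_contrastive
from .transfer import TransferConfig, cross_validate, extract_features

logger = logging.getLogger("polycontrast")

#: The two explicit combinations integrated with implicit dropout by default;
#: Enumeration–Masking is the flagship mixed combination.
DEFAULT_MIXED_SELECTION = (("enumeration", "masking"), ("drop", "original"))


def enumerate_combinations(modes: Sequence[str] = MODES,
                           with_repetition: bool = True) -> list[tuple[str, str]]:
    """Unordered mode pairs in deterministic (alphabetical) order."""
    if not modes:
        raise ValueError("modes must be non-empty")
    ordered = sorted(modes)
    if with_repetition:
        return list(itertools.combinations_with_replacement(ordered, 2))
    return list(itertools.combinations(ordered, 2))


@dataclass
class ComboRow:
    pair: tuple
    implicit: bool
    r2_per_task: dict = field(default_factory=dict)   # task name -> mean R²
    fold_assignments: dict = field(default_factory=dict)  # task -> list of arrays
    complete: bool = True
    error: str | None = None

    @property
    def key(self) -> tuple:
        return (self.pair[0], self.pair[1], self.implicit)


@dataclass
class ComboGridResult:
    """One row per augmentation combination; shared baseline row."""

    rows: list
    task_names: list
    baseline_key: tuple = ("original", "original", False)

    def row(self, key: tuple) -> ComboRow:
        for r in self.rows:
            if r.key == tuple(key):
                return r
        raise KeyError(f"no row for combination {key}")

    @property
    def baseline(self) -> ComboRow:
        return self.row(self.baseline_key)


def count_wins(result: ComboGridResult,
               baseline_key: tuple | None = None) -> dict[tuple, int]:
    """Per-combination count of tasks with mean R² strictly above baseline."""
    base = result.row(baseline_key or result.baseline_key)
    if not base.complete:
        raise ValueError("baseline row is incomplete")
    wins: dict[tuple, int] = {}
    for row in result.rows:
        if row.key == base.key:
            wins[row.key] = 0
            continue
        wins[row.key] = sum(
            1 for task in result.task_names
            if row.complete and row.r2_per_task[task] > base.r2_per_task[task])
    return wins


def select_top(result: ComboGridResult, threshold: int | None = None) -> list[tuple]:
    """Step-1 selection: combinations winning on ≥ threshold tasks.

    Default threshold is n_tasks − 1 (the top tier of the explicit grid).
    The baseline itself is never selected.
    """
    if threshold is None:
        threshold = len(result.task_names) - 1
    wins = count_wins(result)
    return [r.pair for r in result.rows
            if r.key != result.baseline_key and wins[r.key] >= threshold]


def _canonical_pair(pair: Sequence[str]) -> tuple[str, str]:
    a, b = sorted(pair)
    return (a, b)


def run_grid(corpus: Sequence[str], combos: Sequence[tuple],
             tasks: dict[str, tuple], pretrain_config: ContrastiveConfig,
             transfer_config: TransferConfig, encoder_config: EncoderConfig,
             implicit: bool = False, init_seed: int = 0) -> ComboGridResult:
    """Pre-train and evaluate one model per augmentation combination.

    ``tasks`` maps a task name to ``(polymers, labels)``. Every combination
    starts from an identical encoder/projector initialisation (``init_seed``)
    and uses the same ``transfer_config`` seed, so fold assignments agree
    across rows. A failed combination is recorded as an incomplete row.
    """
    corpus = list(corpus)
    vocab = Vocabulary.build(corpus + ["[MASK]"])
    task_names = list(tasks)
    rows: list[ComboRow] = []
    for pair in combos:
        pair = _canonical_pair(pair)
        row = ComboRow(pair=pair, implicit=implicit)
        try:
            encoder = PolymerEncoder(
                EncoderConfig(**vars(encoder_config).copy()), vocab, seed=init_seed)
            projector = Projector(encoder_config.hidden_dim,
                                  encoder_config.projection_dim, seed=init_seed)
            spec_a = AugmentationSpec(mode=pair[0], implicit_dropout=implicit)
            spec_b = AugmentationSpec(mode=pair[1], implicit_dropout=implicit)
            ckpt, _ = train_contrastive(corpus, spec_a, spec_b, encoder,
                                        projector, pretrain_config)
            for name in task_names:
                polymers, y = tasks[name]
                feats = extract_features(ckpt, polymers)
                report = cross_validate(feats, y, transfer_config)
                row.r2_per_task[name] = report.mean_r2
                row.fold_assignments[name] = report.fold_assignments
        except Exception as exc:
            logger.warning("combination %s failed: %s", pair, exc)
            row.complete = False
            row.error = str(exc)
        rows.append(row)
    baseline_key = ("original", "original", implicit)
    return ComboGridResult(rows=rows, task_names=task_names,
                           baseline_key=baseline_key)


def run_mixed(selected: Sequence[tuple], corpus: Sequence[str],
              tasks: dict[str, tuple], pretrain_config: ContrastiveConfig,
              transfer_config: TransferConfig, encoder_config: EncoderConfig,
              init_seed: int = 0) -> ComboGridResult:
    """Step 2: re-run selected explicit combinations with implicit dropout on.

    The Original–Original baseline is carried along (also with implicit
    dropout, i.e. the implicit-only regime) so wins remain well defined.
    """
    combos = [_canonical_pair(p) for p in selected]
    if ("original", "original") not in combos:
        combos = [("original", "original")] + combos
    return run_grid(corpus, combos, tasks, pretrain_config, transfer_config,
                    encoder_config, implicit=True, init_seed=init_seed)
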