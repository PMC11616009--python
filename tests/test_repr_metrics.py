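"""Alignment/uniformity closed forms, oracles, invariances, trajectories."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from polycontrast.augmentations import AugmentationSpec
from polycontrast.encoder import EncoderCheckpoint, Projector
from polycontrast.polymer_smiles import canonicalize
from polycontrast.pretrain import ContrastiveConfig, train_contrastive
from polycontrast.repr_metrics import (
    EvalPairSet,
    alignment,
    build_eval_pairs,
    evaluate_pairs,
    metric_trajectory,
    uniformity,
)
from polycontrast.synthetic_data import generate_embedding_fixture

from conftest import make_tiny_encoder
from oracles import brute_alignment, brute_uniformity


def test_alignment_identical_pairs_is_zero():
    E, E2 = generate_embedding_fixture(10, 6, "identical", np.random.default_rng(0))
    assert alignment(E, E2) == pytest.approx(0.0, abs=1e-12)


def test_antipodal_unit_pair_closed_forms():
    E1, E2 = generate_embedding_fixture(1, 5, "antipodal_pair", np.random.default_rng(1))
    assert alignment(E1, E2) == pytest.approx(4.0, abs=1e-9)
    two_points = np.vstack([E1, E2])
    assert uniformity(two_points, t=2.0) == pytest.approx(-8.0, abs=1e-9)


def test_uniformity_identical_rows_is_zero():
    row = np.random.default_rng(2).normal(size=7)
    E = np.tile(row, (5, 1))
    assert uniformity(E) == pytest.approx(0.0, abs=1e-12)


def test_metrics_match_bruteforce_loops():
    rng = np.random.default_rng(3)
    E1 = rng.normal(size=(10, 8))
    E2 = rng.normal(size=(10, 8))
    assert alignment(E1, E2) == pytest.approx(brute_alignment(E1, E2), abs=1e-10)
    E = rng.normal(size=(12, 16))
    assert uniformity(E) == pytest.approx(brute_uniformity(E), abs=1e-10)
    # unnormalised variants agree too
    assert alignment(E1, E2, normalize=False) == pytest.approx(
        brute_alignment(E1, E2, normalize=False), abs=1e-10)
    assert uniformity(E, normalize=False) == pytest.approx(
        brute_uniformity(E, normalize=False), abs=1e-10)


def test_metrics_invariant_to_common_rotation():
    rng = np.random.default_rng(4)
    E1 = rng.normal(size=(9, 6))
    E2 = rng.normal(size=(9, 6))
    Q = ortho_group.rvs(6, random_state=5)
    assert alignment(E1 @ Q, E2 @ Q) == pytest.approx(alignment(E1, E2), rel=1e-9)
    assert uniformity(E1 @ Q) == pytest.approx(uniformity(E1), rel=1e-9)
    # permutation invariance of uniformity
    perm = rng.permutation(9)
    assert uniformity(E1[perm]) == pytest.approx(uniformity(E1), rel=1e-12)


def test_metric_sign_bounds():
    rng = np.random.default_rng(6)
    for _ in range(10):
        E1 = rng.normal(size=(6, 4))
        E2 = rng.normal(size=(6, 4))
        assert alignment(E1, E2) >= 0.0
        assert uniformity(np.vstack([E1, E2])) <= 0.0


def test_uniformity_subsampling_close_to_exact():
    rng = np.random.default_rng(7)
    E = rng.normal(size=(300, 8))
    exact = uniformity(E)
    sub = uniformity(E, exact_limit=150, rng=np.random.default_rng(0))
    assert sub == pytest.approx(exact, abs=0.05)


def test_metric_input_validation():
    with pytest.raises(ValueError):
        alignment(np.zeros((0, 3)), np.zeros((0, 3)))
    with pytest.raises(ValueError):
        uniformity(np.ones((1, 3)))
    with pytest.raises(ValueError):
        alignment(np.ones((2, 3)), np.ones((3, 3)))


def test_build_eval_pairs_semantics_and_reproducibility(small_corpus):
    polymers = small_corpus[:20]
    pairs = build_eval_pairs(polymers, np.random.default_rng(8))
    assert len(pairs) == 20
    assert pairs.check_semantics()
    again = build_eval_pairs(polymers, np.random.default_rng(8))
    assert pairs.positives == again.positives
    with pytest.raises(ValueError):
        EvalPairSet(["a"], [])


def test_gaussian_cluster_fixture_alignment_ordering():
    E1, E2 = generate_embedding_fixture(40, 8, "gaussian_clusters",
                                        np.random.default_rng(9))
    within = alignment(E1, E2)
    shuffled = E2[np.random.default_rng(10).permutation(40)]
    assert within < alignment(E1, shuffled)


def test_metric_trajectory_rows_and_determinism(tmp_path, small_corpus, tiny_vocab):
    enc = make_tiny_encoder(tiny_vocab)
    proj = Projector(enc.config.hidden_dim, enc.config.projection_dim, seed=0)
    cfg = ContrastiveConfig(epochs=1, batch_size=16, learning_rate=1e-3, seed=0,
                            checkpoint_cadence=[0.5, 1.0])
    _, traj = train_contrastive(small_corpus[:32], AugmentationSpec("enumeration"),
                                AugmentationSpec("masking"), enc, proj, cfg)
    pairs = build_eval_pairs(small_corpus[32:48], np.random.default_rng(11))
    table = metric_trajectory(traj.checkpoints, pairs)
    assert list(table.columns) == ["epoch_fraction", "alignment", "uniformity"]
    assert list(table["epoch_fraction"]) == [0.5, 1.0]
    # identical checkpoint evaluated twice -> identical row
    twice = metric_trajectory([traj.checkpoints[0], traj.checkpoints[0]], pairs)
    assert twice.iloc[0].equals(twice.iloc[1])
    # corrupt checkpoint file is skipped with a warning, not fatal
    bad = tmp_path / "bad.npz"
    bad.write_text("not a checkpoint")
    mixed = metric_trajectory([str(bad), traj.checkpoints[1]], pairs)
    assert len(mixed) == 1


def test_evaluate_pairs_uses_pooled_h(small_corpus, tiny_vocab):
    enc = make_tiny_encoder(tiny_vocab)
    ckpt = EncoderCheckpoint.capture(enc)
    pairs = build_eval_pairs(small_corpus[:10], np.random.default_rng(12))
    report = evaluate_pairs(ckpt, pairs)
    assert report.embedding_role == "pooled_h"
    assert report.n_pairs == 10
    assert report.alignment_loss >= 0.0 and report.uniformity_loss <= 0.0
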