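"""Frozen-encoder transfer: metrics, early stopping, cross-validation."""

import numpy as np
import pytest

from polycontrast.encoder import EncoderCheckpoint, weight_checksum
from polycontrast.synthetic_data import (
    SyntheticTaskSpec,
    descriptor_matrix,
    generate_polymers,
    generate_property_dataset,
    make_noise_sd,
)
from polycontrast.transfer import (
    TransferConfig,
    cross_validate,
    extract_features,
    fit_head,
    fold_splits,
    r_squared,
    rmse,
    run_transfer,
)

from conftest import make_tiny_encoder


def test_rmse_cases():
    assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert rmse([0, 0, 0], [2, -2, 2]) == pytest.approx(2.0)
    assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))


def test_r_squared_cases():
    y = [1.0, 2.0, 3.0]
    assert r_squared(y, y) == pytest.approx(1.0)
    assert r_squared(y, [2.0, 2.0, 2.0]) == pytest.approx(0.0)
    assert r_squared(y, [1.0, 2.0, 4.0]) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        r_squared([2.0, 2.0], [1.0, 2.0])


def test_fit_head_monotone_degradation_stops_at_start_plus_patience():
    """No improvement after epoch 1 -> stop at early_stop_start + patience."""
    rng = np.random.default_rng(0)
    X = np.ones((32, 4)) + 0.01 * rng.normal(size=(32, 4))
    y = np.full(32, 10.0)              # training pulls predictions up ...
    X_val = X.copy()
    y_val = np.full(32, -10.0)         # ... monotonically away from validation
    cfg = TransferConfig(head_dropout=0.0, seed=0)
    head, record = fit_head(X, y, cfg, np.random.default_rng(1),
                            X_val=X_val, y_val=y_val)
    assert record.best_epoch == 1
    assert record.stopped_epoch == cfg.early_stop_start + cfg.patience == 100


def test_fit_head_improving_runs_to_max_epochs():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(64, 3))
    y = X @ np.array([1.0, -2.0, 0.5])
    cfg = TransferConfig(head_dropout=0.0, max_epochs=60, learning_rate=1e-3)
    _, record = fit_head(X, y, cfg, np.random.default_rng(3), X_val=X, y_val=y)
    assert record.stopped_epoch == 60  # steady improvement -> no early stop


def test_fit_head_learns_noiseless_linear_map():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(200, 3))
    y = X @ np.array([2.0, -1.0, 0.5]) + 0.3
    cfg = TransferConfig(head_dropout=0.0, max_epochs=500, learning_rate=1e-2)
    head, _ = fit_head(X, y, cfg, np.random.default_rng(5), X_val=X, y_val=y)
    from polycontrast import nn
    pred = head(nn.Tensor(X), train=False, rng=rng).data
    assert r_squared(y, pred) >= 0.99


def test_fold_splits_partition_and_determinism():
    cfg = TransferConfig(seed=7)
    splits = fold_splits(100, cfg)
    held = np.concatenate([va for _, va in splits])
    assert sorted(held.tolist()) == list(range(100))
    assert all(len(va) == 20 for _, va in splits)
    again = fold_splits(100, cfg)
    for (_, a), (_, b) in zip(splits, again):
        assert np.array_equal(a, b)


def test_cross_validate_descriptor_task_high_r2():
    """Easy synthetic task: linear in 3 descriptors, 5% noise, R^2 >= 0.9."""
    polymers = generate_polymers(400, rng=np.random.default_rng(6))
    spec = SyntheticTaskSpec(coefficients=(1.0, -0.8, 2.5), seed=8)
    spec.noise_sd = make_noise_sd(polymers, spec, noise_frac=0.05)
    frame = generate_property_dataset(polymers, spec)
    X = descriptor_matrix(polymers)[:, :3]
    cfg = TransferConfig(seed=9, max_epochs=300)
    report = cross_validate(X, frame["y"].to_numpy(), cfg)
    assert report.mean_r2 >= 0.9
    assert len(report.fold_r2) == 5
    assert report.to_dict()["mean_r2"] == pytest.approx(report.mean_r2)


def test_extract_features_deterministic_and_frozen(small_corpus, tiny_vocab):
    enc = make_tiny_encoder(tiny_vocab)
    ckpt = EncoderCheckpoint.capture(enc)
    f1 = extract_features(ckpt, small_corpus[:10])
    f2 = extract_features(ckpt, small_corpus[:10])
    assert np.array_equal(f1.values, f2.values)
    assert f1.values.shape == (10, enc.config.hidden_dim)
    assert f1.role == "pooled_h"


def test_run_transfer_freeze_contract_and_enumeration_swap(small_corpus, tiny_vocab):
    enc = make_tiny_encoder(tiny_vocab)
    ckpt = EncoderCheckpoint.capture(enc)
    before = weight_checksum(ckpt.build_encoder())
    polymers = generate_polymers(40, rng=np.random.default_rng(10))
    spec = SyntheticTaskSpec(seed=11, noise_sd=0.1)
    y = generate_property_dataset(polymers, spec)["y"].to_numpy()
    cfg = TransferConfig(seed=12, max_epochs=30)
    canon = run_transfer(polymers, y, ckpt, cfg)
    assert weight_checksum(ckpt.build_encoder()) == before
    enum = run_transfer(polymers, y, ckpt, cfg, enumerate_inputs=True, enum_seed=1)
    assert weight_checksum(ckpt.build_encoder()) == before
    # same folds either way (fairness of the robustness comparison)
    for a, b in zip(canon.fold_assignments, enum.fold_assignments):
        assert np.array_equal(a, b)


def test_cross_validate_requires_enough_samples():
    with pytest.raises(ValueError):
        cross_validate(np.ones((3, 2)), [1.0, 2.0, 3.0], TransferConfig(folds=5))
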