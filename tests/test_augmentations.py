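"""Explicit augmentation operators and positive-pair batch construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polycontrast.augmentations import (
    AugmentationSpec,
    apply_drop,
    apply_mask,
    make_positive_pairs,
    make_view,
)
from polycontrast.polymer_smiles import canonicalize, tokenize
from polycontrast.synthetic_data import generate_polymers


def test_drop_count_and_order():
    tokens = list("ABCDEFGHIJ")  # n = 10 -> k = 1
    out = apply_drop(tokens, 0.1, np.random.default_rng(0))
    assert len(out) == 9
    it = iter(tokens)
    assert all(any(t == u for u in it) for t in out)  # survivor order preserved


@pytest.mark.parametrize("n,ratio,expected_removed", [
    (10, 0.1, 1), (5, 0.1, 1), (20, 0.1, 2), (30, 0.1, 3), (7, 0.0, 0), (15, 0.2, 3),
])
def test_drop_minimum_one_rule(n, ratio, expected_removed):
    tokens = [f"t{i}" for i in range(n)]
    out = apply_drop(tokens, ratio, np.random.default_rng(1))
    assert len(out) == n - expected_removed


def test_mask_preserves_length_and_count():
    tokens = [f"t{i}" for i in range(20)]
    out = apply_mask(tokens, 0.1, "[MASK]", np.random.default_rng(2))
    assert len(out) == 20
    assert sum(t == "[MASK]" for t in out) == 2
    assert sum(a == b for a, b in zip(tokens, out)) == 18


def test_mask_seed_variation_fixed_count():
    tokens = [f"t{i}" for i in range(30)]
    out1 = apply_mask(tokens, 0.1, "[MASK]", np.random.default_rng(3))
    out2 = apply_mask(tokens, 0.1, "[MASK]", np.random.default_rng(4))
    assert sum(t == "[MASK]" for t in out1) == 3 == sum(t == "[MASK]" for t in out2)
    assert out1 != out2  # different seeds pick different positions (w.h.p.)


def test_ratio_zero_is_identity():
    tokens = tokenize("[*]CC(Cl)[*]")
    assert apply_drop(tokens, 0.0, np.random.default_rng(0)) == tokens
    assert apply_mask(tokens, 0.0, "[MASK]", np.random.default_rng(0)) == tokens


def test_invalid_ratio_rejected():
    with pytest.raises(ValueError):
        apply_drop(list("ABC"), 1.0, np.random.default_rng(0))
    with pytest.raises(ValueError):
        AugmentationSpec(mode="drop", ratio=1.2)
    with pytest.raises(ValueError):
        AugmentationSpec(mode="shuffle")


def test_protect_stars_never_touches_connection_tokens():
    tokens = tokenize("[*]CC(Cl)CC[*]")
    for seed in range(20):
        rng = np.random.default_rng(seed)
        dropped = apply_drop(tokens, 0.3, rng, protect_stars=True)
        assert dropped.count("[*]") == 2
        masked = apply_mask(tokens, 0.3, "[MASK]", rng, protect_stars=True)
        assert masked.count("[*]") == 2


def test_protect_stars_clamps_to_pool():
    tokens = ["[*]", "C", "[*]"]  # pool of 1 eligible token
    out = apply_drop(tokens, 0.9, np.random.default_rng(0), protect_stars=True)
    assert out == ["[*]", "[*]"]


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 10_000), ratio=st.floats(0.05, 0.5))
def test_drop_mask_contracts_property(seed, ratio):
    """Drop removes exactly k tokens in order; mask keeps length, changes k."""
    tokens = tokenize("[*]CC(=O)OC(c1ccccc1)C(F)CC[*]")
    n = len(tokens)
    k = max(1, int(np.floor(ratio * n + 0.5)))
    dropped = apply_drop(tokens, ratio, np.random.default_rng(seed))
    assert len(dropped) == n - k
    masked = apply_mask(tokens, ratio, "[MASK]", np.random.default_rng(seed))
    assert len(masked) == n
    assert sum(t == "[MASK]" for t in masked) == k


def test_make_view_modes():
    x = "[*]CC(c1ccccc1)[*]"
    assert make_view(x, AugmentationSpec("original"), np.random.default_rng(0)) == x
    enum = make_view(x, AugmentationSpec("enumeration"), np.random.default_rng(0))
    assert canonicalize(enum) == canonicalize(x)
    n = len(tokenize(x))
    drop = make_view(x, AugmentationSpec("drop", ratio=0.1), np.random.default_rng(0))
    assert len(tokenize(drop)) == n - 1
    masked = make_view(x, AugmentationSpec("masking", ratio=0.1), np.random.default_rng(0))
    assert "[MASK]" in masked


def test_make_positive_pairs_structure_and_determinism():
    anchors = generate_polymers(3, rng=np.random.default_rng(5))
    spec_a = AugmentationSpec("enumeration")
    spec_b = AugmentationSpec("masking")
    batch = make_positive_pairs(anchors, spec_a, spec_b, np.random.default_rng(6))
    assert len(batch.views) == 6
    assert batch.pairing == [(0, 3), (1, 4), (2, 5)]
    again = make_positive_pairs(anchors, spec_a, spec_b, np.random.default_rng(6))
    assert batch.views == again.views  # bit-identical under a fixed seed


def test_make_positive_pairs_original_baseline():
    anchors = ["[*]CC[*]", "[*]CCO[*]"]
    spec = AugmentationSpec("original")
    batch = make_positive_pairs(anchors, spec, spec, np.random.default_rng(0))
    assert batch.views[:2] == batch.views[2:] == anchors


def test_make_positive_pairs_aborts_on_invalid_anchor():
    with pytest.raises(ValueError, match="invalid anchor"):
        make_positive_pairs(["[*]CC[*]", "C((C"], AugmentationSpec("original"),
                            AugmentationSpec("original"), np.random.default_rng(0))
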