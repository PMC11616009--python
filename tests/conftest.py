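import numpy as np
import pytest

from polycontrast.encoder import EncoderConfig, PolymerEncoder, Projector, Vocabulary
from polycontrast.synthetic_data import generate_polymers


@pytest.fixture(scope="session")
def small_corpus():
    """64 valid synthetic repeat units, fixed seed."""
    return generate_polymers(64, rng=np.random.default_rng(12345))


@pytest.fixture(scope="session")
def tiny_vocab(small_corpus):
    return Vocabulary.build(small_corpus + ["[MASK]"])


def make_tiny_encoder(vocab, seed=0, hidden=32, heads=2, max_len=96):
    cfg = EncoderConfig(hidden_dim=hidden, n_heads=heads, n_layers=2,
                        max_len=max_len, projection_dim=16)
    return PolymerEncoder(cfg, vocab, seed=seed)


@pytest.fixture()
def tiny_encoder(tiny_vocab):
    return make_tiny_encoder(tiny_vocab)


@pytest.fixture()
def tiny_projector(tiny_encoder):
    cfg = tiny_encoder.config
    return Projector(cfg.hidden_dim, cfg.projection_dim, seed=0)
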