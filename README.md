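# polycontrast

Self-supervised **contrastive representation learning for polymer SMILES**,
built for polymer-informatics researchers who want label-free polymer
representations and a controlled way to study which SMILES augmentations
make contrastive pre-training work.

A polymer repeat unit is written as a SMILES string with two wildcard atoms
`[*]` marking the points where the unit bonds to its neighbours along the
chain (e.g. `[*]CC(Cl)[*]` for polyvinyl chloride). The package provides:

- **Augmentations** that turn one repeat unit *x* into two views
  (*x_i*, *x_j*): *enumeration* (a randomized re-rendering of the same
  molecular graph), token *masking*, token *drop* (both touch
  `max(1, round(0.10·n))` of the *n* tokens by default), the *original*
  identity, and *implicit* augmentation — the encoder's own dropout (rate
  0.1 on hidden states and attention probabilities) so two passes over the
  same string give different embeddings.
- **NT-Xent pre-training.** Views are encoded by a transformer *f*(·),
  `[CLS]`-pooled to the representation *h*, and projected by a two-layer
  MLP *g*(·) to latent vectors *z* where the normalised temperature-scaled
  cross-entropy loss

  ℓ(i,j) = −log [ exp(sim(z_i, z_j)/τ) / Σ_{k≠i} exp(sim(z_i, z_k)/τ) ],  τ = 0.05,

  pulls positive pairs together against the 2(N−1) in-batch negatives
  (symmetrised mean over all 2N directed terms; AdamW, gradient-norm
  clipping at 1.0).
- **Representation diagnostics:** alignment
  E‖f(x) − f(x⁺)‖² over known positive pairs and uniformity
  log E exp(−2‖f(x) − f(y)‖²) over all pairs on the unit hypersphere —
  lower is better for both — traced across training checkpoints.
- **Frozen-encoder transfer learning:** a single-hidden-layer ReLU MLP head
  on frozen pooled representations, 5-fold cross-validation, 500-epoch
  protocol with early stopping (monitor active after epoch 50, patience
  50), reported as held-out RMSE and R²; plus an enumeration stress test
  that feeds non-canonical renderings of every input.
- **A two-step augmentation-combination study:** all 10 unordered pairs of
  explicit modes against the Original–Original baseline, counting per-task
  wins, then the top tier re-run with implicit dropout.
- **Synthetic data generators** (fragment-assembled repeat units,
  descriptor-based property tasks, embedding fixtures) so everything runs
  with no downloads, and a reference regex SMILES tokenizer.

The training engine is a compact numpy reverse-mode autodiff stack
(`polycontrast.nn`) — no GPU or deep-learning framework required.

## Worked example

```python
import numpy as np
from polycontrast import (
    AugmentationSpec, ContrastiveConfig, EncoderConfig, PolymerEncoder,
    Projector, TransferConfig, Vocabulary, build_eval_pairs, evaluate_pairs,
    generate_polymers, generate_property_dataset, run_transfer,
    train_contrastive,
)
from polycontrast.synthetic_data import SyntheticTaskSpec, make_noise_sd

corpus = generate_polymers(2200, rng=np.random.default_rng(42))
train, held_out = corpus[:2000], corpus[2000:]

vocab = Vocabulary.build(corpus + ["[MASK]"])
encoder = PolymerEncoder(EncoderConfig(hidden_dim=64, n_heads=4, max_len=96), vocab, seed=0)
projector = Projector(64, 128, seed=0)
config = ContrastiveConfig(epochs=5, batch_size=64, learning_rate=1e-3, seed=0,
                           checkpoint_cadence=[1.0])

final, traj = train_contrastive(
    train,
    AugmentationSpec("enumeration", implicit_dropout=True),
    AugmentationSpec("masking", implicit_dropout=True),
    encoder, projector, config)

pairs = build_eval_pairs(held_out, np.random.default_rng(7))
before = evaluate_pairs(traj.initial_checkpoint, pairs)
after = evaluate_pairs(final, pairs)
print(f"alignment  {before.alignment_loss:.4f} -> {after.alignment_loss:.4f}")
print(f"uniformity {before.uniformity_loss:.4f} -> {after.uniformity_loss:.4f}")
```

Output (one run on a laptop-class CPU, ~1 min):

```
alignment  0.0233 -> 0.0133
uniformity -0.2563 -> -2.1345
```

Both metrics drop: after five epochs of Enumeration–Masking pre-training
with implicit dropout, enumerated renderings of the same polymer embed
closer together (alignment 0.023 → 0.013) while the embedding cloud
spreads over the hypersphere (uniformity −0.26 → −2.13) — the signature of
a representation that is both invariant to SMILES rendering and
information-preserving. The frozen encoder then transfers:

```python
task = generate_polymers(1000, rng=np.random.default_rng(6))
spec = SyntheticTaskSpec(coefficients=(1.0, -0.8, 2.5), seed=8)
spec.noise_sd = make_noise_sd(task, spec, noise_frac=0.05)
y = generate_property_dataset(task, spec)["y"].to_numpy()
report = run_transfer(task, y, final, TransferConfig(seed=9))
print(f"mean R2 {report.mean_r2:.3f}")   # -> mean R2 0.977
```

A command-line interface mirrors the library
(`polycontrast synth|augment|pretrain|metrics|transfer|grid`); every run
writes a JSON manifest with the resolved configuration and input digests.

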