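# Methods

## Model and objective

The package learns polymer representations by contrastive self-supervision
on repeat-unit SMILES. Each training anchor *x* (a repeat unit with two
`[*]` connection atoms) is turned into two views by per-branch augmentation
recipes; the batch of 2N views is encoded by a transformer *f*(·),
`[CLS]`-pooled to *h*, and projected by a two-layer ReLU MLP *g*(·) to
*z* ∈ R^128. The objective is the symmetrised NT-Xent loss with cosine
similarity and temperature τ = 0.05: each directed term is the softmax
cross-entropy of the positive pair against the 2N−1 other views in the
batch, and the batch loss averages both directions over all N pairs.
Optimisation is AdamW with global gradient-norm clipping at 1.0. Views are
re-augmented fresh every epoch (caching them would collapse stochastic
augmentations to a fixed dataset); a final batch with fewer than two
anchors is dropped because NT-Xent needs at least one negative.

Assumptions: homopolymer repeat units (exactly two `[*]`; a permissive
profile accepting ≥ 1 star is available), and augmented strings need not be
chemically valid — masking and drop operate on the token stream, and the
encoder consumes raw token streams.

## Augmentations

Explicit modes: `original` (identity), `enumeration` (atom order is
permuted with the caller's seeded generator and the molecule re-written
non-canonically, so the molecular graph — hence the label — is unchanged),
`masking` (replace tokens with `[MASK]`), `drop` (delete tokens). For
masking/drop the affected count is k = max(1, round(ratio·n)) at the
default ratio 0.10, rounding half away from zero; the minimum-one rule
prevents a no-op on short monomers. `protect_stars` (default off) exempts
connection tokens, clamping k to the eligible pool. Implicit augmentation
sets the encoder's hidden-state and attention-probability dropout to 0.1
(0.0 when disabled); both branches of a training run must agree on the
implicit flag because dropout is a property of the shared encoder pass.

## Encoder

The reference encoder is a small post-norm transformer trained from random
initialisation (defaults: width 600, 2 layers, 4 heads, feed-forward
2×width, max 128 tokens; desk-scale runs use width 64 or 32). A `[CLS]`
token is prepended by the encoder's own preprocessing, so augmentations
never see it; its final-layer embedding is the pooled representation *h*.
The projector exists only during pre-training — downstream consumers always
use *h*.

One non-standard initialisation choice: the residual-branch output
projections (attention output and second feed-forward matrix) are scaled by
`residual_gain` (default 4) at init. Without it, a freshly initialised
post-norm stack is collapsed — the constant `[CLS]` residual dominates the
content-dependent signal and every input maps to nearly the same pooled
vector (positive-pair alignment ≈ 0.002 against typical pair distances of
the same order). With the gain, distinct inputs are distinguishable from
the start (init alignment ≈ 0.02–0.03, uniformity ≈ −0.3), which is the
regime in which contrastive training can improve both diagnostics at once.

The numerical engine (`polycontrast.nn`) is a reverse-mode autodiff over
numpy arrays written for this package: float32 training tensors, fused
layer-norm/softmax backward passes, AdamW, and global-norm clipping.
Boundary computations (the public NT-Xent function, alignment/uniformity,
RMSE/R²) are float64.

## Representation diagnostics

Alignment is the mean squared Euclidean distance between embeddings of
known positive pairs; uniformity is the log mean Gaussian potential,
log E exp(−t‖·‖²), over all embedding pairs, with t = 2. Rows are
L2-normalised first (the unit-hypersphere framing; exposed as a flag), and
both metrics are computed on pooled *h*, not *z*, so encoders without a
projector can be compared on the same axes. Evaluation pairs are built by
enumerating each held-out polymer once — a semantics-preserving positive.
Uniformity is taken over the union of both pair sides; it is exact up to
5000 embeddings and switches to a seeded pair subsample (logged) above
that. Checkpoints are captured densely early and sparsely late (every 2 %
of total epochs up to 20 %, then every 20 % — 14 checkpoints), because most
movement in the alignment–uniformity plane happens early.

## Transfer learning

The pre-trained encoder is frozen (weights verifiably untouched; encoding
is eval-mode and deterministic) and a single-hidden-layer MLP head
(hidden = input width, ReLU, dropout 0.1) is trained on *h* with AdamW
(lr 1e-3, no weight decay) under an l2 loss: 5-fold seeded shuffled
cross-validation, at most 500 epochs, early stopping monitoring the
held-out-fold l2 loss from epoch 50 with patience 50 and best-epoch weights
restored. No hyperparameter is tuned. Two harness choices the protocol
leaves open: features and target are z-scored on each training fold
(predictions mapped back to label units before computing RMSE/R²), because
the fixed learning rate presumes unit-scale inputs; and the head trains in
minibatches of 64 — full-batch training of very small heads occasionally
stalls in poor optima. The enumeration stress test replaces every input
SMILES with a randomized rendering before encoding, touching nothing else.

## Augmentation-combination study

Step 1 trains one model per unordered pair of explicit modes (10 pairs,
alphabetically canonicalized; Original–Original is the baseline) from an
identical initialisation, corpus and seed, evaluates each by frozen
transfer on every task with shared fold assignments, and counts tasks where
a combination's mean R² strictly exceeds the baseline's (ties are not
wins). Step 2 re-runs combinations with wins ≥ n_tasks − 1 (configurable)
with implicit dropout in both branches; the default mixed selection
includes Enumeration–Masking, the flagship recipe.

## Synthetic data

The corpus generator assembles repeat units from divalent backbone
fragments (alkylene, ether, amine, ester, amide, thioether, arylene,
cyclohexylene) with monovalent side groups grafted as branches, capped with
two `[*]`. Assembly guarantees chemical validity and gives structural
descriptors real variance. Property tasks are linear in graph-level
descriptors (aromatic atoms, heteroatoms, rings, heavy atoms) plus Gaussian
noise; because descriptors depend only on the molecular graph, every
enumerated rendering of a polymer has the same label, which is what makes
enumeration a testable semantics-preserving augmentation end to end. The
default evaluation task uses coefficients (1.0, −0.8, 2.5) on the first
three descriptors with noise at 5 % of the signal standard deviation.

What the generator does *not* emulate: the property distributions, sizes
and noise structure of real polymer datasets (band gap, electron affinity,
dielectric constant, …), tokenizer/vocabulary scale of large pre-trained
encoders, or copolymer/polyelectrolyte chemistry. Passing tests therefore
demonstrate that the machinery is correct and that the contrastive recipe
behaves as designed on learnable structure — not that any particular
real-data accuracy will be reached.

## Problem sizes and numerical choices

Desk-scale defaults used by the test suite and the acceptance script:
pre-training on 2000 generated polymers for 5 epochs, batch 64, width-64
encoder, evaluated on 200 held-out enumeration pairs; transfer on 1000
labelled polymers; the full 10-combination grid on a 256-polymer corpus
with a width-32 encoder. Desk-scale pre-training from random init uses
learning rate 1e-3 (the 1e-5 config default is the published fine-tuning
regime for a large pre-trained prior and moves a small random-init model
too little in a few epochs). Checkpoints store float32 weights plus config
and vocabulary in one `.npz` file. Degenerate inputs: zero vectors are
rejected by cosine similarity and row normalisation; constant targets make
R² undefined (error); τ ≤ 0 and ratio ≥ 1 are parameter errors; a
mixed-precision flag is accepted for config compatibility but the float
engine ignores it with a warning.

## Known limitations

- The engine is CPU/numpy; throughput is adequate for desk-scale studies,
  not for million-polymer corpora.
- Only `[CLS]` pooling is implemented.
- The tokenizer is a regex reference implementation (injectable), not a
  learned subword vocabulary.
- `run_grid` retrains one model per combination sequentially; at realistic
  scale this is the dominant cost and would want parallelism.
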