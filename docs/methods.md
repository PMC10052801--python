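# Methods

## Overview

`ligandgen` implements a sequence-conditioned molecular generator. The
generative core is a conditional Wasserstein GAN with gradient penalty
(WGAN-GP) that operates in the latent space of a SMILES autoencoder. A
protein target enters the model as a fixed-length embedding produced by a
masked-token Transformer encoder; a perception layer projects that
embedding into a common condition space. The generator receives standard
normal noise `z` concatenated with the condition `c` and emits a molecular
latent `S = G(z, c)`; the frozen decoder of the autoencoder maps `S` to a
SMILES string.

The three learned components are trained in sequence:

1. **Protein encoder** — a Transformer (post-norm blocks, learned positional
   embeddings) pretrained by masked-token prediction over the 22-letter
   amino-acid alphabet. Random residue positions (`ceil(0.15·n)`, never
   control tokens, at least one) are replaced by `[MASK]` and predicted with
   cross-entropy on masked positions only. The prediction head covers 23
   classes: the 22 residues plus the unknown fallback, so an untrained,
   near-uniform head scores `ln 23 ≈ 3.135`. A sequence embedding is the
   mean-pooled final hidden state over non-pad positions, linearly projected
   to the feature dimension. At full scale the encoder is 12 layers × 512
   hidden × 8 heads with a 756-d output feature; the feature dimension is an
   explicit, independent projection knob because 756 does not follow from a
   512-d hidden state by any stated recipe.
2. **SMILES autoencoder** — one-hot token sequences (29 chemistry tokens +
   pad/start/end/unknown, greedy longest-match tokenization) pass through a
   2-layer bidirectional LSTM encoder; the final-step outputs of the two
   top-layer directions are concatenated and linearly projected to the
   latent. A 4-layer LSTM decoder is conditioned by the latent through
   learned **linear** maps that initialise every layer's hidden and cell
   state, and is trained with teacher forcing. (A squashing nonlinearity on
   the state maps was tried first and slowed convergence badly; the latent
   is otherwise not re-injected at later timesteps.) Generation is
   autoregressive: greedy or multinomial with temperature; control tokens
   other than end-of-sequence are masked out of the softmax. After training
   the decoder is frozen (parameters excluded from all later graphs and
   checksummed) so adversarial training cannot move it.
3. **Conditional WGAN-GP** — the critic has a shared MLP trunk on the latent
   with two heads: an unconditional head (is the latent from the encoder's
   distribution over real molecules?) and a conditional head on the trunk
   features concatenated with `c` (does this molecule belong with this
   target?). The critic loss is the two-head Wasserstein estimate plus a
   gradient penalty `λ_gp · E[(‖∇_x̂(D(x̂) + D(x̂,c))‖₂ − 1)²]` computed on
   the *combined* score at interpolates `x̂ = ε·x_real + (1−ε)·x_fake`. The
   generator loss offers two conventions: `wasserstein` (default)
   `−½E[D(x)] − ½E[D(x,c)]`, and `as_printed`, the log form with a sigmoid
   squashing the critic scores first — the log form is otherwise undefined
   for an unbounded critic. Training alternates `n_critic = 5` critic
   updates per generator update (Adam, β = (0.5, 0.9)).

### Supervised contrastive term

The generator objective adds `λ_scl · L_SCL`, a supervised contrastive loss
over the batch: with `Φ(x_i)` the L2-normalised final hidden layer of the
generator and `y_i` the target label,

```
L_SCL = Σ_i  −1/(N_{y_i}−1) Σ_{j≠i, y_j=y_i}
        log[ exp(Φ(x_i)·Φ(x_j)/τ) / Σ_{k≠i} exp(Φ(x_i)·Φ(x_k)/τ) ]
```

Anchors whose label has no second batch member contribute zero (the 1/(N-1)
normaliser would be undefined); batches are sampled label-stratified so
this is rare. Two closed-form checks pin the implementation: the symmetric
4-sample batch (two labels, orthogonal unit embeddings) gives
`4·log(1 + 2/e) ≈ 2.2058`, and a batch of N identical same-label embeddings
gives `N·log(N−1)`. Defaults: `τ = 0.1`, `λ_scl = 1.0`, `λ_gp = 10.0` (the
WGAN-GP reference value); the loss-weight symbol is deliberately split into
`λ_scl` and `λ_gp` because the two roles are distinct.

## Data curation

Raw (SMILES, sequence, activity) tables are reduced in a fixed order:

1. per-target median binarization — label 1 iff activity **strictly**
   exceeds the target's sample median (ties → 0; configurable);
2. label-0 rows removed;
3. SMILES sanitization: salts dropped (largest fragment by heavy-atom
   count, ties broken by lexicographic canonical SMILES), stereochemistry
   erased, canonicalization; rejected if unparseable, carbon-free
   ("inorganic"), or containing elements outside {C, N, S, O, F, Cl, Br, H};
4. strings that do not tokenize under the 29-token vocabulary removed;
5. proteins with residues outside the 22-letter alphabet (e.g. X) removed;
6. exact (SMILES, sequence) duplicates dropped, first occurrence kept.

A ledger counts every removal per rule and asserts
`n_in = n_out + Σ dropped` on every call. Note that strict-median
labelling caps the label-1 fraction of any target at one half, so at most
half of a raw table can survive step 2.

## Synthetic study conditions

All experiments run on synthetic fixtures with known ground truth:

- **Molecule families**: a scaffold per target (benzene, thiophene,
  piperidine, … — the leading scaffolds chosen chemically distinct so
  neighbouring families separate in latent space) decorated with one or two
  substituents from a small pool {C, N, O, F, Cl, CC, CO, CN}. Fixture
  strings are ≤ 14 tokens. Enumeration order is seeded; the scaffold itself
  is always the first member.
- **Sequences**: per-target motifs of length 6 repeated to a length in
  [30, 100], with optional noisy variants (5% point substitutions, edge
  crops) to give embedding experiments within-family structure.
- **Latent ground truth**: per-target isotropic Gaussians
  `N(mean_t, scale²·I)` whose means sit on a regular simplex with a single
  separation parameter (default scale 0.5). Activities are distinct
  uniforms so per-target medians are well defined and exactly half of an
  even-sized target exceeds its median.

What the generator does **not** emulate: real bioactivity distributions,
assay noise, ChEMBL-scale chemical diversity, or any sequence–chemistry
coupling beyond the target identity itself. Passing tests therefore
demonstrate that the machinery recovers planted structure at desk scale,
not that the method reproduces production-scale results on real corpora.

## Bundled experiments and their sizes

Problem sizes are chosen so the full suite trains every component from
scratch on one CPU core in minutes:

- **Masked-LM benchmark**: two 6-residue motif families, 40 training + 8
  held-out variant sequences (2% substitution noise), 300 steps at 2 layers × 64 hidden × 2 heads.
  Expected: held-out masked-token accuracy > 0.8 and ≥ 50% loss reduction.
- **Autoencoder benchmark**: 500 molecules (5 scaffolds × 100), 10% held
  out, test-scale model (encoder 2×128 bidirectional units, decoder 4×64,
  latent 48, max length 16), batch 50, Adam 3e-3 stepped down ×1/3 at 50%
  and ×2/15 at 83% of the epoch budget (early stop at 0.92).
  The fine-lr tail is what converts low token loss into exact-string
  reconstruction (budget 380 epochs). Expected: ≥ 90% held-out exact
  reconstruction.
- **Conditional recovery**: two ground-truth latent Gaussians 4 apart
  (scale 0.5), one-hot conditions, 3000 generator steps with the learning
  rate stepped down at 60% and 85% of the budget. The contrastive
  weight is zero here so the experiment isolates the adversarial
  conditioning path; expected per-condition generated means within 0.5 of
  truth and ≥ 90% nearest-mean classification.
- **Contrastive ablation**: three targets, identical seeds, `λ_scl` 1 vs 0;
  the within/between-condition distance ratio of generated latents must be
  strictly smaller with the term on.
- **End-to-end pipeline** (test profile): 3 targets × 100 molecules,
  protein encoder 150 steps, autoencoder 500 epochs on the full simulated
  molecule corpus (the label filter gates only what the GAN sees as real
  latents, mirroring the method's use of a large separate corpus for
  autoencoder pretraining), GAN 800 generator steps, ~1000 molecules
  decoded. Expected ≥ 30% valid SMILES (typically ~50–70%).
- **Zero-shot conditioning**: for each training target a motif variant
  (unseen sequence) conditions generation; generated latents are assigned
  to the nearest family mean (autoencoder latent mean of each target's
  molecule family). Expected ≥ 60% average assignment to the parent
  family. With a handful of mutually unrelated synthetic targets there is
  no mechanism for extrapolating to a wholly novel family, so the held-out
  sequences are paralog-like relatives — the desk-scale analogue of
  removing one protein from training while its neighbours remain.

## Numerical and design notes

- **Autodiff engine**: the models run on a compact reverse-mode autodiff
  engine over numpy arrays (`ligandgen.nn`). Backward rules are written in
  terms of the engine's own ops, so gradients are differentiable again —
  the gradient penalty's double backward uses this. The LSTM cell's gate
  nonlinearities are fused into one numba kernel with a hand-derived
  backward (first-order only; nothing differentiates through an LSTM
  twice). Sequences travel through LSTM layers as per-timestep lists
  because slicing a packed (B, T, D) tensor per step would scatter into
  full-size zero buffers every timestep.
- Parameters are float32; loss comparisons against brute-force oracles run
  in float64 (the engine follows input dtype).
- LSTM forget-gate biases initialise to 1; other weights use uniform
  Glorot-style fan-in/fan-out bounds.
- Decoding never emits pad/start/unknown tokens (logits masked to −∞);
  multinomial decoding at temperature < 1e-6 falls back to greedy exactly.
- Encoder/critic/generator determinism: evaluation-mode forward passes are
  pure functions of parameters and inputs (the models use no dropout), so
  repeated calls are bit-identical; every stochastic routine takes an
  explicit seed and the pipeline derives per-stage seeds from the global
  seed by hashing the stage name.
- Metric identity is structure-level: canonical SMILES before all set
  comparisons. Unique@k truncates the valid stream in generation order.
  Novelty is computed over distinct valid generated molecules. Tanimoto
  uses 2048-bit radius-2 Morgan fingerprints. SAscore and NP-likeness come
  from the fragment-contribution scorers shipped with RDKit's Contrib tree;
  their values depend on those published fragment tables (single-atom
  molecules, for instance, score *hard* on SA because every fragment is
  rare — methane scores ≈ 7.3).

## Known limitations

- The held-out-reconstruction and zero-shot numbers are specific to the
  fixture grammar; they say nothing about reconstruction of arbitrary
  drug-like SMILES at this model scale.
- The `as_printed` generator loss keeps the log-form adversarial
  objective available but is not the training default; with an unbounded
  WGAN critic the log form needs the sigmoid squashing and trains less
  stably.
- The engine is single-threaded CPU code; full-scale dimensions (512-d
  latents, 12-layer encoders, ChEMBL-scale corpora) are configurable but
  not practical in it.
- Whether Φ in the contrastive term should be a separate projection head
  rather than the generator's final hidden layer is ambiguous in the
  method's description; the latter is implemented.
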