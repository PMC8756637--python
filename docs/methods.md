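# Methods

## The model

`pairedvae` fits a multi-view variational autoencoder to joint single-cell
profiles: for each cell, gene-expression UMI counts `x ∈ N^G` and
chromatin-accessibility fragment counts over peaks, presented to the model
as a TF-IDF-transformed vector `y ∈ R^P`.  Both modalities are generated
from one low-dimensional latent code `z ∈ R^D` whose prior is a K-component
Gaussian mixture:

    c ~ Cat(π),      z | c ~ N(μ_c, diag(σ_c²))

so that mixture components play the role of cell populations and the
cluster posterior p(c|z) is available in closed form (responsibilities
normalised in log-space).

Observation laws:

- **RNA**: negative binomial, parameterised as a Gamma(shape α, rate
  β)–Poisson mixture.  The decoder emits per-cell, per-gene (α, β) through
  softplus links; the marginal law has the closed form
  `log P(x) = lgamma(x+α) − lgamma(x+1) − lgamma(α) + α·log(β/(1+β)) −
  x·log(1+β)`, mean α/β and variance mean + mean²/α.  Imputed expression is
  the Gamma mean α/β.
- **ATAC**: zero-inflated Poisson on the discretised TF-IDF target
  (`round` by default; `floor`/`raw` exposed in the config).  The decoder
  emits a Poisson rate μ (softplus) and a non-dropout probability τ
  (sigmoid clamped to [ε, 1−ε]); `P(y=0) = (1−τ) + τe^{−μ}`,
  `P(y=k) = τ·Poisson(k; μ)` for k>0.

## Architecture

The encoder is asymmetric.  The RNA branch is a mask-attention block:
linear(G→128) → layer-norm → batch-norm → ReLU, multiplied elementwise by a
softmax gate computed from the same 128-dim hidden layer.  The ATAC branch
is linear(P→128) → batch-norm → ReLU followed by multi-head self-attention
(8 heads × 16 dims) with a residual skip and layer normalisation.  Because
a cell enters the network as a single vector, the attention operates over
*hidden-unit groups*: the 128-unit activation is viewed as 8 tokens of 16
dims; each head projects queries/keys/values per token (16×16 maps),
attends across the 8 tokens with scaled dot-product weights (scale √16),
and the concatenated heads are projected back to 16 dims per token.  The
two branch outputs are concatenated (256), passed through a shared 256-dim
linear layer and a 128-dim layer (ReLU), and two linear heads emit the
posterior mean and log-variance of the 10-dim latent code
(σ = exp(½·logvar), floored at 1e-4; reparameterised sample z = μ + σ⊙ε).

The decoders mirror the branches.  The RNA channel is
MLP(D→128) → layer-norm → batch-norm, gated by softmax(MLP(z)); the ATAC
channel is MLP(D→128) → batch-norm → self-attention with residual →
layer-norm.  Both channels' final 128-unit activations are additionally
weighted by a *cluster-attention* vector softmax(linear(p(c|z))), K→128,
which injects the mixture assignment into the generative path.  Output
heads apply softplus (rates, floored at 1e-8) or clamped sigmoid
(probabilities).

Every elementwise softmax gate (mask attention and cluster attention) is
scaled by its width H.  A softmax over H=128 units sums to 1, so the raw
gate would shrink activations by ~1/H — and decoder channels are gated
twice — starving downstream Glorot-initialised layers of signal; the H
factor makes the uniform gate the identity while preserving the normalised
attention pattern, and is absorbable into the following linear layer, so
the represented model family is unchanged.  Without this conditioning fix
the optimiser reliably converges to embeddings with merged populations on
data that a linear baseline separates perfectly.

Two auxiliary single-channel encoders share the structure (not the
weights) of the corresponding encoder branch.  They embed (i) the imputed
single-modality profiles and (ii) the raw single-modality inputs, and both
posteriors are pulled toward the joint posterior by closed-form
diagonal-Gaussian KL terms (the cycle-consistency loss and its raw-data
regulariser; weight λ, default 1).  Gradients flow through the imputations
into the decoders by default (`detach_imputed` disables this for
ablations).

## Objective

The per-cell objective is

    L = −log NB(x | α, β) − log ZIP(ŷ | μ, τ) + β_KL·KL̂ + λ·L_consistency

where KL̂ is the single-sample estimate `log q(z|x,y) − log Σ_c π_c N(z|μ_c,σ_c)`
evaluated at the decoded sample (the KL direction is q‖p, as the
variational lower bound requires; no closed form exists against a
mixture), and L_consistency sums the auxiliary-encoder KLs.  All reported
loss-table entries are per-cell means of the unweighted terms.

## Training schedule

Adam, minibatch 128, learning rate 5e-3, 30 epochs — with the first 5
epochs a warm-up under a standard-normal prior.  At the end of warm-up a
diagonal-covariance Gaussian mixture is fit by EM (scikit-learn, seeded,
3 restarts) to the warm-up posterior means and installs the prior
parameters (π, μ_c, σ_c), which remain free to move under gradient descent
afterwards unless frozen by config.  Cluster-attention inputs during
warm-up are uniform responsibilities.

Two numerical choices matter for stability at this learning rate and data
scale and are this package's own:

- **Output-bias initialisation.**  Softplus heads start near 0.7 regardless
  of data scale; the decoder rate-head biases are therefore initialised at
  softplus⁻¹ of per-feature marginal means (for ATAC at 2× the target mean,
  since τ starts at ½), so optimisation starts at the feature-marginal null
  model and spends its budget on per-cell structure.
- **KL annealing.**  The prior-KL weight β_KL ramps linearly from 0 to 1
  over the first `kl_anneal_epochs` (default 15) epochs.  Without it the
  encoder collapses to the prior before the decoders become informative
  (textbook posterior collapse); the reported loss table always shows the
  unweighted KL.
- Gradient clipping (global norm 500) is available as a guard; measured
  gradient norms on the reference problem sit well below it.

## Synthetic data

The generator mirrors the model's assumptions: K component means placed at
exact mutual distance `cluster_separation` (scaled orthonormal directions;
exact whenever K ≤ D), unit-variance Gaussian latent codes, softplus-linked
fixed linear maps to gene means (scaled by a log-normal per-cell depth
factor, σ=0.3) and to peak rates, Gamma–Poisson gene counts (shape 2), and
Poisson peak counts thinned by structural dropout (probability 0.5).
Defaults — 2000 cells, 500 genes, 2000 peaks, K=4, separation 8 — give
roughly 62% RNA zeros and 79% ATAC zeros, sparsity in the range of real
joint-profiling assays, and are the conditions of the package's headline
recovery experiment.  What the simulator does *not* emulate: batch effects,
doublets, peak–gene linkage (cis-regulation), non-linear latent geometry,
and read-level noise; passing tests therefore demonstrate correct recovery
of mixture-structured data of the model's own family, not performance on
any real assay.

## Evaluation protocol

Clustering is K-means (k-means++, 10 restarts, seeded) on the posterior
mean embedding, scored by adjusted Rand index computed from exact integer
pair counts.  Imputation is scored per cell by Pearson correlation against
the simulator's noiseless means, with 10% of nonzero RNA entries zeroed at
input as a held-out set; the comparison baseline is the raw (masked) input.
ATAC recovery uses the expected signal under the fitted ZIP law (τ·μ):
with a presence-based TF-IDF target the value-if-present is essentially
idf_j·scale/n_i — deterministic given presence — so presence probability,
the quantity that tracks accessibility, is carried by τ, and μ alone
reflects mostly the IDF weighting.  τ·μ is mapped back through the
deterministic TF-IDF weighting (`tfidf_inverse`) before correlating with
count-scale rates.

## Numerical details and limitations

- All tensors are float32 by default (float64 via config, used by the
  gradient-check tests); likelihood floors: rates 1e-8, probabilities 1e-6,
  scales 1e-4.
- The automatic-differentiation engine is a compact tape-based
  reverse-mode implementation over numpy; every primitive is
  finite-difference-tested, and an end-to-end central-difference check on
  the full objective guards the composition.
- Determinism: one `numpy` Generator seeded from `TrainConfig.seed` drives
  initialisation, shuffling and reparameterisation draws; identical seeds
  reproduce losses, embeddings and cluster assignments bit-for-bit on one
  thread (BLAS reductions are deterministic at these sizes).
- TF-IDF uses binarised term frequency, IDF = log(1 + N/df), scale 1e4
  (variant and scale configurable).  Zeros are preserved exactly.
- `estimate_k` (eigenvalues of the cell–cell correlation matrix against a
  permutation null) is a labelled heuristic for choosing K when no
  annotation exists; the primary path is user-specified K.
- Known limitations: no explicit batch covariate; no RNA zero-inflation;
  no transfer of new cells beyond plain encoding; training cost grows
  linearly in features × cells on CPU (the reference experiment, 2000
  cells × 2500 features × 30 epochs, runs in a few minutes single-threaded).
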