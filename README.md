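# pairedvae

A multi-view deep generative model for **paired single-cell RNA + ATAC
profiles** — assays such as SNARE-seq, sci-CAR, Paired-seq, SHARE-seq and
10x Multiome that measure gene expression and chromatin accessibility in
the *same* cell.  `pairedvae` learns one low-dimensional embedding from
both modalities and uses it for cell clustering and for denoising
(imputing) each modality, addressing the extreme sparsity of joint
profiling data.

It is intended for computational biologists who want a transparent,
dependency-light (numpy/scipy/scikit-learn; no GPU framework)
implementation of the model to study, extend, or run on data at desk
scale.

## The model

Each cell's expression counts `x ∈ N^G` and TF-IDF-transformed peak vector
`y ∈ R^P` are generated from a shared latent code `z ∈ R^D` (D = 10) with a
Gaussian-mixture prior whose K components play the role of cell
populations:

    c ~ Cat(π)                    z | c ~ N(μ_c, diag σ_c²)
    α_x, β_x = Decoder_x(z)       x ~ NB   (Gamma(α_x, β_x)–Poisson)
    μ_y, τ_y = Decoder_y(z)       y ~ ZIP(μ_y, τ_y)

The encoder is asymmetric: a mask-attention channel for RNA and a
multi-head self-attention channel for ATAC, joined into the posterior
q(z|x,y) = N(μ_z, diag σ_z²).  Decoder channels mirror the encoder and are
weighted by a cluster-attention vector computed from the responsibilities
p(c|z).  Training maximises the evidence lower bound plus a cycle-GAN-like
clustering-consistency penalty: the imputed profiles (Gamma mean α/β for
RNA, Poisson mean μ for ATAC) are re-embedded by auxiliary single-channel
encoders and pulled toward the joint posterior by closed-form Gaussian KLs.
Optimisation follows the published schedule — Adam, minibatch 128,
learning rate 5e-3, 30 epochs — with the mixture prior initialised by EM
on a short warm-up embedding.  Full derivations, parameter tables and
numerical choices are in [docs/methods.md](docs/methods.md).

Because real joint-profiling datasets require external downloads, the
package ships a first-class simulator (`simulate_joint`) that draws paired
counts from exactly this generative family with known ground truth, so
every claim — clustering accuracy, imputation gain — is scored against a
planted truth.

## Worked example

`examples/02_train_and_cluster.py` simulates 500 cells (200 genes, 400
peaks, four populations), trains the joint model for 20 epochs and
clusters the embedding:

```
 epoch phase       total
    16  main 1724.644849
    17  main 1537.360163
    18  main 1387.689413
    19  main 1268.845268
    20  main 1179.743179

joint-embedding ARI vs planted populations: 0.945
```

The per-epoch `total` is the per-cell mean of the objective (negative
log-likelihoods of both modalities + prior KL + consistency KL); the ARI
(adjusted Rand index) of 0.945 means K-means on the learned 10-dim
embedding recovers the four planted populations almost perfectly
(1 = exact recovery, 0 = chance).

`examples/03_imputation.py` additionally hides 10% of the nonzero RNA
entries at input and scores denoising:

```
mean per-cell r (imputed vs true means):  0.852
mean per-cell r (raw input vs true means): 0.567
fraction of cells where imputation wins:   0.994
MSE on held-out entries: imputed 1.082 vs raw 4.890
```

Imputed expression correlates with the true (noiseless) per-cell means far
better than the sparse raw counts do, for 99% of cells, and reconstructs
the held-out entries with a quarter of the raw error.

The other examples cover the simulator (`01`) and the probability
primitives (`04`).  A thin CLI wraps the same functions:

```bash
pairedvae simulate --n-cells 2000 --out sim/
pairedvae train --rna sim/rna --atac sim/atac --k 4 --min-features 0 --min-cells 0 --out model/
pairedvae encode --rna sim/rna --atac sim/atac --checkpoint model/model.npz --out emb/
pairedvae cluster --embedding emb/embedding.tsv --k 4 --out clusters.tsv
pairedvae evaluate --clusters clusters.tsv --labels sim/labels.tsv
```

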