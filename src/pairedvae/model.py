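"""The multi-view generative model.

A cell's gene-expression counts ``x`` and TF-IDF-transformed accessibility
``y`` are modelled as draws from a negative-binomial and a zero-inflated
Poisson law, conditioned on a shared low-dimensional latent code ``z`` with
a K-component Gaussian-mixture prior:

    c ~ Cat(pi),   z | c ~ N(mu_c, diag(sigma_c^2))
    alpha_x, beta_x = Decoder_x(z)        x ~ NB (Gamma(alpha, beta)-Poisson)
    mu_y, tau_y     = Decoder_y(z)        y ~ ZIP(mu_y, tau_y)

The encoder is asymmetric: the RNA branch is a mask-attention gated MLP, the
ATAC branch a multi-head self-attention block; both feed a shared layer that
emits the posterior mean and log-variance of ``z``.  Decoder channels are
weighted by a cluster-attention vector computed from the mixture
responsibilities p(c|z).  Two auxiliary single-channel encoders embed the
imputed (and raw) single modalities and are pulled toward the joint
posterior by closed-form Gaussian KL consistency terms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import logsumexp as np_logsumexp
from sklearn.mixture import GaussianMixture

from . import nn
from .autodiff import Tensor, no_grad, softmax, logsumexp, concatenate
from .likelihoods import (
    nb_log_pmf_t,
    zip_log_pmf_t,
    diag_gaussian_log_density_t,
    diag_gaussian_kl_t,
)

__all__ = [
    "ModelConfig",
    "GMMPrior",
    "LatentPosterior",
    "RNADecoderOutput",
    "ATACDecoderOutput",
    "LossReport",
    "MultiViewVAE",
    "cluster_posterior",
    "init_gmm_prior",
    "elbo_terms",
    "consistency_loss",
    "impute",
    "estimate_k",
    "save_checkpoint",
    "load_checkpoint",
]


# ----------------------------------------------------------------- containers
@dataclass
class ModelConfig:
    """Architecture and numerical settings.

    ``latent_dim`` 10, hidden width 128, shared layer 256 and 8 attention
    heads of 16 dimensions are the published defaults; ``K`` is the expected
    number of cell populations and must be set by the user (or estimated
    with :func:`estimate_k`).
    """

    K: int = 4
    latent_dim: int = 10
    hidden_dim: int = 128
    shared_dim: int = 256
    n_heads: int = 8
    head_dim: int = 16
    lambda_consistency: float = 1.0
    zip_target_mode: str = "round"          # {"round", "floor", "raw"}
    eps_rate: float = 1e-8
    eps_prob: float = 1e-6
    sigma_floor: float = 1e-4
    trainable_prior: bool = True
    detach_imputed: bool = False            # detach imputations in the cycle loss
    modality: str = "joint"                 # {"joint", "rna", "atac"}
    dtype: str = "float32"

    def __post_init__(self):
        if self.n_heads * self.head_dim != self.hidden_dim:
            raise ValueError("n_heads * head_dim must equal hidden_dim")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.modality not in ("joint", "rna", "atac"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.zip_target_mode not in ("round", "floor", "raw"):
            raise ValueError(f"unknown zip_target_mode {self.zip_target_mode!r}")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class GMMPrior:
    """Mixture weights and diagonal-Gaussian component parameters."""

    K: int
    log_pi: np.ndarray      # (K,)
    mu: np.ndarray          # (K, D)
    sigma: np.ndarray       # (K, D), floored

    def __post_init__(self):
        self.log_pi = np.asarray(self.log_pi, dtype=np.float64)
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=np.float64))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=np.float64))
        if self.log_pi.shape != (self.K,):
            raise ValueError("log_pi must have shape (K,)")
        if self.mu.shape[0] != self.K or self.sigma.shape != self.mu.shape:
            raise ValueError("mu/sigma must have shape (K, D)")
        total = np.exp(np_logsumexp(self.log_pi))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mixture weights sum to {total}, not 1")
        if np.any(self.sigma < 1e-4 - 1e-12):
            raise ValueError("sigma below the 1e-4 floor")

    @classmethod
    def standard_normal(cls, D: int) -> "GMMPrior":
        return cls(K=1, log_pi=np.zeros(1), mu=np.zeros((1, D)), sigma=np.ones((1, D)))


@dataclass
class LatentPosterior:
    """Per-cell approximate posterior over the common embedding."""

    mu_z: np.ndarray
    sigma_z: np.ndarray
    z_sample: np.ndarray
    resp: np.ndarray

    def __post_init__(self):
        if np.any(self.sigma_z <= 0):
            raise ValueError("sigma_z must be strictly positive")
        rowsum = self.resp.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-5) or np.any(self.resp < 0):
            raise ValueError("responsibilities must be non-negative and sum to 1")


@dataclass
class RNADecoderOutput:
    alpha: np.ndarray    # Gamma shape, cells x genes
    beta: np.ndarray     # Gamma rate, cells x genes


@dataclass
class ATACDecoderOutput:
    mu: np.ndarray       # Poisson rate, cells x peaks
    tau: np.ndarray      # non-dropout probability, cells x peaks


@dataclass
class LossReport:
    """Per-cell mean loss terms for one batch or epoch."""

    nll_rna: float
    nll_atac: float
    kl_prior: float
    kl_consistency: float
    lambda_consistency: float
    n_cells: int

    @property
    def total(self) -> float:
        return (self.nll_rna + self.nll_atac + self.kl_prior
                + self.lambda_consistency * self.kl_consistency)


# ------------------------------------------------------------- free functions
def cluster_posterior(z: np.ndarray, prior: GMMPrior) -> np.ndarray:
    """Responsibilities p(c|z) ∝ pi_c N(z | mu_c, diag(sigma_c^2)).

    Computed in log-space with a log-sum-exp normalisation per cell.
    """
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    d = (z[:, None, :] - prior.mu[None]) / prior.sigma[None]
    log_n = -0.5 * (d * d).sum(-1) - np.log(prior.sigma).sum(-1)[None] \
        - 0.5 * prior.mu.shape[1] * np.log(2 * np.pi)
    logits = prior.log_pi[None] + log_n
    return np.exp(logits - np_logsumexp(logits, axis=1, keepdims=True))


def init_gmm_prior(embeddings: np.ndarray, K: int, seed: int,
                   sigma_floor: float = 1e-4) -> GMMPrior:
    """Fit a diagonal-covariance Gaussian mixture by EM on warm-up embeddings.

    Deterministic given ``seed``.  A mixture with a vanishing component is
    refit with a fresh derived seed, at most 5 times.
    """
    embeddings = np.asarray(embeddings, dtype=np.float64)
    if embeddings.shape[0] < K:
        raise ValueError("need at least K cells to fit a K-component mixture")
    last_exc = None
    for attempt in range(5):
        gm = GaussianMixture(n_components=K, covariance_type="diag",
                             random_state=int(seed) + attempt, n_init=3,
                             reg_covar=1e-6, max_iter=200)
        gm.fit(embeddings)
        if np.all(gm.weights_ > 1e-8):
            sigma = np.maximum(np.sqrt(gm.covariances_), sigma_floor)
            return GMMPrior(K=K, log_pi=np.log(gm.weights_), mu=gm.means_, sigma=sigma)
        last_exc = ValueError(f"degenerate mixture component on attempt {attempt}")
    raise last_exc


def elbo_terms(x: np.ndarray, y_target: np.ndarray, posterior: LatentPosterior,
               rna_out: RNADecoderOutput | None, atac_out: ATACDecoderOutput | None,
               prior: GMMPrior) -> LossReport:
    """Reference (numpy) evaluation of the ELBO terms for one forward pass.

    ``nll`` terms are negative log-likelihood sums over features; the prior
    term is the single-sample Monte-Carlo estimate
    ``log q(z|x,y) - log p_mixture(z)`` evaluated at ``posterior.z_sample``.
    All terms are returned as per-cell means (sums / n_cells).
    """
    n = posterior.mu_z.shape[0]
    nll_rna = 0.0
    if rna_out is not None:
        ll = nb_log_pmf_t(Tensor(np.asarray(x, dtype=np.float64)),
                          Tensor(rna_out.alpha.astype(np.float64)),
                          Tensor(rna_out.beta.astype(np.float64))).data
        nll_rna = float(-ll.sum()) / n
    nll_atac = 0.0
    if atac_out is not None:
        ll = zip_log_pmf_t(Tensor(np.asarray(y_target, dtype=np.float64)),
                           Tensor(atac_out.mu.astype(np.float64)),
                           Tensor(atac_out.tau.astype(np.float64))).data
        nll_atac = float(-ll.sum()) / n
    kl = _kl_prior_np(posterior.z_sample, posterior.mu_z, posterior.sigma_z, prior)
    return LossReport(nll_rna=nll_rna, nll_atac=nll_atac, kl_prior=float(kl.sum()) / n,
                      kl_consistency=0.0, lambda_consistency=0.0, n_cells=n)


def _kl_prior_np(z, mu_z, sigma_z, prior: GMMPrior) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    dq = (z - mu_z) / sigma_z
    log_q = -0.5 * (dq * dq).sum(-1) - np.log(sigma_z).sum(-1) \
        - 0.5 * z.shape[1] * np.log(2 * np.pi)
    d = (z[:, None, :] - prior.mu[None]) / prior.sigma[None]
    log_n = -0.5 * (d * d).sum(-1) - np.log(prior.sigma).sum(-1)[None] \
        - 0.5 * z.shape[1] * np.log(2 * np.pi)
    log_p = np_logsumexp(prior.log_pi[None] + log_n, axis=1)
    return log_q - log_p


def consistency_loss(posterior_raw: LatentPosterior,
                     posterior_from_imputed_rna: LatentPosterior | None,
                     posterior_from_imputed_atac: LatentPosterior | None) -> float:
    """Cycle-consistency penalty: KL(q(z|x,y) || q(z|x_impute)) + KL(q(z|x,y) || q(z|y_impute)).

    Closed-form diagonal-Gaussian KL per cell, averaged over the batch.
    """
    n = posterior_raw.mu_z.shape[0]
    total = np.zeros(n)
    for aux in (posterior_from_imputed_rna, posterior_from_imputed_atac):
        if aux is None:
            continue
        if aux.mu_z.shape != posterior_raw.mu_z.shape:
            raise ValueError("posterior shape mismatch")
        total = total + diag_gaussian_kl_t(
            Tensor(posterior_raw.mu_z.astype(np.float64)),
            Tensor(posterior_raw.sigma_z.astype(np.float64)),
            Tensor(aux.mu_z.astype(np.float64)),
            Tensor(aux.sigma_z.astype(np.float64))).data
    return float(total.mean())


def impute(rna_out: RNADecoderOutput | None, atac_out: ATACDecoderOutput | None):
    """Imputed profiles: the Gamma mean ``alpha/beta`` for RNA and the
    Poisson mean ``mu`` for ATAC."""
    imputed_rna = rna_out.alpha / rna_out.beta if rna_out is not None else None
    imputed_atac = atac_out.mu.copy() if atac_out is not None else None
    return imputed_rna, imputed_atac


def estimate_k(matrix: np.ndarray, n_permutations: int = 20, seed: int = 0,
               max_cells: int = 500) -> int:
    """Heuristic component count: eigenvalues of the cell-cell Pearson
    correlation matrix exceeding a permutation-null 95th percentile."""
    rng = np.random.default_rng(seed)
    X = np.asarray(matrix, dtype=np.float64)
    if X.shape[0] > max_cells:
        X = X[rng.choice(X.shape[0], max_cells, replace=False)]
    C = np.corrcoef(X)
    C = np.nan_to_num(C)
    ev = np.sort(np.linalg.eigvalsh(C))[::-1]
    null_top = []
    for _ in range(n_permutations):
        Xp = np.apply_along_axis(rng.permutation, 0, X)
        Cp = np.nan_to_num(np.corrcoef(Xp))
        null_top.append(np.sort(np.linalg.eigvalsh(Cp))[::-1])
    thresh = np.percentile(np.asarray(null_top), 95, axis=0)
    return max(int(np.sum(ev > thresh[: len(ev)])), 1)


# --------------------------------------------------------------- sub-networks
def _gate(logits: Tensor) -> Tensor:
    """Softmax attention gate scaled by its width.

    The softmax over H hidden units sums to 1, so the raw gate would shrink
    activations by ~1/H and starve downstream Glorot-initialised layers of
    signal; multiplying by H makes the uniform gate the identity while
    keeping the normalised attention pattern.
    """
    return softmax(logits, axis=-1) * float(logits.shape[-1])


class _RNABranch(nn.Module):
    """linear(G->H) -> layer-norm -> batch-norm -> ReLU, gated by a softmax
    mask-attention vector computed from the first hidden layer.

    Encoder inputs are log1p-transformed (variance stabilisation for
    heavy-tailed counts); the observation likelihood stays on raw targets.
    """

    def __init__(self, n_in, hidden, rng, dtype):
        super().__init__()
        self.lin = nn.Linear(n_in, hidden, rng, dtype=dtype)
        self.ln = nn.LayerNorm(hidden, dtype=dtype)
        self.bn = nn.BatchNorm1d(hidden, dtype=dtype)
        self.mask = nn.Linear(hidden, hidden, rng, dtype=dtype)

    def __call__(self, x):
        h = self.lin(x.log1p())
        a = self.bn(self.ln(h)).relu()
        return a * _gate(self.mask(h))


class _ATACBranch(nn.Module):
    """linear(P->H) -> batch-norm -> ReLU -> multi-head self-attention with
    residual skip -> layer-norm."""

    def __init__(self, n_in, hidden, n_heads, head_dim, rng, dtype):
        super().__init__()
        self.lin = nn.Linear(n_in, hidden, rng, dtype=dtype)
        self.bn = nn.BatchNorm1d(hidden, dtype=dtype)
        self.mha = nn.MultiHeadSelfAttention(hidden, n_heads, head_dim, rng, dtype=dtype)
        self.ln = nn.LayerNorm(hidden, dtype=dtype)

    def __call__(self, y):
        a = self.bn(self.lin(y.log1p())).relu()
        return self.ln(a + self.mha(a))


class _Encoder(nn.Module):
    """One or two modality branches -> shared layer -> (mu, logvar) heads."""

    def __init__(self, branches: list, hidden, shared, latent, rng, dtype):
        super().__init__()
        self.branches = branches
        in_dim = hidden * len(branches)
        self.shared = nn.Linear(in_dim, shared, rng, dtype=dtype)
        self.mid = nn.Linear(shared, hidden, rng, dtype=dtype)
        self.head_mu = nn.Linear(hidden, latent, rng, dtype=dtype)
        self.head_logvar = nn.Linear(hidden, latent, rng, dtype=dtype)

    def __call__(self, inputs: list):
        feats = [branch(x) for branch, x in zip(self.branches, inputs)]
        h = feats[0] if len(feats) == 1 else concatenate(feats, axis=-1)
        h = self.shared(h).relu()
        h = self.mid(h).relu()
        return self.head_mu(h), self.head_logvar(h)


class _RNADecoder(nn.Module):
    """Mask-attention decoder channel emitting Gamma shape/rate heads."""

    def __init__(self, latent, hidden, n_out, K, rng, dtype, eps_rate):
        super().__init__()
        self.mlp = nn.Linear(latent, hidden, rng, dtype=dtype)
        self.ln = nn.LayerNorm(hidden, dtype=dtype)
        self.bn = nn.BatchNorm1d(hidden, dtype=dtype)
        self.mask = nn.Linear(latent, hidden, rng, dtype=dtype)
        self.cluster_attn = nn.Linear(K, hidden, rng, dtype=dtype)
        self.head_alpha = nn.Linear(hidden, n_out, rng, dtype=dtype)
        self.head_beta = nn.Linear(hidden, n_out, rng, dtype=dtype)
        self.eps_rate = eps_rate

    def hidden_activation(self, z, resp):
        u = self.bn(self.ln(self.mlp(z))) * _gate(self.mask(z))
        return u * _gate(self.cluster_attn(resp))

    def __call__(self, z, resp):
        u = self.hidden_activation(z, resp)
        alpha = self.head_alpha(u).softplus() + self.eps_rate
        beta = self.head_beta(u).softplus() + self.eps_rate
        return alpha, beta


class _ATACDecoder(nn.Module):
    """Self-attention decoder channel emitting ZIP rate/probability heads."""

    def __init__(self, latent, hidden, n_out, K, n_heads, head_dim, rng, dtype,
                 eps_rate, eps_prob):
        super().__init__()
        self.mlp = nn.Linear(latent, hidden, rng, dtype=dtype)
        self.bn = nn.BatchNorm1d(hidden, dtype=dtype)
        self.mha = nn.MultiHeadSelfAttention(hidden, n_heads, head_dim, rng, dtype=dtype)
        self.ln = nn.LayerNorm(hidden, dtype=dtype)
        self.cluster_attn = nn.Linear(K, hidden, rng, dtype=dtype)
        self.head_mu = nn.Linear(hidden, n_out, rng, dtype=dtype)
        self.head_tau = nn.Linear(hidden, n_out, rng, dtype=dtype)
        self.eps_rate = eps_rate
        self.eps_prob = eps_prob

    def hidden_activation(self, z, resp):
        a = self.bn(self.mlp(z))
        h = self.ln(a + self.mha(a))
        return h * _gate(self.cluster_attn(resp))

    def __call__(self, z, resp):
        h = self.hidden_activation(z, resp)
        mu = self.head_mu(h).softplus() + self.eps_rate
        tau = self.head_tau(h).sigmoid() * (1.0 - 2 * self.eps_prob) + self.eps_prob
        return mu, tau


# ------------------------------------------------------------------ the model
class MultiViewVAE(nn.Module):
    """Joint encoder, cluster-attention decoders, auxiliary encoders and the
    trainable mixture prior, wired per :class:`ModelConfig`."""

    def __init__(self, n_genes: int, n_peaks: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.n_genes = n_genes
        self.n_peaks = n_peaks
        dt = cfg.np_dtype
        H, D, K = cfg.hidden_dim, cfg.latent_dim, cfg.K

        self.use_rna = cfg.modality in ("joint", "rna")
        self.use_atac = cfg.modality in ("joint", "atac")

        branches = []
        if self.use_rna:
            branches.append(_RNABranch(n_genes, H, rng, dt))
        if self.use_atac:
            branches.append(_ATACBranch(n_peaks, H, cfg.n_heads, cfg.head_dim, rng, dt))
        self.encoder = _Encoder(branches, H, cfg.shared_dim, D, rng, dt)

        self.dec_rna = _RNADecoder(D, H, n_genes, K, rng, dt, cfg.eps_rate) if self.use_rna else None
        self.dec_atac = (_ATACDecoder(D, H, n_peaks, K, cfg.n_heads, cfg.head_dim,
                                      rng, dt, cfg.eps_rate, cfg.eps_prob)
                         if self.use_atac else None)

        # auxiliary single-channel encoders (same structure as the branch, own weights)
        self.aux_rna = (_Encoder([_RNABranch(n_genes, H, rng, dt)], H, cfg.shared_dim,
                                 D, rng, dt) if self.use_rna else None)
        self.aux_atac = (_Encoder([_ATACBranch(n_peaks, H, cfg.n_heads, cfg.head_dim,
                                               rng, dt)], H, cfg.shared_dim, D, rng, dt)
                         if self.use_atac else None)

        # mixture prior, standard-normal start; overwritten by EM initialisation
        self.prior_logit_pi = nn.Parameter(np.zeros(K, dtype=dt))
        self.prior_mu = nn.Parameter(rng.standard_normal((K, D)).astype(dt) * 0.01)
        self.prior_log_sigma = nn.Parameter(np.zeros((K, D), dtype=dt))
        self.standard_prior = True   # warm-up phase flag

    # ------------------------------------------------------------- init helpers
    def init_output_bias(self, rna_mean: np.ndarray | None,
                         atac_target_mean: np.ndarray | None):
        """Start the decoder rate heads at the per-feature marginal means.

        With softplus links, zero-initialised heads emit rates near 0.7
        regardless of the data scale, so early optimisation is spent fitting
        marginal magnitudes rather than structure.  Setting the head biases
        to softplus^{-1} of the observed per-feature means puts the initial
        reconstruction at the null (feature-marginal) model, which the
        warm-up phase then only has to modulate per cell.
        """
        def softplus_inv(v):
            v = np.clip(np.asarray(v, dtype=np.float64), 1e-3, None)
            # softplus_inv(v) ~ v for large v; expm1 overflows past ~700
            small = np.minimum(v, 30.0)
            return np.where(v > 30.0, v, np.log(np.expm1(small)))

        dt = self.cfg.np_dtype
        if self.dec_rna is not None and rna_mean is not None:
            # Gamma mean alpha/beta: alpha ~ 1, beta ~ 1/mean
            self.dec_rna.head_alpha.b.data = np.full(
                self.n_genes, softplus_inv(1.0), dtype=dt)
            self.dec_rna.head_beta.b.data = softplus_inv(
                1.0 / np.clip(rna_mean, 1e-3, None)).astype(dt)
        if self.dec_atac is not None and atac_target_mean is not None:
            # ZIP observed mean tau*mu with tau starting at 1/2
            self.dec_atac.head_mu.b.data = softplus_inv(
                2.0 * atac_target_mean).astype(dt)

    # ------------------------------------------------------------------ prior
    def set_prior(self, prior: GMMPrior):
        dt = self.cfg.np_dtype
        if prior.K != self.cfg.K:
            raise ValueError("prior component count differs from model K")
        self.prior_logit_pi.data = prior.log_pi.astype(dt)
        self.prior_mu.data = prior.mu.astype(dt)
        self.prior_log_sigma.data = np.log(prior.sigma).astype(dt)
        self.standard_prior = False

    def get_prior(self) -> GMMPrior:
        if self.standard_prior:
            return GMMPrior.standard_normal(self.cfg.latent_dim)
        log_pi = self.prior_logit_pi.data.astype(np.float64)
        log_pi = log_pi - np_logsumexp(log_pi)
        sigma = np.maximum(np.exp(self.prior_log_sigma.data.astype(np.float64)),
                           self.cfg.sigma_floor)
        return GMMPrior(K=self.cfg.K, log_pi=log_pi, mu=self.prior_mu.data.astype(np.float64),
                        sigma=sigma)

    def _prior_tensors(self):
        log_pi = self.prior_logit_pi - logsumexp(self.prior_logit_pi, axis=0, keepdims=True)
        sigma = self.prior_log_sigma.exp() + self.cfg.sigma_floor
        return log_pi, self.prior_mu, sigma

    def responsibilities_t(self, z: Tensor) -> Tensor:
        """Differentiable p(c|z) under the current prior, (B, K)."""
        if self.standard_prior:
            return Tensor(np.full((z.shape[0], self.cfg.K),
                                  1.0 / self.cfg.K, dtype=z.data.dtype))
        log_pi, mu, sigma = self._prior_tensors()
        zb = z.reshape(z.shape[0], 1, z.shape[1])
        d = (zb - mu) / sigma
        log_n = (d * d).sum(axis=-1) * (-0.5) - sigma.log().sum(axis=-1) \
            - 0.5 * self.cfg.latent_dim * np.log(2 * np.pi)
        return softmax(log_n + log_pi, axis=-1)

    def kl_prior_t(self, z: Tensor, mu_z: Tensor, sigma_z: Tensor) -> Tensor:
        """Single-sample estimate log q(z|x,y) - log p(z) per cell, (B,)."""
        log_q = diag_gaussian_log_density_t(z, mu_z, sigma_z)
        if self.standard_prior:
            zero = Tensor(np.zeros(1, dtype=z.data.dtype))
            one = Tensor(np.ones(1, dtype=z.data.dtype))
            log_p = diag_gaussian_log_density_t(z, zero, one)
        else:
            log_pi, mu, sigma = self._prior_tensors()
            zb = z.reshape(z.shape[0], 1, z.shape[1])
            d = (zb - mu) / sigma
            log_n = (d * d).sum(axis=-1) * (-0.5) - sigma.log().sum(axis=-1) \
                - 0.5 * self.cfg.latent_dim * np.log(2 * np.pi)
            log_p = logsumexp(log_n + log_pi, axis=-1)
        return log_q - log_p

    # ---------------------------------------------------------------- encoding
    def _encoder_inputs(self, x: Tensor | None, y: Tensor | None) -> list:
        inputs = []
        if self.use_rna:
            inputs.append(x)
        if self.use_atac:
            inputs.append(y)
        return inputs

    def posterior_t(self, x, y, eps: np.ndarray | None):
        """Forward the joint encoder; ``eps=None`` forces z = mu (deterministic)."""
        mu, logvar = self.encoder(self._encoder_inputs(x, y))
        sigma = (logvar * 0.5).exp() + self.cfg.sigma_floor
        if eps is None:
            z = mu
        else:
            z = mu + sigma * Tensor(eps.astype(mu.data.dtype))
        resp = self.responsibilities_t(z)
        return mu, sigma, z, resp

    def encode(self, x: np.ndarray, y: np.ndarray | None, eps=None,
               batch_size: int = 1024) -> LatentPosterior:
        """Eval-mode posterior for a full matrix of cells (numpy in/out)."""
        was_training = self.training
        self.eval()
        mus, sigmas, zs, resps = [], [], [], []
        n = (x if x is not None else y).shape[0]
        with no_grad():
            for lo in range(0, n, batch_size):
                hi = min(lo + batch_size, n)
                xt = Tensor(np.asarray(x[lo:hi], dtype=self.cfg.np_dtype)) if self.use_rna else None
                yt = Tensor(np.asarray(y[lo:hi], dtype=self.cfg.np_dtype)) if self.use_atac else None
                e = None if eps is None else eps[lo:hi]
                mu, sigma, z, resp = self.posterior_t(xt, yt, e)
                mus.append(mu.data); sigmas.append(sigma.data)
                zs.append(z.data); resps.append(resp.data)
        if was_training:
            self.train()
        return LatentPosterior(mu_z=np.concatenate(mus), sigma_z=np.concatenate(sigmas),
                               z_sample=np.concatenate(zs), resp=np.concatenate(resps))

    def decode(self, posterior: LatentPosterior):
        """Eval-mode decoder outputs for an encoded batch (numpy in/out)."""
        was_training = self.training
        self.eval()
        rna_out = atac_out = None
        with no_grad():
            z = Tensor(posterior.z_sample.astype(self.cfg.np_dtype))
            resp = Tensor(posterior.resp.astype(self.cfg.np_dtype))
            if self.dec_rna is not None:
                a, b = self.dec_rna(z, resp)
                rna_out = RNADecoderOutput(alpha=a.data, beta=b.data)
            if self.dec_atac is not None:
                m, t = self.dec_atac(z, resp)
                atac_out = ATACDecoderOutput(mu=m.data, tau=t.data)
        if was_training:
            self.train()
        return rna_out, atac_out

    # -------------------------------------------------------------------- loss
    def zip_target(self, y_tfidf: np.ndarray) -> np.ndarray:
        mode = self.cfg.zip_target_mode
        if mode == "round":
            return np.round(y_tfidf)
        if mode == "floor":
            return np.floor(y_tfidf)
        return y_tfidf

    def loss_t(self, x: np.ndarray | None, y_tfidf: np.ndarray | None,
               rng: np.random.Generator, with_consistency: bool = True,
               kl_weight: float = 1.0):
        """Training objective on one minibatch.  Returns (total, terms-dict)
        of per-cell-mean tensors; ``total`` carries the full graph.

        ``kl_weight`` scales the prior KL in the optimised objective (the
        reported term stays unweighted); the trainer anneals it from 0 to 1
        across the warm-up epochs to prevent posterior collapse.
        """
        dt = self.cfg.np_dtype
        n = (x if x is not None else y_tfidf).shape[0]
        xt = Tensor(np.asarray(x, dtype=dt)) if self.use_rna else None
        yt = Tensor(np.asarray(y_tfidf, dtype=dt)) if self.use_atac else None
        eps = rng.standard_normal((n, self.cfg.latent_dim))
        mu, sigma, z, resp = self.posterior_t(xt, yt, eps)

        zero = Tensor(np.zeros(()))
        nll_rna = nll_atac = zero
        rna_mean_t = atac_mean_t = None
        if self.use_rna:
            alpha, beta = self.dec_rna(z, resp)
            nll_rna = -nb_log_pmf_t(xt, alpha, beta).sum() / float(n)
            rna_mean_t = alpha / beta
        if self.use_atac:
            mu_y, tau_y = self.dec_atac(z, resp)
            y_target = Tensor(self.zip_target(np.asarray(y_tfidf)).astype(dt))
            nll_atac = -zip_log_pmf_t(y_target, mu_y, tau_y).sum() / float(n)
            atac_mean_t = mu_y

        kl_prior = self.kl_prior_t(z, mu, sigma).sum() / float(n)

        kl_cons = zero
        if with_consistency:
            terms = []
            if self.use_rna:
                imp = rna_mean_t.detach() if self.cfg.detach_imputed else rna_mean_t
                terms.append(self._aux_kl(self.aux_rna, imp, mu, sigma))
                terms.append(self._aux_kl(self.aux_rna, xt, mu, sigma))
            if self.use_atac:
                imp = atac_mean_t.detach() if self.cfg.detach_imputed else atac_mean_t
                terms.append(self._aux_kl(self.aux_atac, imp, mu, sigma))
                terms.append(self._aux_kl(self.aux_atac, yt, mu, sigma))
            for t in terms:
                kl_cons = kl_cons + t

        total = (nll_rna + nll_atac + kl_weight * kl_prior
                 + self.cfg.lambda_consistency * kl_cons)
        return total, {"nll_rna": nll_rna, "nll_atac": nll_atac,
                       "kl_prior": kl_prior, "kl_consistency": kl_cons}

    def _aux_kl(self, aux: _Encoder, inp: Tensor, mu_joint: Tensor, sigma_joint: Tensor):
        mu_a, logvar_a = aux([inp])
        sigma_a = (logvar_a * 0.5).exp() + self.cfg.sigma_floor
        return diag_gaussian_kl_t(mu_joint, sigma_joint, mu_a, sigma_a).mean()

    def aux_posterior(self, aux_name: str, data: np.ndarray) -> LatentPosterior:
        """Eval-mode posterior of one auxiliary single-channel encoder."""
        aux = {"rna": self.aux_rna, "atac": self.aux_atac}[aux_name]
        was_training = self.training
        self.eval()
        with no_grad():
            mu, logvar = aux([Tensor(np.asarray(data, dtype=self.cfg.np_dtype))])
            sigma = (logvar * 0.5).exp() + self.cfg.sigma_floor
        if was_training:
            self.train()
        resp = cluster_posterior(mu.data, self.get_prior())
        return LatentPosterior(mu_z=mu.data, sigma_z=sigma.data, z_sample=mu.data.copy(),
                               resp=resp)


# -------------------------------------------------------------- checkpointing
def save_checkpoint(model: MultiViewVAE, path: str):
    """Single-file archive of every parameter/buffer plus config and prior."""
    state = model.state_dict()
    meta = {"config": asdict(model.cfg), "n_genes": model.n_genes,
            "n_peaks": model.n_peaks, "standard_prior": model.standard_prior}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str) -> MultiViewVAE:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = ModelConfig(**meta["config"])
    model = MultiViewVAE(meta["n_genes"], meta["n_peaks"], cfg,
                         np.random.default_rng(0))
    model.load_state_dict(state)
    model.standard_prior = meta["standard_prior"]
    return model
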