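"""Two-phase optimisation of the multi-view VAE.

Phase 1 (warm-up) optimises the ELBO under a fixed standard-normal latent
prior so an embedding exists at all; a diagonal-covariance Gaussian mixture
is then fit by EM on the warm-up posterior means to initialise the K
component prior.  Phase 2 optimises the full constrained objective:
reconstruction + mixture-prior KL + cycle-consistency KLs, where each step
also feeds the raw single-modality data through the corresponding auxiliary
encoder and pulls its posterior toward the joint one (the raw-data
regularisation that guards against overfitting the imputation cycle).

Defaults follow the published schedule: Adam, minibatch 128, learning rate
5e-3, 30 epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import JointProfile, tfidf_transform
from .model import LossReport, ModelConfig, MultiViewVAE, init_gmm_prior
from .nn import Adam

log = logging.getLogger("pairedvae")

__all__ = ["TrainConfig", "TrainResult", "train", "convergence_report"]


@dataclass
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 5e-3
    max_epochs: int = 30
    warmup_epochs: int = 5
    optimizer: str = "adam"
    seed: int = 0
    early_stop_patience: int | None = None
    grad_clip_norm: float | None = 500.0
    kl_anneal_epochs: int = 15
    output_bias_init: bool = True

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 <= self.warmup_epochs < self.max_epochs):
            raise ValueError("need 0 <= warmup_epochs < max_epochs")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class TrainResult:
    model: MultiViewVAE
    losses: pd.DataFrame        # one row per epoch: phase + per-cell-mean terms
    n_steps: int


def _dense(m):
    return np.asarray(m.todense()) if hasattr(m, "todense") else np.asarray(m)


def train(jp: JointProfile, model_cfg: ModelConfig, train_cfg: TrainConfig) -> TrainResult:
    """Fit the model on a (filtered, TF-IDF-transformed) joint profile.

    Deterministic given ``train_cfg.seed``: parameter initialisation,
    shuffling and the reparameterisation draws all derive from it.
    """
    if jp.n_cells == 0:
        raise ValueError("empty joint profile")
    use_rna = model_cfg.modality in ("joint", "rna")
    use_atac = model_cfg.modality in ("joint", "atac")
    x = _dense(jp.rna_counts).astype(np.float64) if use_rna else None
    y = None
    if use_atac:
        tfidf = jp.atac_tfidf if jp.atac_tfidf is not None else tfidf_transform(jp.atac_counts)
        y = _dense(tfidf).astype(np.float64)

    rng = np.random.default_rng(train_cfg.seed)
    model = MultiViewVAE(len(jp.gene_ids), len(jp.peak_ids), model_cfg, rng)
    if train_cfg.output_bias_init:
        model.init_output_bias(x.mean(axis=0) if x is not None else None,
                               model.zip_target(y).mean(axis=0) if y is not None else None)
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate,
               clip_norm=train_cfg.grad_clip_norm)

    n = jp.n_cells
    rows = []
    n_steps = 0
    best = np.inf
    stale = 0
    for epoch in range(1, train_cfg.max_epochs + 1):
        warmup = epoch <= train_cfg.warmup_epochs
        # KL annealing: ramp the prior-KL weight to 1 so the encoder stays
        # informative (and the trainable prior can track the forming
        # embedding) while reconstruction shapes the representation
        kl_weight = min(1.0, epoch / max(train_cfg.kl_anneal_epochs, 1))
        order = rng.permutation(n)
        acc = {"nll_rna": 0.0, "nll_atac": 0.0, "kl_prior": 0.0, "kl_consistency": 0.0}
        n_batches = 0
        model.train()
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo: lo + train_cfg.batch_size]
            xb = x[idx] if x is not None else None
            yb = y[idx] if y is not None else None
            total, terms = model.loss_t(xb, yb, rng, with_consistency=not warmup,
                                        kl_weight=kl_weight)
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}")
            opt.zero_grad()
            total.backward()
            opt.step()
            total.zero_graph()
            for k in acc:
                acc[k] += terms[k].item()
            n_batches += 1
            n_steps += 1
        report = LossReport(
            nll_rna=acc["nll_rna"] / n_batches,
            nll_atac=acc["nll_atac"] / n_batches,
            kl_prior=acc["kl_prior"] / n_batches,
            kl_consistency=acc["kl_consistency"] / n_batches,
            lambda_consistency=0.0 if warmup else model_cfg.lambda_consistency,
            n_cells=n)
        rows.append({"epoch": epoch, "phase": "warmup" if warmup else "main",
                     "nll_rna": report.nll_rna, "nll_atac": report.nll_atac,
                     "kl_prior": report.kl_prior, "kl_consistency": report.kl_consistency,
                     "total": report.total})
        log.info("epoch %3d [%s] total=%.4f rna=%.4f atac=%.4f klp=%.4f cons=%.4f",
                 epoch, rows[-1]["phase"], report.total, report.nll_rna,
                 report.nll_atac, report.kl_prior, report.kl_consistency)

        if epoch == train_cfg.warmup_epochs:
            post = model.encode(x, y)
            prior = init_gmm_prior(post.mu_z, model_cfg.K, train_cfg.seed,
                                   sigma_floor=model_cfg.sigma_floor)
            model.set_prior(prior)
            if not model_cfg.trainable_prior:
                for p in (model.prior_logit_pi, model.prior_mu, model.prior_log_sigma):
                    p.requires_grad = False
            log.info("initialised %d-component mixture prior from warm-up embedding",
                     model_cfg.K)

        if train_cfg.early_stop_patience is not None and not warmup:
            if rows[-1]["total"] < best - 1e-6:
                best = rows[-1]["total"]
                stale = 0
            else:
                stale += 1
                if stale >= train_cfg.early_stop_patience:
                    log.info("early stop at epoch %d", epoch)
                    break

    model.eval()
    return TrainResult(model=model, losses=pd.DataFrame(rows), n_steps=n_steps)


def convergence_report(loss_table: pd.DataFrame, rel_tol: float = 1e-3,
                       window: int = 3) -> dict:
    """Epoch at which the relative total-loss change stays below ``rel_tol``
    for ``window`` consecutive epochs, or ``"not converged"``."""
    if len(loss_table) < 2:
        raise ValueError("need at least 2 epochs to assess convergence")
    totals = loss_table["total"].to_numpy(dtype=np.float64)
    epochs = loss_table["epoch"].to_numpy()
    denom = np.maximum(np.abs(totals[:-1]), 1e-12)
    rel = np.abs(np.diff(totals)) / denom
    stable = rel < rel_tol
    run = 0
    for i, s in enumerate(stable):
        run = run + 1 if s else 0
        if run >= window:
            return {"converged": True, "epoch": int(epochs[i + 1]),
                    "final_total": float(totals[-1])}
    return {"converged": False, "epoch": None, "final_total": float(totals[-1])}
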