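"""Count likelihoods and Gaussian divergences used by the generative model.

The RNA observation law is the negative binomial obtained by marginalising a
Gamma(shape ``alpha``, rate ``beta``) prior over a Poisson mean:

    log P(x) = lgamma(x+a) - lgamma(x+1) - lgamma(a)
               + a*log(b/(1+b)) + x*log(1/(1+b))

with mean ``alpha/beta`` and over-dispersion ``var = mean + mean^2/alpha``.
The ATAC observation law is a zero-inflated Poisson: with probability
``1-tau`` the entry is a structural zero, otherwise it is Poisson(``mu``).

All functions are implemented on the autodiff :class:`~pairedvae.autodiff.Tensor`
so they can sit inside the training objective; the public numpy entry points
validate their inputs and return plain arrays.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "nb_log_pmf",
    "zip_log_pmf",
    "nb_log_pmf_t",
    "zip_log_pmf_t",
    "diag_gaussian_log_density_t",
    "diag_gaussian_kl",
    "diag_gaussian_kl_t",
]


# --------------------------------------------------------------- tensor forms
def nb_log_pmf_t(x: Tensor, alpha: Tensor, beta: Tensor) -> Tensor:
    """Gamma–Poisson (negative binomial) log-pmf, differentiable in alpha/beta."""
    one = 1.0
    log_b_ratio = (beta / (one + beta)).log()
    log_inv = -(one + beta).log()
    xt = x if isinstance(x, Tensor) else Tensor(x)
    return ((xt + alpha).lgamma() - (xt + one).lgamma() - alpha.lgamma()
            + alpha * log_b_ratio + xt * log_inv)


def zip_log_pmf_t(y: Tensor, mu: Tensor, tau: Tensor) -> Tensor:
    """Zero-inflated Poisson log-pmf, differentiable in mu/tau.

    y > 0: log(tau) + y*log(mu) - mu - lgamma(y+1)
    y = 0: log((1-tau) + tau*exp(-mu)), evaluated stably.
    """
    yt = y if isinstance(y, Tensor) else Tensor(y)
    log_pois = yt * mu.log() - mu - (yt + 1.0).lgamma()
    log_pos = tau.log() + log_pois
    # zero branch: log(1-tau + tau*e^{-mu}); both terms in (0,1], direct log1p-style
    log_zero = ((1.0 - tau) + tau * (-mu).exp()).log()
    mask = (yt.data > 0)
    return log_pos * Tensor(mask.astype(log_pos.dtype)) + log_zero * Tensor((~mask).astype(log_zero.dtype))


def diag_gaussian_log_density_t(z: Tensor, mu: Tensor, sigma: Tensor, axis: int = -1) -> Tensor:
    """Sum of per-dimension N(z | mu, sigma^2) log-densities along ``axis``."""
    d = (z - mu) / sigma
    return (-0.5 * (d * d) - sigma.log() - 0.5 * np.log(2.0 * np.pi)).sum(axis=axis)


def diag_gaussian_kl_t(mu1: Tensor, sigma1: Tensor, mu2: Tensor, sigma2: Tensor) -> Tensor:
    """Closed-form KL(N(mu1, sigma1^2) || N(mu2, sigma2^2)), summed over the last axis."""
    v1 = sigma1 * sigma1
    v2 = sigma2 * sigma2
    d = mu1 - mu2
    term = (v2.log() - v1.log() + (v1 + d * d) / v2 - 1.0) * 0.5
    return term.sum(axis=-1)


# ---------------------------------------------------------------- numpy forms
def _validate_counts(x, name):
    x = np.asarray(x)
    if np.any(x < 0):
        raise ValueError(f"{name} must be non-negative")
    if not np.allclose(x, np.round(x)):
        raise ValueError(f"{name} must be integer-valued")
    return x.astype(np.float64)


def nb_log_pmf(x, alpha, beta) -> np.ndarray:
    """Negative-binomial log-pmf of the Gamma(shape a, rate b)–Poisson mixture.

    Parameters
    ----------
    x : array-like of non-negative integers
    alpha, beta : array-like, strictly positive Gamma shape and rate

    Returns
    -------
    Log-probabilities with the broadcast shape of the inputs.
    """
    x = _validate_counts(x, "x")
    alpha = np.asarray(alpha, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    if np.any(alpha <= 0) or np.any(beta <= 0):
        raise ValueError("alpha and beta must be strictly positive")
    out = nb_log_pmf_t(Tensor(x), Tensor(alpha), Tensor(beta))
    return out.data


def zip_log_pmf(y, mu, tau) -> np.ndarray:
    """Zero-inflated Poisson log-pmf: dropout probability 1-tau, rate mu."""
    y = _validate_counts(y, "y")
    mu = np.asarray(mu, dtype=np.float64)
    tau = np.asarray(tau, dtype=np.float64)
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    if np.any((tau <= 0) | (tau >= 1)):
        raise ValueError("tau must lie strictly inside (0, 1)")
    out = zip_log_pmf_t(Tensor(y), Tensor(mu), Tensor(tau))
    return out.data


def diag_gaussian_kl(mu1, sigma1, mu2, sigma2) -> np.ndarray:
    """Closed-form diagonal-Gaussian KL, summed over the last axis (numpy)."""
    out = diag_gaussian_kl_t(Tensor(np.asarray(mu1, dtype=np.float64)),
                             Tensor(np.asarray(sigma1, dtype=np.float64)),
                             Tensor(np.asarray(mu2, dtype=np.float64)),
                             Tensor(np.asarray(sigma2, dtype=np.float64)))
    return out.data
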