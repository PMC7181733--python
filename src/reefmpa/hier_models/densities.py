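"""Exact log densities used by the model likelihoods.

The Gamma density is parameterized by its mean μ and shape k (so that
E[y] = μ and Var[y] = μ²/k), i.e. shape k and rate k/μ in the standard
parameterization.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_LOG_2PI = float(np.log(2.0 * np.pi))


def log_density_normal(y, mu, sigma):
    """Normal log density; vectorized; σ must be positive."""
    sigma = np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    z = (y - mu) / sigma
    return -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * z * z


def log_density_gamma_mean_shape(y, mu, k):
    """Gamma(mean=μ, shape=k) log density; vectorized; all arguments positive.

    f(y) = (k/μ)^k y^(k−1) e^(−k y/μ) / Γ(k); k = 1 reduces to an
    Exponential with mean μ.
    """
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    k = np.asarray(k, float)
    if np.any(y <= 0) or np.any(mu <= 0) or np.any(k <= 0):
        raise ValueError("y, mu and k must all be > 0")
    return k * (np.log(k) - np.log(mu)) - gammaln(k) + (k - 1.0) * np.log(y) - k * y / mu


def log_prior_normal_coef(beta, scale: float = 10.0):
    """N(0, scale) prior log density, summed over coefficients."""
    beta = np.asarray(beta, float)
    return float(np.sum(-0.5 * _LOG_2PI - np.log(scale) - 0.5 * (beta / scale) ** 2))


def log_prior_half_cauchy(x, scale: float = 2.0):
    """half-Cauchy(0, scale) log density, summed; support x > 0."""
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise ValueError("half-Cauchy support is x > 0")
    return float(np.sum(np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2)))


def log_prior_exponential(x, rate: float = 1.0):
    """Exponential(rate) log density, summed; support x > 0."""
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise ValueError("Exponential support is x > 0")
    return float(np.sum(np.log(rate) - rate * x))
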