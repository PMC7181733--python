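"""Hamiltonian Monte Carlo with step-size and mass adaptation.

A deliberately compact, fully seeded sampler: leapfrog integration with a
jittered number of steps, dual-averaging step-size adaptation toward a
target acceptance rate during warmup, and a diagonal mass matrix estimated
from the second warmup phase. Chains are independent (spawned seeds) and
runs are reproducible bit-for-bit given the same seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PosteriorSamples:
    """MCMC draws with chain structure.

    ``draws`` holds post-warmup iterations only, shaped
    (n_chains, n_iter − warmup, n_params).
    """

    draws: np.ndarray
    param_names: list[str]
    n_iter: int
    warmup: int
    seed: int
    accept_rate: np.ndarray  # per chain
    divergences: int = 0
    step_size: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def flat(self) -> np.ndarray:
        """Draws pooled over chains, shape (chains × draws, params)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def to_arviz(self):
        import arviz as az

        return az.from_dict(posterior={name: self.draws[:, :, i] for i, name in enumerate(self.param_names)})


def _value_and_grad_fn(log_posterior, grad, fd_eps: float = 1e-6):
    if hasattr(log_posterior, "value_and_grad"):
        return log_posterior.value_and_grad
    if grad is not None:
        return lambda q: (float(log_posterior(q)), np.asarray(grad(q), float))

    def numeric(q):
        f0 = float(log_posterior(q))
        g = np.empty_like(q)
        for i in range(q.size):
            step = fd_eps * max(1.0, abs(q[i]))
            qp = q.copy()
            qp[i] += step
            qm = q.copy()
            qm[i] -= step
            g[i] = (float(log_posterior(qp)) - float(log_posterior(qm))) / (2 * step)
        return f0, g

    return numeric


def _find_initial_step(vg, q0, rng, inv_mass):
    """Double/halve until one leapfrog step has acceptance near 0.5."""
    eps = 0.1
    logp0, grad0 = vg(q0)
    p = rng.standard_normal(q0.size) / np.sqrt(inv_mass)
    h0 = logp0 - 0.5 * float(np.sum(p * p * inv_mass))
    p1 = p + 0.5 * eps * grad0
    q1 = q0 + eps * inv_mass * p1
    logp1, grad1 = vg(q1)
    p1 = p1 + 0.5 * eps * grad1
    h1 = logp1 - 0.5 * float(np.sum(p1 * p1 * inv_mass))
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        p1 = p + 0.5 * eps * grad0
        q1 = q0 + eps * inv_mass * p1
        logp1, _ = vg(q1)
        if not np.isfinite(logp1):
            h1 = -np.inf
        else:
            _, grad1 = vg(q1)
            p2 = p1 + 0.5 * eps * grad1
            h1 = logp1 - 0.5 * float(np.sum(p2 * p2 * inv_mass))
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


def _run_chain(vg, q0, n_iter, warmup, rng, max_leapfrog, target_accept):
    dim = q0.size
    inv_mass = np.ones(dim)
    q = q0.copy()
    logp, grad = vg(q)
    if not np.isfinite(logp):
        raise FloatingPointError("log posterior is not finite at the initial point")

    eps = _find_initial_step(vg, q, rng, inv_mass)
    # dual averaging state (Hoffman & Gelman 2014)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    draws = np.empty((n_iter - warmup, dim))
    accepts = 0
    divergences = 0
    # second warmup phase samples for mass estimation
    mass_win_start = int(warmup * 0.4)
    mass_win_end = int(warmup * 0.8)
    mass_buf = []
    adapt_count = 0

    for it in range(n_iter):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        h0 = logp - 0.5 * float(np.sum(p0 * p0 * inv_mass))

        qn, pn, gn, logpn = q, p0, grad, logp
        diverged = False
        for _ in range(n_steps):
            pn = pn + 0.5 * eps * gn
            qn = qn + eps * inv_mass * pn
            logpn, gn = vg(qn)
            if not np.isfinite(logpn):
                diverged = True
                break
            pn = pn + 0.5 * eps * gn
        if diverged:
            h1 = -np.inf
        else:
            h1 = logpn - 0.5 * float(np.sum(pn * pn * inv_mass))
            if not np.isfinite(h1):
                h1 = -np.inf
        log_accept = min(0.0, h1 - h0)
        if it >= warmup and (h0 - h1) > 1000.0:
            divergences += 1
        if np.log(rng.random()) < log_accept:
            q, logp, grad = qn, logpn, gn
            if it >= warmup:
                accepts += 1

        if it < warmup:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - np.exp(log_accept))
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if mass_win_start <= it < mass_win_end:
                mass_buf.append(q.copy())
            if it == mass_win_end - 1 and len(mass_buf) > 10:
                var = np.var(np.asarray(mass_buf), axis=0)
                inv_mass = var + 1e-6
                # restart step-size adaptation under the new metric
                eps = _find_initial_step(vg, q, rng, inv_mass)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
            if it == warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - warmup] = q

    accept_rate = accepts / max(1, n_iter - warmup)
    return draws, accept_rate, divergences, eps


def sample_posterior(
    log_posterior,
    init: np.ndarray,
    n_iter: int = 7000,
    warmup: int = 1500,
    n_chains: int = 3,
    seed: int = 0,
    grad=None,
    max_leapfrog: int = 24,
    target_accept: float = 0.8,
    jitter: float = 0.5,
) -> PosteriorSamples:
    """Draw from a log posterior with HMC.

    ``log_posterior`` is a callable returning the log density; if it
    exposes ``value_and_grad`` (as :class:`~reefmpa.hier_models.glm.HierarchicalGLM`
    does) analytic gradients are used, otherwise ``grad`` or central finite
    differences. Initial points are jittered per chain; all randomness
    derives from ``seed`` and reruns are bit-identical.
    """
    if warmup >= n_iter:
        raise ValueError("warmup must be smaller than n_iter")
    init = np.asarray(init, float)
    vg = _value_and_grad_fn(log_posterior, grad)
    names = getattr(log_posterior, "param_names", None) or [f"theta[{i}]" for i in range(init.size)]

    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    all_draws = []
    rates, divs, steps = [], 0, []
    for c in range(n_chains):
        rng = np.random.default_rng(seeds[c])
        q0 = init + jitter * rng.standard_normal(init.size)
        logp0, _ = vg(q0)
        if not np.isfinite(logp0):
            q0 = init.copy()
        with np.errstate(over="ignore", invalid="ignore"):
            # exploding trial momenta yield -inf energies and are rejected
            draws, rate, ndiv, eps = _run_chain(vg, q0, n_iter, warmup, rng, max_leapfrog, target_accept)
        all_draws.append(draws)
        rates.append(rate)
        divs += ndiv
        steps.append(eps)
        logger.info("chain %d: accept=%.2f step=%.3g divergences=%d", c, rate, eps, ndiv)
    if divs > 0:
        logger.warning("%d divergent transitions; inspect diagnostics", divs)
    return PosteriorSamples(
        draws=np.asarray(all_draws),
        param_names=list(names),
        n_iter=n_iter,
        warmup=warmup,
        seed=seed,
        accept_rate=np.asarray(rates),
        divergences=divs,
        step_size=np.asarray(steps),
    )
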