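"""MCMC convergence diagnostics: split R-hat and effective sample size.

Convergence passes when every parameter's split R-hat lies within 0.01 of
1 — the same rule used to vet the fitted models in the study design this
package implements. Computations delegate to :mod:`arviz`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmc import PosteriorSamples

#: maximum allowed |R-hat − 1| for a converged parameter
RHAT_TOLERANCE = 0.01


@dataclass
class ConvergenceReport:
    table: pd.DataFrame  # index = parameter, columns = rhat, ess
    rhat_tolerance: float
    passed: bool

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        worst = self.table["rhat"].max()
        return (
            f"convergence {status}: max R-hat = {worst:.4f} "
            f"(tolerance |R-hat - 1| <= {self.rhat_tolerance}), "
            f"min ESS = {self.table['ess'].min():.0f}"
        )


def split_rhat(chains: np.ndarray) -> float:
    """Split R-hat of one parameter from draws shaped (n_chains, n_draws)."""
    chains = np.asarray(chains, float)
    n_chains, n_draws = chains.shape
    if n_chains < 2:
        raise ValueError("split R-hat requires at least 2 chains")
    half = n_draws // 2
    halves = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = halves.var(axis=1, ddof=1).mean()
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def diagnostics(samples: PosteriorSamples, rhat_tolerance: float = RHAT_TOLERANCE) -> ConvergenceReport:
    """Per-parameter split R-hat and bulk ESS, with a pass flag.

    Raises if fewer than two chains were run (between-chain variance is
    undefined otherwise).
    """
    import arviz as az

    if samples.n_chains < 2:
        raise ValueError("diagnostics require >= 2 chains")
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, name in enumerate(samples.param_names):
            chains = samples.draws[:, :, i]
            rows[name] = {
                "rhat": split_rhat(chains),
                "ess": float(az.ess(np.ascontiguousarray(chains))),
            }
    table = pd.DataFrame(rows).T[["rhat", "ess"]]
    passed = bool((np.abs(table["rhat"] - 1.0) <= rhat_tolerance).all())
    return ConvergenceReport(table=table, rhat_tolerance=rhat_tolerance, passed=passed)
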