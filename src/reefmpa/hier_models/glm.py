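"""Hierarchical GLM log posteriors with analytic gradients.

A :class:`HierarchicalGLM` holds a fixed-effects design matrix, grouped
random intercepts (and optionally random year slopes) with partial
pooling, and a Normal or mean/shape-Gamma likelihood (identity or log
link respectively). The unconstrained parameter vector is::

    [beta (p), z_int (G), z_slope (G)?, log_tau_int, log_tau_slope?, log_scale (s)]

where scale is the residual σ (Normal) or the per-stratum Gamma shape k.
Random effects use the non-centered parameterization u = τ·z with
z ~ N(0, 1), which removes the funnel geometry that frustrates HMC in
hierarchical models; the realized effects are τ_int·z_int etc.
Priors: beta ~ N(0, 10); τ ~ half-Cauchy(0, 2); σ ~ half-Cauchy(0, 2);
k ~ Exponential(1). Positive parameters are sampled on the log scale and
the log posterior includes the change-of-variables Jacobian so that HMC
targets the correct density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class HierarchicalGLM:
    """Log posterior of a hierarchical Normal/Gamma regression.

    Parameters
    ----------
    likelihood
        ``"normal"`` (identity link) or ``"gamma"`` (log link, mean/shape).
    y
        Response vector (positive for the Gamma likelihood).
    X
        Fixed-effects design matrix (n × p).
    beta_names
        Column labels for X.
    group_idx
        Integer codes (n,) of the random-intercept group of each row
        (reef, or reef × functional group).
    n_groups
        Number of random-effect groups G.
    slope_t
        Optional (n,) covariate (centered year) multiplying per-group
        random slopes; ``None`` for intercepts-only models.
    scale_idx
        Integer codes (n,) selecting which scale parameter applies to each
        row (e.g. the Gamma shape of its functional group); all zeros for
        a single shared scale.
    n_scales
        Number of scale parameters.
    """

    likelihood: str
    y: np.ndarray
    X: np.ndarray
    beta_names: list[str]
    group_idx: np.ndarray
    n_groups: int
    slope_t: np.ndarray | None = None
    scale_idx: np.ndarray | None = None
    n_scales: int = 1
    beta_prior_scale: float = 10.0
    tau_prior_scale: float = 2.0
    shape_prior_rate: float = 1.0
    group_names: list[str] = field(default_factory=list)
    scale_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.likelihood not in ("normal", "gamma"):
            raise ValueError("likelihood must be 'normal' or 'gamma'")
        self.y = np.asarray(self.y, float)
        self.X = np.asarray(self.X, float)
        self.group_idx = np.asarray(self.group_idx, int)
        if self.slope_t is not None:
            self.slope_t = np.asarray(self.slope_t, float)
        if self.scale_idx is None:
            self.scale_idx = np.zeros(len(self.y), int)
        else:
            self.scale_idx = np.asarray(self.scale_idx, int)
        if self.likelihood == "gamma" and np.any(self.y <= 0):
            raise ValueError("gamma likelihood requires y > 0")
        self.n_obs, self.p = self.X.shape
        self.has_slopes = self.slope_t is not None
        # parameter layout
        sizes = [("beta", self.p), ("z_int", self.n_groups)]
        if self.has_slopes:
            sizes.append(("z_slope", self.n_groups))
        sizes.append(("log_tau_int", 1))
        if self.has_slopes:
            sizes.append(("log_tau_slope", 1))
        sizes.append(("log_scale", self.n_scales))
        self.slices: dict[str, slice] = {}
        start = 0
        for name, size in sizes:
            self.slices[name] = slice(start, start + size)
            start += size
        self.n_params = start

    # ------------------------------------------------------------------
    @property
    def param_names(self) -> list[str]:
        names = list(self.beta_names)
        gnames = self.group_names or [str(i) for i in range(self.n_groups)]
        names += [f"z_int[{g}]" for g in gnames]
        if self.has_slopes:
            names += [f"z_slope[{g}]" for g in gnames]
        names += ["log_tau_int"]
        if self.has_slopes:
            names += ["log_tau_slope"]
        snames = self.scale_names or [str(i) for i in range(self.n_scales)]
        names += [f"log_scale[{s}]" for s in snames]
        return names

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        theta = np.asarray(theta, float)
        if theta.shape[-1] != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {theta.shape[-1]}")
        return {name: theta[..., sl] for name, sl in self.slices.items()}

    def init(self) -> np.ndarray:
        """Deterministic starting point with finite posterior density."""
        theta = np.zeros(self.n_params)
        if self.likelihood == "gamma":
            # start FG intercepts near log-mean response via least squares on log y
            beta0, *_ = np.linalg.lstsq(self.X, np.log(self.y), rcond=None)
            theta[self.slices["beta"]] = beta0
            theta[self.slices["log_scale"]] = np.log(2.0)
        theta[self.slices["log_tau_int"]] = np.log(0.5)
        if self.has_slopes:
            theta[self.slices["log_tau_slope"]] = np.log(0.5)
        return theta

    def random_effects(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Realized per-group effects u = τ·z on the response scale."""
        p = self.unpack(theta)
        out = {"u_int": np.exp(p["log_tau_int"][0]) * p["z_int"]}
        if self.has_slopes:
            out["u_slope"] = np.exp(p["log_tau_slope"][0]) * p["z_slope"]
        return out

    def linear_predictor(self, theta: np.ndarray) -> np.ndarray:
        p = self.unpack(theta)
        u = self.random_effects(theta)
        eta = self.X @ p["beta"] + u["u_int"][self.group_idx]
        if self.has_slopes:
            eta = eta + u["u_slope"][self.group_idx] * self.slope_t
        return eta

    # ------------------------------------------------------------------
    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        theta = np.asarray(theta, float)
        # unstable trajectories can fling log-scale parameters to overflow
        # territory; treat those states as zero-density so HMC rejects them
        if not np.all(np.isfinite(theta)) or np.any(np.abs(theta[self.slices["log_tau_int"].start :]) > 40.0):
            return -np.inf, np.zeros(self.n_params)
        with np.errstate(all="ignore"):
            logp, grad = self._value_and_grad_impl(theta)
        if not (np.isfinite(logp) and np.all(np.isfinite(grad))):
            return -np.inf, np.zeros(self.n_params)
        return logp, grad

    def _value_and_grad_impl(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        p = self.unpack(theta)
        beta, z_int = p["beta"], p["z_int"]
        tau_int = float(np.exp(p["log_tau_int"][0]))
        scale = np.exp(p["log_scale"])
        grad = np.zeros(self.n_params)

        eta = self.X @ beta + tau_int * z_int[self.group_idx]
        if self.has_slopes:
            z_slope = p["z_slope"]
            tau_slope = float(np.exp(p["log_tau_slope"][0]))
            eta = eta + tau_slope * z_slope[self.group_idx] * self.slope_t

        # --- likelihood and d/d eta -----------------------------------
        if self.likelihood == "normal":
            sigma = scale[0]
            z = (self.y - eta) / sigma
            loglik = float(np.sum(-0.5 * _LOG_2PI - np.log(sigma) - 0.5 * z * z))
            dl_deta = z / sigma
            dl_dlogscale = np.array([np.sum(z * z - 1.0)])
        else:
            k = scale[self.scale_idx]
            inv_mu_y = self.y * np.exp(-eta)
            loglik = float(
                np.sum(k * (np.log(k) - eta) - gammaln(k) + (k - 1.0) * np.log(self.y) - k * inv_mu_y)
            )
            dl_deta = k * (inv_mu_y - 1.0)
            per_obs = np.log(scale[self.scale_idx]) + 1.0 - digamma(scale[self.scale_idx]) + np.log(self.y) - eta - inv_mu_y
            dl_dk = np.bincount(self.scale_idx, weights=per_obs, minlength=self.n_scales)
            dl_dlogscale = scale * dl_dk

        grad[self.slices["beta"]] += self.X.T @ dl_deta
        agg_int = np.bincount(self.group_idx, weights=dl_deta, minlength=self.n_groups)
        grad[self.slices["z_int"]] += tau_int * agg_int
        if self.has_slopes:
            agg_slope = np.bincount(self.group_idx, weights=dl_deta * self.slope_t, minlength=self.n_groups)
            grad[self.slices["z_slope"]] += tau_slope * agg_slope
        grad[self.slices["log_scale"]] += dl_dlogscale

        # --- priors ----------------------------------------------------
        s_b = self.beta_prior_scale
        logp = loglik
        logp += float(np.sum(-0.5 * _LOG_2PI - np.log(s_b) - 0.5 * (beta / s_b) ** 2))
        grad[self.slices["beta"]] += -beta / s_b**2

        def ranef_terms(z, tau, agg, z_slice, tau_slice):
            nonlocal logp
            G = z.size
            # standard-normal prior on z (non-centered parameterization)
            logp += G * (-0.5 * _LOG_2PI) - 0.5 * float(np.sum(z * z))
            grad[z_slice] += -z
            # tau enters the likelihood through eta = ... + tau z[g] ...
            grad[tau_slice] += tau * float(np.sum(z * agg))
            # half-Cauchy prior on tau plus log-scale Jacobian
            s_t = self.tau_prior_scale
            logp += np.log(2.0 / (np.pi * s_t)) - np.log1p((tau / s_t) ** 2) + np.log(tau)
            grad[tau_slice] += -2.0 * (tau / s_t) ** 2 / (1.0 + (tau / s_t) ** 2) + 1.0

        ranef_terms(z_int, tau_int, agg_int, self.slices["z_int"], self.slices["log_tau_int"])
        if self.has_slopes:
            ranef_terms(z_slope, tau_slope, agg_slope, self.slices["z_slope"], self.slices["log_tau_slope"])

        if self.likelihood == "normal":
            sigma = scale[0]
            s_t = self.tau_prior_scale
            logp += np.log(2.0 / (np.pi * s_t)) - np.log1p((sigma / s_t) ** 2) + np.log(sigma)
            grad[self.slices["log_scale"]] += -2.0 * (sigma / s_t) ** 2 / (1.0 + (sigma / s_t) ** 2) + 1.0
        else:
            r = self.shape_prior_rate
            logp += float(np.sum(np.log(r) - r * scale + p["log_scale"]))
            grad[self.slices["log_scale"]] += -r * scale + 1.0

        return float(logp), grad

    def __call__(self, theta: np.ndarray) -> float:
        return self.value_and_grad(theta)[0]


def log_posterior(model: HierarchicalGLM, params: np.ndarray) -> float:
    """Log posterior density of ``params`` (unconstrained scale) under ``model``."""
    return model(params)


# ----------------------------------------------------------------------
# concrete model builders
# ----------------------------------------------------------------------

RECOVERY_BETA_NAMES = ["intercept", "habitat", "year", "management", "habitat:year", "management:year"]


def _codes(values) -> tuple[np.ndarray, list[str]]:
    cats = sorted(set(values))
    lookup = {c: i for i, c in enumerate(cats)}
    return np.asarray([lookup[v] for v in values], int), cats


def recovery_model(design, standardize: bool = True) -> tuple[HierarchicalGLM, dict]:
    """Normal recovery model from a :func:`build_recovery_design` table.

    Covariates: habitat (regime-shifted = 1), centered year, management
    (protected = 1) and the two year interactions; per-reef random
    intercepts and year slopes. Returns the model and a meta dict holding
    the response standardization (mean, sd) used to keep N(0, 10) priors
    weakly informative.
    """
    h = (design["habitat"] == "regime_shifted").to_numpy(float)
    m = (design["management"] == "protected").to_numpy(float)
    t = design["year_c"].to_numpy(float)
    X = np.column_stack([np.ones(len(design)), h, t, m, h * t, m * t])
    group_idx, reefs = _codes(design["reef_id"])
    y = design["y"].to_numpy(float)
    y_mean, y_sd = (float(y.mean()), float(y.std(ddof=0))) if standardize else (0.0, 1.0)
    if y_sd == 0:
        y_sd = 1.0
    model = HierarchicalGLM(
        likelihood="normal",
        y=(y - y_mean) / y_sd,
        X=X,
        beta_names=RECOVERY_BETA_NAMES,
        group_idx=group_idx,
        n_groups=len(reefs),
        slope_t=t,
        group_names=reefs,
        scale_names=["sigma"],
    )
    meta = {"reefs": reefs, "y_mean": y_mean, "y_sd": y_sd, "years": sorted(design["year"].unique())}
    return model, meta


def trophic_model(design, period: str = "pre") -> tuple[HierarchicalGLM, dict]:
    """Gamma carnivore/herbivore model from a :func:`build_trophic_design` table.

    Every fixed effect is indexed by functional group (FG); random
    intercepts (and year slopes, post-bleaching) are per reef × FG, and the
    Gamma shape k is per FG. Pre-bleaching design: intercept + management.
    Post-bleaching: intercept + habitat + year + management + habitat:year
    + management:year.
    """
    fg_idx, fgs = _codes(design["fg"])
    m = (design["management"] == "protected").to_numpy(float)
    cols, names = [], []
    for j, fg in enumerate(fgs):
        ind = (fg_idx == j).astype(float)
        cols += [ind, ind * m]
        names += [f"intercept[{fg}]", f"management[{fg}]"]
    slope_t = None
    if period == "post":
        h = (design["habitat"] == "regime_shifted").to_numpy(float)
        t = design["year_c"].to_numpy(float)
        extra_cols, extra_names = [], []
        for j, fg in enumerate(fgs):
            ind = (fg_idx == j).astype(float)
            extra_cols += [ind * h, ind * t, ind * h * t, ind * m * t]
            extra_names += [f"habitat[{fg}]", f"year[{fg}]", f"habitat:year[{fg}]", f"management:year[{fg}]"]
        cols += extra_cols
        names += extra_names
        slope_t = t
    X = np.column_stack(cols)
    group_keys = design["reef_id"].astype(str) + ":" + design["fg"].astype(str)
    group_idx, groups = _codes(group_keys)
    model = HierarchicalGLM(
        likelihood="gamma",
        y=design["y"].to_numpy(float),
        X=X,
        beta_names=names,
        group_idx=group_idx,
        n_groups=len(groups),
        slope_t=slope_t,
        scale_idx=fg_idx,
        n_scales=len(fgs),
        group_names=groups,
        scale_names=[f"k[{fg}]" for fg in fgs],
    )
    meta = {"fgs": fgs, "groups": groups, "period": period, "years": sorted(design["year"].unique())}
    return model, meta
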