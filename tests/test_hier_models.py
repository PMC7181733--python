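import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import approx_fprime

from reefmpa.hier_models import (
    build_recovery_design,
    build_trophic_design,
    center_years,
    log_density_gamma_mean_shape,
    log_density_normal,
    log_posterior,
)
from reefmpa.hier_models.glm import HierarchicalGLM, recovery_model, trophic_model


# ----------------------------------------------------------------- densities
def test_normal_log_density_standard_point():
    assert log_density_normal(0.0, 0.0, 1.0) == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)


def test_normal_log_density_is_symmetric():
    rng = np.random.default_rng(0)
    y, mu, sigma = rng.normal(size=20), rng.normal(size=20), rng.uniform(0.5, 3, 20)
    assert log_density_normal(y, mu, sigma) == pytest.approx(log_density_normal(2 * mu - y, mu, sigma))


def test_normal_log_density_matches_direct_formula():
    rng = np.random.default_rng(1)
    for _ in range(50):
        y, mu, sigma = rng.normal(), rng.normal(), rng.uniform(0.1, 5)
        direct = -0.5 * np.log(2 * np.pi) - np.log(sigma) - (y - mu) ** 2 / (2 * sigma**2)
        assert log_density_normal(y, mu, sigma) == pytest.approx(direct, rel=1e-10)
        assert log_density_normal(y, mu, sigma) == pytest.approx(stats.norm.logpdf(y, mu, sigma), rel=1e-10)


def test_gamma_log_density_known_point():
    # shape 2, mean 2 -> rate 1: f(2) = 2 e^-2
    assert log_density_gamma_mean_shape(2.0, 2.0, 2.0) == pytest.approx(np.log(2.0) - 2.0, abs=1e-12)


def test_gamma_log_density_matches_direct_formula():
    rng = np.random.default_rng(2)
    for _ in range(50):
        y, mu, k = rng.uniform(0.1, 50), rng.uniform(0.1, 50), rng.uniform(0.2, 20)
        # oracle: scipy Gamma with shape k and scale mu/k
        assert log_density_gamma_mean_shape(y, mu, k) == pytest.approx(
            stats.gamma.logpdf(y, a=k, scale=mu / k), rel=1e-10
        )


def test_gamma_with_unit_shape_is_exponential():
    y, mu = 3.0, 5.0
    assert log_density_gamma_mean_shape(y, mu, 1.0) == pytest.approx(stats.expon.logpdf(y, scale=mu), rel=1e-12)


def test_gamma_mean_parameterization_via_simulation():
    rng = np.random.default_rng(3)
    mu, k = 7.0, 3.0
    draws = rng.gamma(shape=k, scale=mu / k, size=100_000)
    assert draws.mean() == pytest.approx(mu, rel=0.02)
    assert draws.var() == pytest.approx(mu**2 / k, rel=0.05)


@pytest.mark.parametrize("args", [(0.0, 1.0, 1.0), (1.0, 0.0, 1.0), (1.0, 1.0, 0.0), (-1.0, 1.0, 1.0)])
def test_gamma_rejects_non_positive_arguments(args):
    with pytest.raises(ValueError):
        log_density_gamma_mean_shape(*args)


def test_normal_rejects_non_positive_sigma():
    with pytest.raises(ValueError):
        log_density_normal(0.0, 0.0, -1.0)


# ------------------------------------------------------------------- designs
def test_center_years_matches_hand_values():
    assert list(center_years([2005, 2008, 2011, 2014])) == pytest.approx([-4.5, -1.5, 1.5, 4.5])


def _mini_summaries():
    rows = []
    for reef, mgmt, regime, pre in [
        ("a", "fished", "recovering", 200.0),
        ("b", "protected", "regime_shifted", 400.0),
    ]:
        rows.append({"reef_id": reef, "year": 1994, "total_biomass": pre, "richness": 20.0,
                     "carnivore_biomass": pre / 2, "herbivore_biomass": pre / 2})
        for i, year in enumerate([2005, 2008, 2011, 2014]):
            val = pre + 10.0 * i
            rows.append({"reef_id": reef, "year": year, "total_biomass": val, "richness": 20.0 + i,
                         "carnivore_biomass": val / 2, "herbivore_biomass": val / 2})
    summaries = pd.DataFrame(rows)
    sites = pd.DataFrame(
        {"reef_id": ["a", "b"], "management": ["fished", "protected"], "regime": ["recovering", "regime_shifted"]}
    )
    return summaries, sites


def test_recovery_design_matches_hand_construction():
    summaries, sites = _mini_summaries()
    design = build_recovery_design(summaries, sites, "biomass")
    a = design[design.reef_id == "a"].sort_values("year")
    assert list(a["y"]) == pytest.approx([0.0, 10.0, 20.0, 30.0])
    assert list(a["year_c"]) == pytest.approx([-4.5, -1.5, 1.5, 4.5])
    assert (a["pre_level"] == 200.0).all()
    assert set(design["habitat"]) == {"recovering", "regime_shifted"}


def test_recovery_design_missing_baseline_names_reef():
    summaries, sites = _mini_summaries()
    with pytest.raises(ValueError, match="a"):
        build_recovery_design(summaries[summaries.year > 1994], sites, "biomass")


def test_trophic_design_periods_and_positivity():
    summaries, sites = _mini_summaries()
    pre = build_trophic_design(summaries, sites, "pre")
    assert set(pre["year"]) == {1994} and len(pre) == 4  # 2 reefs x 2 FG
    assert (pre["year_c"] == 0).all()
    post = build_trophic_design(summaries, sites, "post")
    assert set(post["fg"]) == {"carnivore", "herbivore"}
    assert sorted(post["year_c"].unique()) == pytest.approx([-4.5, -1.5, 1.5, 4.5])
    bad = summaries.copy()
    bad.loc[bad.index[0], "carnivore_biomass"] = 0.0
    with pytest.raises(ValueError, match="positive"):
        build_trophic_design(bad, sites, "pre")


# ------------------------------------------------------- log posterior oracle
def _halfcauchy_logpdf(x, scale=2.0):
    return np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2)


def test_normal_log_posterior_equals_term_by_term_sum():
    """5-observation toy: hand-sum every likelihood and prior term."""
    y = np.array([0.3, -1.2, 0.8, 2.0, -0.5])
    X = np.column_stack([np.ones(5), [0, 0, 1, 1, 1], [-1.5, 1.5, -1.5, 0.0, 1.5]])
    group_idx = np.array([0, 0, 1, 1, 1])
    t = X[:, 2]
    model = HierarchicalGLM(
        likelihood="normal", y=y, X=X, beta_names=["b0", "b1", "b2"],
        group_idx=group_idx, n_groups=2, slope_t=t,
    )
    rng = np.random.default_rng(4)
    theta = 0.3 * rng.standard_normal(model.n_params)
    beta = theta[model.slices["beta"]]
    z_int, z_slope = theta[model.slices["z_int"]], theta[model.slices["z_slope"]]
    log_tau_i, log_tau_s = theta[model.slices["log_tau_int"]][0], theta[model.slices["log_tau_slope"]][0]
    log_sigma = theta[model.slices["log_scale"]][0]
    tau_i, tau_s, sigma = np.exp([log_tau_i, log_tau_s, log_sigma])

    mu = X @ beta + tau_i * z_int[group_idx] + tau_s * z_slope[group_idx] * t
    expected = sum(stats.norm.logpdf(y[i], mu[i], sigma) for i in range(5))
    expected += sum(stats.norm.logpdf(b, 0, 10.0) for b in beta)
    expected += sum(stats.norm.logpdf(z, 0, 1.0) for z in np.concatenate([z_int, z_slope]))
    expected += _halfcauchy_logpdf(tau_i) + log_tau_i
    expected += _halfcauchy_logpdf(tau_s) + log_tau_s
    expected += _halfcauchy_logpdf(sigma) + log_sigma
    assert log_posterior(model, theta) == pytest.approx(expected, rel=1e-8)


def test_gamma_log_posterior_equals_term_by_term_sum():
    y = np.array([5.0, 12.0, 3.0, 40.0, 22.0])
    X = np.column_stack([np.ones(5), [0, 1, 0, 1, 1]])
    group_idx = np.array([0, 0, 1, 1, 2])
    fg_idx = np.array([0, 1, 0, 1, 0])
    model = HierarchicalGLM(
        likelihood="gamma", y=y, X=X, beta_names=["b0", "b1"],
        group_idx=group_idx, n_groups=3, scale_idx=fg_idx, n_scales=2,
    )
    rng = np.random.default_rng(5)
    theta = model.init() + 0.2 * rng.standard_normal(model.n_params)
    beta = theta[model.slices["beta"]]
    z = theta[model.slices["z_int"]]
    log_tau = theta[model.slices["log_tau_int"]][0]
    log_k = theta[model.slices["log_scale"]]
    tau, k = np.exp(log_tau), np.exp(log_k)

    mu = np.exp(X @ beta + tau * z[group_idx])
    expected = sum(stats.gamma.logpdf(y[i], a=k[fg_idx[i]], scale=mu[i] / k[fg_idx[i]]) for i in range(5))
    expected += sum(stats.norm.logpdf(b, 0, 10.0) for b in beta)
    expected += sum(stats.norm.logpdf(zi, 0, 1.0) for zi in z)
    expected += _halfcauchy_logpdf(tau) + log_tau
    expected += sum(stats.expon.logpdf(ki) + lk for ki, lk in zip(k, log_k))
    assert log_posterior(model, theta) == pytest.approx(expected, rel=1e-8)


def test_zero_observation_model_reduces_to_priors():
    model = HierarchicalGLM(
        likelihood="normal", y=np.empty(0), X=np.empty((0, 2)), beta_names=["b0", "b1"],
        group_idx=np.empty(0, int), n_groups=2,
    )
    theta = np.full(model.n_params, 0.1)
    beta = theta[model.slices["beta"]]
    z = theta[model.slices["z_int"]]
    log_tau = 0.1
    expected = (
        sum(stats.norm.logpdf(b, 0, 10.0) for b in beta)
        + sum(stats.norm.logpdf(zi, 0, 1.0) for zi in z)
        + _halfcauchy_logpdf(np.exp(log_tau)) + log_tau
        + _halfcauchy_logpdf(np.exp(0.1)) + 0.1
    )
    assert log_posterior(model, theta) == pytest.approx(expected, rel=1e-10)


def test_dimension_mismatch_raises():
    model = HierarchicalGLM(
        likelihood="normal", y=np.array([1.0]), X=np.ones((1, 1)), beta_names=["b0"],
        group_idx=np.zeros(1, int), n_groups=1,
    )
    with pytest.raises(ValueError, match="parameters"):
        log_posterior(model, np.zeros(model.n_params + 1))


def test_analytic_gradients_match_finite_differences(summaries, labelled):
    sites, _ = labelled
    rng = np.random.default_rng(6)
    models = [
        recovery_model(build_recovery_design(summaries, sites, "biomass"))[0],
        trophic_model(build_trophic_design(summaries, sites, "pre"), "pre")[0],
        trophic_model(build_trophic_design(summaries, sites, "post"), "post")[0],
    ]
    for model in models:
        theta = model.init() + 0.1 * rng.standard_normal(model.n_params)
        _, grad = model.value_and_grad(theta)
        numeric = approx_fprime(theta, lambda th: model(th), 1e-6)
        assert np.max(np.abs(grad - numeric) / (1.0 + np.abs(numeric))) < 1e-3
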