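import math

import numpy as np
import pytest

from reefmpa.reserve_effects import (
    effects_by_group,
    jackknife_bounds,
    log_response_ratio,
    mean_difference,
    response_ratio_pct,
)
from reefmpa.survey_io import TROPHIC_GROUPS


def test_mean_difference_example():
    assert mean_difference([10, 20], [10, 10, 10]) == pytest.approx(5.0)


def test_identical_groups_have_zero_difference():
    assert mean_difference([7, 7], [7, 7, 7]) == 0.0


def test_mean_difference_matches_independent_two_mean_computation():
    rng = np.random.default_rng(1)
    p, f = rng.uniform(0, 100, 9), rng.uniform(0, 100, 12)
    assert mean_difference(p, f) == pytest.approx(sum(p) / 9 - sum(f) / 12, rel=1e-12)


def test_response_ratio_example():
    assert response_ratio_pct([17.5, 17.5], [10, 10]) == pytest.approx(75.0)
    assert response_ratio_pct([10.0], [10.0, 10.0]) == pytest.approx(0.0)


def test_log_response_ratio_consistent_with_percent_ratio():
    rng = np.random.default_rng(2)
    p, f = rng.uniform(1, 100, 9), rng.uniform(1, 100, 12)
    lrr = log_response_ratio(p, f)
    assert math.exp(lrr) - 1.0 == pytest.approx(response_ratio_pct(p, f) / 100.0, rel=1e-12)


@pytest.mark.parametrize("func", [mean_difference, response_ratio_pct, log_response_ratio])
def test_empty_group_raises(func):
    with pytest.raises(ValueError):
        func([], [1.0, 2.0])


def test_zero_fished_mean_is_undefined_ratio():
    with pytest.raises(ValueError, match="not positive"):
        response_ratio_pct([1.0, 2.0], [0.0, 0.0])


def test_jackknife_example_enumerates_all_leave_one_out():
    values = np.array([10.0, 20.0, 10.0, 10.0, 10.0])
    protected = np.array([True, True, False, False, False])
    jk = jackknife_bounds(values, protected, "mean_difference")
    assert jk.estimate == pytest.approx(5.0)
    assert list(jk.loo_estimates) == pytest.approx([10.0, 0.0, 5.0, 5.0, 5.0])
    assert (jk.jackknife_min, jk.jackknife_max) == (0.0, 10.0)


def test_all_equal_sites_collapse_interval():
    jk = jackknife_bounds([5.0] * 21, [True] * 9 + [False] * 12, "mean_difference")
    assert jk.jackknife_min == jk.jackknife_max == jk.estimate == 0.0


def test_twenty_one_sites_give_twenty_one_estimates():
    rng = np.random.default_rng(3)
    jk = jackknife_bounds(rng.uniform(10, 500, 21), [True] * 9 + [False] * 12)
    assert len(jk.loo_estimates) == 21
    assert jk.n_protected == 9 and jk.n_fished == 12


@pytest.mark.parametrize("estimator", ["mean_difference", "response_ratio_pct", "log_response_ratio"])
def test_jackknife_matches_exhaustive_enumeration(estimator):
    """Oracle: recompute each leave-one-out estimate with raw arithmetic."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        values = rng.uniform(5, 500, 21)
        protected = np.zeros(21, bool)
        protected[rng.choice(21, 9, replace=False)] = True
        jk = jackknife_bounds(values, protected, estimator)
        oracle = []
        for i in range(21):
            keep = [j for j in range(21) if j != i]
            p = [values[j] for j in keep if protected[j]]
            f = [values[j] for j in keep if not protected[j]]
            if estimator == "mean_difference":
                oracle.append(sum(p) / len(p) - sum(f) / len(f))
            elif estimator == "response_ratio_pct":
                oracle.append(((sum(p) / len(p)) / (sum(f) / len(f)) - 1) * 100)
            else:
                oracle.append(math.log((sum(p) / len(p)) / (sum(f) / len(f))))
        assert list(jk.loo_estimates) == pytest.approx(oracle, rel=1e-12)
        assert jk.jackknife_min == pytest.approx(min(oracle), rel=1e-12)
        assert jk.jackknife_max == pytest.approx(max(oracle), rel=1e-12)


def test_estimate_lies_within_jackknife_interval_for_mean_difference():
    rng = np.random.default_rng(5)
    for _ in range(20):
        jk = jackknife_bounds(rng.uniform(0, 300, 21), [True] * 9 + [False] * 12, "mean_difference")
        assert jk.jackknife_min <= jk.estimate <= jk.jackknife_max


def test_estimators_invariant_to_site_ordering():
    rng = np.random.default_rng(6)
    values = rng.uniform(5, 500, 21)
    protected = np.array([True] * 9 + [False] * 12)
    perm = rng.permutation(21)
    a = jackknife_bounds(values, protected)
    b = jackknife_bounds(values[perm], protected[perm])
    assert a.estimate == pytest.approx(b.estimate)
    assert a.jackknife_min == pytest.approx(b.jackknife_min)
    assert a.jackknife_max == pytest.approx(b.jackknife_max)


def test_too_few_sites_per_group_raises():
    with pytest.raises(ValueError, match="2 sites"):
        jackknife_bounds([1.0, 2.0, 3.0], [True, False, False])


def test_effects_table_strata_and_counts(summaries, labelled):
    sites, _ = labelled
    out = effects_by_group(summaries, sites, grouping="total", estimator="mean_difference")
    pre = out[out.year == 1994]
    assert set(pre["stratum"]) == {"all"}
    assert (pre["n_protected"] == 9).all() and (pre["n_fished"] == 12).all()
    post = out[out.year > 1998]
    assert set(post["stratum"]) == {"recovering", "regime_shifted"}
    rec = post[post.stratum == "recovering"]
    assert (rec["n_protected"] == 5).all() and (rec["n_fished"] == 7).all()


def test_group_mean_differences_sum_to_total(summaries, labelled):
    sites, _ = labelled
    total = effects_by_group(summaries, sites, grouping="total", estimator="mean_difference")
    groups = effects_by_group(summaries, sites, grouping="trophic_group", estimator="mean_difference")
    for year in (1994, 2008):
        for stratum in set(total.loc[total.year == year, "stratum"]):
            t = total[(total.year == year) & (total.stratum == stratum) & (total.variable == "total_biomass")]
            g = groups[(groups.year == year) & (groups.stratum == stratum)]
            assert g["estimate"].sum() == pytest.approx(float(t["estimate"].iloc[0]), rel=1e-9)
            assert len(g) == len(TROPHIC_GROUPS)


def test_pre_bleaching_macroalgae_excluded_from_benthic_effects(summaries, labelled):
    sites, _ = labelled
    out = effects_by_group(summaries, sites, grouping="benthic", estimator="mean_difference")
    pre = out[out.year == 1994]
    assert "macroalgae" not in set(pre["variable"])
    assert "macroalgae" in set(out[out.year > 1998]["variable"])
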