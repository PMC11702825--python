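"""Normality-routed group tests and Pearson screening."""

import numpy as np
import pandas as pd
import pytest

from ezoct.stats import compare_groups, correlation_screen


def test_identical_samples_give_p_near_one():
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    res = compare_groups(x, x.copy())
    assert res.p_value > 0.95
    assert res.statistic == pytest.approx(0.0, abs=1e-12) or res.p_value > 0.95


def test_gaussian_samples_route_to_t():
    rng = np.random.default_rng(1)
    res = compare_groups(rng.normal(size=60), rng.normal(size=60))
    assert res.test == "t"
    assert res.shapiro_p_a > 0.05 and res.shapiro_p_b > 0.05


def test_exponential_sample_routes_to_wilcoxon():
    rng = np.random.default_rng(2)
    res = compare_groups(rng.exponential(size=60), rng.normal(size=60))
    assert res.test == "wilcoxon"
    assert res.shapiro_p_a <= 0.05


def test_routing_depends_only_on_shapiro_pvalues():
    """Over a battery of normal/exponential draws the route must match the
    Shapiro p-value rule exactly."""
    rng = np.random.default_rng(3)
    for _ in range(50):
        a = rng.normal(size=25) if rng.random() < 0.5 else rng.exponential(size=25)
        b = rng.normal(size=25) if rng.random() < 0.5 else rng.exponential(size=25)
        res = compare_groups(a, b)
        expected = "t" if (res.shapiro_p_a > 0.05 and res.shapiro_p_b > 0.05) else "wilcoxon"
        assert res.test == expected


def test_small_samples_rejected():
    with pytest.raises(ValueError):
        compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


def test_type_i_error_of_routed_procedure():
    """Type-I error at nominal 0.05 stays within +-0.02 over 2,000 null
    replicates with n = 50 per group."""
    rng = np.random.default_rng(4)
    n_reps = 2000
    rejections = 0
    for _ in range(n_reps):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        if compare_groups(a, b).p_value < 0.05:
            rejections += 1
    rate = rejections / n_reps
    assert abs(rate - 0.05) <= 0.02


def test_exact_linear_relation_flagged():
    x = np.arange(20.0)
    df = pd.DataFrame({"x": x, "y": 2 * x + 1})
    (rep,) = correlation_screen(df)
    assert rep.r == pytest.approx(1.0)
    assert rep.flagged_moderate


def test_independent_noise_has_small_r():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({"x": rng.normal(size=500), "y": rng.normal(size=500)})
    (rep,) = correlation_screen(df)
    assert abs(rep.r) < 0.15


@pytest.mark.parametrize("rho", [0.0, 0.3, 0.414, 0.8])
def test_pearson_recovers_population_r(rho):
    """Bivariate Gaussian at population r (incl. 0.414) recovered within 0.1 at n=500."""
    rng = np.random.default_rng(int(rho * 1000) + 7)
    n = 500
    x = rng.normal(size=n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
    (rep,) = correlation_screen(pd.DataFrame({"x": x, "y": y}))
    assert abs(rep.r - rho) <= 0.1
    assert rep.flagged_moderate == (rep.r > 0.3)


def test_zero_variance_reported_not_crashed():
    df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
    (rep,) = correlation_screen(df)
    assert np.isnan(rep.r)
    assert not rep.flagged_moderate
    assert "zero-variance" in rep.note


def test_negative_correlation_never_flagged():
    x = np.arange(30.0)
    df = pd.DataFrame({"x": x, "y": -x})
    (rep,) = correlation_screen(df)
    assert rep.r == pytest.approx(-1.0)
    assert not rep.flagged_moderate
    assert "negative" in rep.note


def test_complete_case_handling():
    df = pd.DataFrame({
        "x": [1.0, 2, 3, np.nan, 5, 6],
        "y": [2.0, 4, 6, 8, np.nan, 12],
    })
    (rep,) = correlation_screen(df)
    assert rep.n == 4
    assert rep.r == pytest.approx(1.0)
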