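"""KM/RMST estimators, pseudo-observations, short-horizon agreement."""

import numpy as np
import pandas as pd
import pytest

import triad_cea as tc
from triad_cea.validation import (km_rmst, km_survival, pseudovalue_regression,
                                  rmst, rmst_pseudovalues, short_horizon_compare,
                                  survival_from_histories)
from triad_cea.states import SPC


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

def test_km_equals_empirical_without_censoring():
    times = np.array([1.0, 2.0, 3.0])
    t, s = km_survival(times, np.ones(3, int))
    assert np.allclose(t, [1, 2, 3])
    assert np.allclose(s, [2 / 3, 1 / 3, 0.0])


def test_km_all_censored_is_one():
    t, s = km_survival(np.array([1.0, 2.0]), np.zeros(2, int))
    assert len(t) == 0
    assert rmst((t, s), 5.0) == 5.0


def test_km_negative_times_rejected():
    with pytest.raises(ValueError):
        km_survival(np.array([-1.0]), np.array([1]))


def test_km_matches_lifelines_with_censoring():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(5)
    t = rng.exponential(10, 400)
    c = rng.uniform(0, 15, 400)
    times, events = np.minimum(t, c), (t <= c).astype(int)
    kt, ks = km_survival(times, events)
    kmf = lifelines.KaplanMeierFitter().fit(times, events)
    ref = kmf.survival_function_at_times(kt).to_numpy()
    assert np.allclose(ks, ref, atol=1e-10)
    # RMST cross-check against lifelines' integral
    from lifelines.utils import restricted_mean_survival_time
    assert km_rmst(times, events, 8.0) == pytest.approx(
        restricted_mean_survival_time(kmf, t=8.0), abs=1e-8)


# --------------------------------------------------------------------------
# RMST
# --------------------------------------------------------------------------

def test_rmst_everyone_survives():
    t, s = km_survival(np.array([10.0, 12.0]), np.array([1, 1]))
    assert rmst((t, s), 5.0) == 5.0
    assert rmst((t, s), 0.0) == 0.0


def test_rmst_exponential_closed_form():
    rng = np.random.default_rng(7)
    n = 20_000
    t = rng.exponential(10.0, n)  # rate 0.1/yr
    est = km_rmst(t, np.ones(n, int), 5.0)
    truth = (1 - np.exp(-0.5)) / 0.1
    # MC SE of restricted mean min(T, 5)
    se = np.std(np.minimum(t, 5.0), ddof=1) / np.sqrt(n)
    assert abs(est - truth) < 3 * se


def test_rmst_step_integral_matches_dense_grid():
    rng = np.random.default_rng(9)
    t = rng.exponential(3.0, 300)
    c = rng.uniform(0, 6, 300)
    times, events = np.minimum(t, c), (t <= c).astype(int)
    kt, ks = km_survival(times, events)
    tau = 4.0
    grid = np.linspace(0, tau, 400_001)
    s_grid = np.ones_like(grid)
    for ti, si in zip(kt, ks):
        s_grid[grid >= ti] = si
    dense = np.trapezoid(s_grid, grid)
    assert rmst((kt, ks), tau) == pytest.approx(dense, abs=1e-4)


# --------------------------------------------------------------------------
# pseudo-observations
# --------------------------------------------------------------------------

def test_pseudovalue_mean_identity():
    rng = np.random.default_rng(11)
    t = rng.exponential(5.0, 120)
    c = rng.uniform(0, 8, 120)
    times, events = np.minimum(t, c), (t <= c).astype(int)
    pv = rmst_pseudovalues(times, events, 6.0)
    assert pv.mean() == pytest.approx(km_rmst(times, events, 6.0), abs=1e-10)


def test_pseudovalues_without_censoring_are_truncated_times():
    rng = np.random.default_rng(13)
    times = rng.exponential(5.0, 50)
    pv = rmst_pseudovalues(times, np.ones(50, int), 4.0)
    assert np.allclose(pv, np.minimum(times, 4.0), atol=1e-9)


def test_identical_times_give_identical_pseudovalues():
    pv = rmst_pseudovalues(np.full(10, 2.0), np.ones(10, int), 5.0)
    assert np.allclose(pv, pv[0])


def test_pseudovalues_need_two_subjects():
    with pytest.raises(ValueError):
        rmst_pseudovalues(np.array([1.0]), np.array([1]), 2.0)


def test_pseudovalue_regression_no_censoring_identity():
    """No covariates, no censoring: treatment coefficient equals the
    difference in mean truncated times exactly."""
    rng = np.random.default_rng(15)
    n = 200
    treat = (rng.random(n) < 0.5).astype(float)
    times = rng.exponential(5.0 + 3.0 * treat)
    tau = 6.0
    pv = rmst_pseudovalues(times, np.ones(n, int), tau)
    est, se, _ = pseudovalue_regression(pv, treat)
    truncated = np.minimum(times, tau)
    expected = truncated[treat == 1].mean() - truncated[treat == 0].mean()
    assert est == pytest.approx(expected, abs=1e-9)
    assert se > 0


def test_pseudovalue_regression_rejects_collinearity():
    pv = np.arange(10.0)
    treat = np.ones(10)
    with pytest.raises(ValueError, match="collinear"):
        pseudovalue_regression(pv, treat, pd.DataFrame({"dup": treat}))


def test_zero_effect_ci_covers_zero():
    rng = np.random.default_rng(17)
    n = 800
    treat = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(5.0, n)
    c = rng.uniform(0, 9, n)
    pv = rmst_pseudovalues(np.minimum(t, c), (t <= c).astype(int), 6.0)
    est, se, _ = pseudovalue_regression(pv, treat)
    assert abs(est) < 1.96 * se


# --------------------------------------------------------------------------
# short-horizon observed-vs-simulated comparison
# --------------------------------------------------------------------------

def test_survival_extraction_from_histories(demo):
    surv = survival_from_histories(demo["histories"])
    hist = demo["histories"]
    deaths = hist[hist["outcome"] == "DEAD"]["patient_id"]
    assert set(surv[surv["event"] == 1]["patient_id"]) == set(deaths)
    assert (surv["time"] > 0).all()


def test_short_horizon_self_consistency(demo):
    """Simulating from fits estimated on the same data reproduces the
    observed adjusted RMST difference (CI overlap)."""
    cohort = demo["cohort"].iloc[:1500].reset_index(drop=True)
    res = short_horizon_compare(cohort, demo["histories"], demo["costs"],
                                demo["fits"], demo["cost_params"],
                                seed=23, tau_months=52.0)
    assert res.rmst_agree
    assert 0 <= res.observed_rmst[SPC] <= 52 * 30.4375 / 365.25 + 1e-9
    assert res.cost_agree


def test_tau_beyond_observation_rejected(demo):
    with pytest.raises(ValueError, match="tau"):
        short_horizon_compare(demo["cohort"], demo["histories"], demo["costs"],
                              demo["fits"], demo["cost_params"],
                              seed=1, tau_months=80.0)


def test_tiny_tau_gives_negligible_delta(demo):
    cohort = demo["cohort"].iloc[:300].reset_index(drop=True)
    res = short_horizon_compare(cohort, demo["histories"], demo["costs"],
                                demo["fits"], demo["cost_params"],
                                seed=29, tau_months=1.0 / 30.4375)  # one day
    bound = 1.0 / 365.25
    assert abs(res.observed_delta_rmst) <= bound
    assert abs(res.simulated_delta_ly) <= bound
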