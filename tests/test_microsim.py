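"""Discounting, inverse-hazard sampling, lifetime trajectories, cohort runs."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import triad_cea as tc
from triad_cea.microsim import (DiscountSpec, SimSettings, discount_integral,
                                sample_sojourn, simulate_lifetime, run_cohort)
from triad_cea.states import SPC, TWO_PILL, DAYS_PER_YEAR

from conftest import degenerate_fit_set, make_linear_fit


# --------------------------------------------------------------------------
# discounting
# --------------------------------------------------------------------------

def test_discount_zero_rate_is_duration():
    assert discount_integral(0.0, 5.0, DiscountSpec(0.0)) == 5.0


def test_discount_closed_form_one_year():
    # (1 - 1/1.03) / ln(1.03)
    v = discount_integral(0.0, 1.0, DiscountSpec(0.03))
    assert v == pytest.approx(0.9853651, abs=1e-6)


def test_discount_additivity():
    spec = DiscountSpec(0.03)
    whole = discount_integral(0.0, 10.0, spec)
    split = discount_integral(0.0, 4.0, spec) + discount_integral(4.0, 10.0, spec)
    assert whole == pytest.approx(split, abs=1e-12)


def test_discount_rejects_reversed_interval():
    with pytest.raises(ValueError):
        discount_integral(3.0, 2.0, DiscountSpec(0.03))
    with pytest.raises(ValueError):
        DiscountSpec(-0.01)


# --------------------------------------------------------------------------
# inverse-cumulative-hazard sampling
# --------------------------------------------------------------------------

def test_exponential_inverse_is_analytic():
    """h = 0.5/yr, E = 1  =>  t = 2 years exactly."""
    fit = make_linear_fit("OUT->DEAD", rate_per_year=0.5, shape=1.0)
    t, event = sample_sojourn(fit, {}, np.random.default_rng(0), cap_years=50.0, e=1.0)
    assert event
    assert t == pytest.approx(2.0, abs=1e-6)


def test_deviate_beyond_cap_returns_censored():
    fit = make_linear_fit("OUT->DEAD", rate_per_year=0.5)
    t, event = sample_sojourn(fit, {}, np.random.default_rng(0), cap_years=1.0, e=3.0)
    assert t == 1.0 and not event


def test_cap_must_be_positive():
    fit = make_linear_fit("OUT->DEAD", rate_per_year=0.5)
    with pytest.raises(ValueError):
        sample_sojourn(fit, {}, np.random.default_rng(0), cap_years=0.0)


def test_inverse_sampling_matches_survivor_function(demo):
    """1e5 draws from a fitted transition: exp(-H(t)) is uniform (KS < 0.01)."""
    fit = demo["fits"]["OUT->HOSP"]
    x = {"age10": 6.8, "male": 0.0, "profile_intermediate": 0.0,
         "profile_poor": 0.0, "propensity": 0.3, "treat": 0.0}
    rng = np.random.default_rng(123)
    n = 100_000
    e = rng.exponential(1.0, n)
    lp = fit.linear_predictor(x)
    from triad_cea.microsim import _invert_cumhaz
    t = np.array([_invert_cumhaz(fit, lp, ei, np.inf) for ei in e])
    u = np.exp(-np.asarray([fit.cumulative_hazard(ti, x)[0] for ti in t[:20_000]]))
    ks = stats.kstest(u, "uniform")
    assert ks.statistic < 0.01


# --------------------------------------------------------------------------
# lifetime trajectories
# --------------------------------------------------------------------------

def test_forced_trajectory_undiscounted_accrual():
    fits = degenerate_fit_set(death_years=10.0)
    costs = _flat_cost_params(drug_spc=0.54, drug_two=0.52, hosp=600.0, outp=0.15)
    out = simulate_lifetime({}, SPC, fits, costs, DiscountSpec(0.0), cap_years=70.0,
                            rng=np.random.default_rng(0))
    assert out["died"]
    T = out["death_time"]
    assert T == pytest.approx(10.0, rel=2e-2)  # sharp but not perfectly degenerate
    assert out["ly_undisc"] == pytest.approx(T, abs=1e-12)
    assert out["ly_disc"] == pytest.approx(T, abs=1e-12)
    assert out["n_hospitalizations"] == 0
    assert out["cost_drug"] == pytest.approx(0.54 * DAYS_PER_YEAR * T, rel=1e-12)
    assert out["cost_hosp"] == 0.0


def test_forced_trajectory_discounted_matches_closed_form():
    fits = degenerate_fit_set(death_years=10.0)
    costs = _flat_cost_params()
    out = simulate_lifetime({}, SPC, fits, costs, DiscountSpec(0.03), cap_years=70.0,
                            rng=np.random.default_rng(0))
    T = out["death_time"]
    delta = math.log(1.03)
    assert out["ly_disc"] == pytest.approx((1 - (1.03) ** (-T)) / delta, rel=1e-10)
    assert out["ly_disc"] < out["ly_undisc"]


def test_alive_at_cap_is_flagged():
    fits = {lbl: make_linear_fit(lbl, 0.0) for lbl in
            ("OUT->HOSP", "OUT->DEAD", "HOSP->OUT", "HOSP->DEAD")}
    out = simulate_lifetime({}, TWO_PILL, fits, _flat_cost_params(),
                            DiscountSpec(0.0), cap_years=12.0,
                            rng=np.random.default_rng(0))
    assert not out["died"]
    assert out["ly_undisc"] == pytest.approx(12.0)


def test_missing_fit_is_an_error():
    fits = degenerate_fit_set()
    del fits["HOSP->DEAD"]
    with pytest.raises(KeyError, match="HOSP->DEAD"):
        simulate_lifetime({}, SPC, fits, _flat_cost_params(), DiscountSpec(0.0),
                          cap_years=10.0, rng=np.random.default_rng(0))


# --------------------------------------------------------------------------
# cohort runs
# --------------------------------------------------------------------------

def test_common_random_numbers_null_contract(demo):
    """Identical parameters for both strategies => per-patient outcome
    pairs identical, so dC = dE = 0 exactly."""
    cohort = demo["cohort"].iloc[:50].reset_index(drop=True)
    fits = {}
    for label, f in demo["fits"].items():
        theta = f.theta.copy()
        theta[f.n_spline + f.covariates.index("treat")] = 0.0
        fits[label] = f.replace_theta(theta)
    costs = _flat_cost_params(drug_spc=0.6, drug_two=0.6)
    settings = SimSettings(discount=DiscountSpec(0.03), seed=5)
    out = run_cohort(cohort, fits, costs, settings)
    inc = tc.incremental_summary(out)
    assert inc.delta_cost == 0.0 and inc.delta_effect == 0.0
    assert inc.dominance == "indifferent"


def test_protective_effect_gains_life_years(demo_outcomes):
    inc = tc.incremental_summary(demo_outcomes["outcomes"])
    assert inc.means[SPC]["ly_disc"] > inc.means[TWO_PILL]["ly_disc"]


def test_cost_conservation(demo_outcomes):
    out = demo_outcomes["outcomes"]
    total = out["cost_drug"] + out["cost_hosp"] + out["cost_outpatient"]
    assert np.allclose(total, out["cost_total"], rtol=1e-9)
    assert (out["ly_disc"] <= out["ly_undisc"] + 1e-12).all()


def test_substream_contract_under_cohort_growth(demo):
    settings = SimSettings(discount=DiscountSpec(0.03), seed=9)
    small = demo["cohort"].iloc[:30].reset_index(drop=True)
    large = demo["cohort"].iloc[:60].reset_index(drop=True)
    o1 = run_cohort(small, demo["fits"], demo["cost_params"], settings)
    o2 = run_cohort(large, demo["fits"], demo["cost_params"], settings)
    pd.testing.assert_frame_equal(o1, o2.iloc[: len(o1)].reset_index(drop=True))


def test_exponential_toy_model_mean_survival():
    """Exponential-only death at 0.08/yr, no cap: simulated undiscounted LY
    matches the analytic mean 1/0.08 within 3 MC SEs."""
    fits = {lbl: make_linear_fit(lbl, 0.0) for lbl in ("OUT->HOSP", "HOSP->OUT", "HOSP->DEAD")}
    fits["OUT->DEAD"] = make_linear_fit("OUT->DEAD", rate_per_year=0.08)
    costs = _flat_cost_params()
    n = 3000
    rng = np.random.default_rng(42)
    ly = [simulate_lifetime({}, SPC, fits, costs, DiscountSpec(0.0), 1e4, rng)["ly_undisc"]
          for _ in range(n)]
    mean, se = np.mean(ly), np.std(ly, ddof=1) / np.sqrt(n)
    assert abs(mean - 12.5) < 3 * se


def _flat_cost_params(drug_spc=0.5, drug_two=0.5, hosp=500.0, outp=0.1):
    from triad_cea.costs import CategoryCost, CostParameters
    return CostParameters(
        hospitalization=CategoryCost(hosp, 10.0, 1.0, 100),
        outpatient=CategoryCost(outp, 0.05, 0.005, 100),
        drug={SPC: CategoryCost(drug_spc, 0.1, 0.01, 100),
              TWO_PILL: CategoryCost(drug_two, 0.1, 0.01, 100)},
    )
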