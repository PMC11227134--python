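"""Shared fixtures: a moderate synthetic cohort with fitted models.

Everything is generated programmatically at fixed seeds; the "demo"
cohort (n = 4,000) is big enough for the fits to be stable but small
enough that the whole suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import triad_cea as tc
from triad_cea.microsim import DiscountSpec, SimSettings

DEMO_N = 4000
DEMO_SEED = 11


@pytest.fixture(scope="session")
def config():
    return tc.default_config()


@pytest.fixture(scope="session")
def demo(config):
    """Cohort + histories + costs + fits + cost parameters at n=4000."""
    cohort = tc.generate_cohort(DEMO_N, DEMO_SEED, config)
    histories = tc.simulate_histories(cohort, config, DEMO_SEED)
    costs = tc.attach_costs(histories, config, DEMO_SEED, cohort=cohort)
    fits = tc.fit_all_transitions(histories, cohort)
    cost_params = tc.estimate_cost_parameters(costs, cohort)
    return {"cohort": cohort, "histories": histories, "costs": costs,
            "fits": fits, "cost_params": cost_params, "config": config}


@pytest.fixture(scope="session")
def demo_outcomes(demo):
    """Lifetime microsimulation of a 500-patient subsample of the demo cohort."""
    cohort = demo["cohort"].iloc[:500].reset_index(drop=True)
    settings = SimSettings(discount=DiscountSpec(0.03), seed=21)
    outcomes = tc.run_cohort(cohort, demo["fits"], demo["cost_params"], settings)
    return {"cohort": cohort, "outcomes": outcomes, "settings": settings}


def make_linear_fit(label: str, rate_per_year: float, shape: float = 1.0,
                    covariates: tuple[str, ...] = ()) -> tc.TransitionFit:
    """Hand-built fit with H(t) = rate * (t / 365.25)^shape (t in days).

    Uses two knots only, so the log cumulative hazard is globally linear
    in log time: an exact Weibull/exponential hazard for oracle tests.
    """
    from triad_cea.states import DAYS_PER_YEAR

    gamma0 = np.log(rate_per_year) - shape * np.log(DAYS_PER_YEAR) \
        if rate_per_year > 0 else -60.0
    theta = np.concatenate([[gamma0, shape], np.zeros(len(covariates))])
    m = 2 + len(covariates)
    return tc.TransitionFit(
        label=label, spec=tc.SplineSpec(np.array([0.0, 8.0])),
        covariates=covariates, centers={}, theta=theta,
        cov=np.zeros((m, m)), loglik=0.0, n_events=100, n_rows=100,
        converged=True)


def degenerate_fit_set(death_years: float = 10.0,
                       sharpness: float = 200.0) -> dict[str, tc.TransitionFit]:
    """Fits forcing death at ~death_years and (essentially) no other event."""
    from triad_cea.states import DAYS_PER_YEAR

    t0 = death_years * DAYS_PER_YEAR
    # H(t) = (t/t0)^sharpness: crosses any Exp(1) deviate almost exactly at t0
    gamma0 = -sharpness * np.log(t0)
    death = tc.TransitionFit(
        label="OUT->DEAD", spec=tc.SplineSpec(np.array([0.0, 12.0])),
        covariates=(), centers={}, theta=np.array([gamma0, sharpness]),
        cov=np.zeros((2, 2)), loglik=0.0, n_events=100, n_rows=100,
        converged=True)
    off = {lbl: make_linear_fit(lbl, 0.0) for lbl in
           ("OUT->HOSP", "HOSP->OUT", "HOSP->DEAD")}
    return {"OUT->DEAD": death, **off}
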