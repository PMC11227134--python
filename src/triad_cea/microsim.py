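"""Individual-level continuous-time microsimulation of lifetime outcomes.

Each patient is simulated under BOTH strategies from the same random
substream (common random numbers), so outcome differences are driven
purely by the fitted parameters.  Sojourn times are drawn by inverting
the fitted cumulative hazard at an Exp(1) deviate; competing transitions
race, the minimum wins, and the clock resets on every state entry.
Life-years accrue in both transient states; drug and outpatient daily
costs accrue out of hospital, the hospitalization daily cost in hospital.
Costs and life-years are discounted continuously at force
``delta = ln(1 + r)`` (annual rate ``r``, default 3%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .costs import CostParameters
from .disease import TransitionFit
from .states import (DEAD, HOSP, OUT, SPC, STRATEGIES, TWO_PILL,
                     DAYS_PER_YEAR, outgoing, transition_label)

_P_SIMULATION = 11


@dataclass
class DiscountSpec:
    """Continuous discounting at annual rate ``rate`` (force ln(1+rate))."""

    rate: float = 0.03

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("discount rate must be >= 0")

    @property
    def force(self) -> float:
        return math.log1p(self.rate)


def discount_integral(t1: float, t2: float, spec: DiscountSpec) -> float:
    """Present value of one unit flowing uniformly over [t1, t2] years.

    ``int_{t1}^{t2} e^(-delta u) du = (e^(-delta t1) - e^(-delta t2)) / delta``;
    with rate 0 this is the plain duration.
    """
    if t1 < 0 or t2 < t1:
        raise ValueError(f"need 0 <= t1 <= t2, got ({t1}, {t2})")
    delta = spec.force
    if delta == 0.0:
        return t2 - t1
    return (math.exp(-delta * t1) - math.exp(-delta * t2)) / delta


# --------------------------------------------------------------------------
# inverse-cumulative-hazard sampling
# --------------------------------------------------------------------------

def _invert_cumhaz(fit: TransitionFit, lp: float, e: float, cap_days: float) -> float:
    """Smallest t (days) with H(t | x) = e, or +inf if H(cap) < e.

    Solves s(u) = ln e - lp on the log-time axis.  The restricted cubic
    spline is exactly linear beyond its boundary knots, so the equation
    is closed-form outside [k_min, k_max] and bracketed for brentq inside.
    """
    target = math.log(e) - lp
    k = fit.spec.knots
    gamma = fit.gamma
    s_lo, ds_lo = fit.spline_at(np.array([k[0]]))
    s_hi, ds_hi = fit.spline_at(np.array([k[-1]]))
    s_lo, s_hi = float(s_lo[0]), float(s_hi[0])

    if target <= s_lo:
        # below the first knot: s(u) = gamma0 + gamma1 * u
        if gamma[1] <= 0:
            return math.inf
        u = (target - gamma[0]) / gamma[1]
    elif target >= s_hi:
        slope = float(ds_hi[0])
        if slope <= 0:
            return math.inf
        u = k[-1] + (target - s_hi) / slope
    else:
        u = brentq(lambda v: float(fit.spline_at(np.array([v]))[0][0]) - target,
                   k[0], k[-1], xtol=1e-12, rtol=8.9e-16)
    t = math.exp(u)
    return t


def sample_sojourn(fit: TransitionFit, x, rng: np.random.Generator,
                   cap_years: float, e: float | None = None) -> tuple[float, bool]:
    """Draw one sojourn time (years) for a single transition.

    Inverse-transform sampling: draw ``E ~ Exp(1)`` (or use the supplied
    deviate) and return the smallest t with ``H(t | x) = E``.  If the
    cumulative hazard at the cap never reaches E, returns ``(cap, False)``.
    """
    if cap_years <= 0:
        raise ValueError("cap must be > 0")
    if e is None:
        e = float(rng.exponential(1.0))
    lp = fit.linear_predictor(x)
    cap_days = cap_years * DAYS_PER_YEAR
    with np.errstate(over="ignore"):
        h_cap = float(fit.cumulative_hazard(cap_days, x)[0])
    if math.isnan(h_cap):
        raise FloatingPointError(f"{fit.label}: NaN cumulative hazard at cap")
    if h_cap < e:
        return cap_years, False
    t_days = _invert_cumhaz(fit, lp, e, cap_days)
    return min(t_days / DAYS_PER_YEAR, cap_years), t_days / DAYS_PER_YEAR <= cap_years


# --------------------------------------------------------------------------
# lifetime simulation
# --------------------------------------------------------------------------

@dataclass
class SimSettings:
    discount: DiscountSpec
    horizon_years: float = 70.0
    max_age: float = 110.0
    seed: int = 0

    def cap_for(self, age_index: float) -> float:
        return max(min(self.horizon_years, self.max_age - age_index), 1e-6)


OUTCOME_COLUMNS = ["patient_id", "strategy", "ly_disc", "ly_undisc",
                   "cost_drug", "cost_hosp", "cost_outpatient", "cost_total",
                   "n_hospitalizations", "death_time", "died"]


def simulate_lifetime(x: dict[str, float], strategy: str,
                      fits: dict[str, TransitionFit],
                      cost_params: CostParameters,
                      discount: DiscountSpec,
                      cap_years: float,
                      rng: np.random.Generator,
                      patient_id: int = -1) -> dict:
    """Simulate one lifetime trajectory; returns a SimOutcome row (dict).

    ``x`` carries the hazard covariates with ``treat`` set from
    ``strategy``.  Clock resets on each state entry; simultaneous
    competing times (within 1e-9 days) resolve to death.
    """
    for r, s in ((OUT, HOSP), (OUT, DEAD), (HOSP, OUT), (HOSP, DEAD)):
        if transition_label(r, s) not in fits:
            raise KeyError(f"missing fit for transition {r}->{s}")
    if cap_years <= 0:
        raise ValueError("cap must be > 0")

    rates = cost_params.daily_rates()
    drug_daily = rates[strategy]
    x = dict(x)
    x["treat"] = 1.0 if strategy == SPC else 0.0

    t = 0.0  # years since index
    state = OUT
    ly = ly_undisc = 0.0
    cost_drug = cost_hosp = cost_outp = 0.0
    n_hosp = 0
    died = False
    death_time = math.nan

    while t < cap_years:
        remaining = cap_years - t
        dests = outgoing(state)
        draws = []
        for s in dests:
            fit = fits[transition_label(state, s)]
            draws.append(sample_sojourn(fit, x, rng, remaining))
        times = np.array([d[0] for d in draws])
        events = [d[1] for d in draws]
        j = int(np.argmin(times))
        if DEAD in dests:
            jd = dests.index(DEAD)
            if abs(times[jd] - times[j]) <= 1e-9 / DAYS_PER_YEAR and events[jd]:
                j = jd
        sojourn = float(times[j])
        reached = events[j] and sojourn < remaining

        pv = discount_integral(t, t + sojourn, discount)
        ly += pv
        ly_undisc += sojourn
        if state == OUT:
            cost_drug += drug_daily * DAYS_PER_YEAR * pv
            cost_outp += rates["outpatient"] * DAYS_PER_YEAR * pv
        else:
            cost_hosp += rates["hosp"] * DAYS_PER_YEAR * pv
        t += sojourn
        if not reached:
            break
        state = dests[j]
        if state == HOSP:
            n_hosp += 1
        if state == DEAD:
            died = True
            death_time = t
            break

    total = cost_drug + cost_hosp + cost_outp
    return {
        "patient_id": patient_id, "strategy": strategy,
        "ly_disc": ly, "ly_undisc": ly_undisc,
        "cost_drug": cost_drug, "cost_hosp": cost_hosp,
        "cost_outpatient": cost_outp, "cost_total": total,
        "n_hospitalizations": n_hosp, "death_time": death_time, "died": died,
    }


def run_cohort(cohort: pd.DataFrame, fits: dict[str, TransitionFit],
               cost_params: CostParameters, settings: SimSettings,
               cap_years: float | None = None) -> pd.DataFrame:
    """Simulate every patient under both strategies (two rows per patient).

    Both strategies reuse the patient's substream keyed by
    ``(seed, patient_id, purpose)`` — common random numbers — so with
    identical parameters the paired outcomes are identical, and adding
    patients never changes existing ones.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    from .cohort import covariate_matrix

    xrecords = covariate_matrix(cohort).to_dict("records")
    rows = []
    ids = cohort["patient_id"].to_numpy()
    ages = cohort["age_index"].to_numpy(float)
    for i in range(len(cohort)):
        pid = int(ids[i])
        cap = cap_years if cap_years is not None else settings.cap_for(ages[i])
        x = xrecords[i]
        for strategy in STRATEGIES:
            rng = np.random.default_rng(
                np.random.SeedSequence((int(settings.seed), pid, _P_SIMULATION)))
            try:
                rows.append(simulate_lifetime(x, strategy, fits, cost_params,
                                              settings.discount, cap, rng,
                                              patient_id=pid))
            except Exception as exc:
                raise RuntimeError(f"simulation failed for patient {pid} "
                                   f"({strategy}): {exc}") from exc
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)
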