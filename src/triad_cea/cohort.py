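"""Synthetic cohort generator: patients, multi-state histories, costs.

Stands in for a regional healthcare-utilization cohort of triple
antihypertensive therapy initiators.  Three pieces:

* :func:`generate_cohort` — covariates, treatment assignment (logistic on
  covariates, intercept calibrated to the marginal single-pill share) and
  administrative censoring times;
* :func:`simulate_histories` — ground-truth three-state event histories
  under competing cause-specific Weibull hazards with clock reset;
* :func:`attach_costs` — per-category cost totals accrued over the
  history (Gamma daily hospital cost, per-patient outpatient and drug
  daily rates).

Reproducibility contract: every random quantity for patient ``i`` is
drawn from a dedicated substream keyed by ``(seed, patient_id, purpose)``,
so enlarging the cohort never perturbs existing patients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .params import GeneratorConfig, COVARIATE_NAMES
from .states import (OUT, HOSP, DEAD, SPC, TWO_PILL, DAYS_PER_YEAR,
                     MAX_FOLLOWUP_DAYS, outgoing, transition_label)

# purpose codes for per-patient RNG substreams
_P_COVARIATES = 1
_P_TREATMENT = 2
_P_HISTORY = 3
_P_COSTS = 4

COHORT_COLUMNS = [
    "patient_id", "age_index", "sex", "clinical_profile", "propensity",
    "strategy", "entry_day", "admin_censor_day",
]

HISTORY_COLUMNS = ["patient_id", "state", "entry_day", "exit_day", "outcome"]

CENSORED = "censored"

_PROFILES = np.array(["good", "intermediate", "poor"])


def _patient_rng(seed: int, patient_id: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(patient_id), purpose)))


def covariate_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns (age10, male, profile dummies, propensity)."""
    x = pd.DataFrame(index=cohort.index)
    x["age10"] = cohort["age_index"].to_numpy(float) / 10.0
    x["male"] = (cohort["sex"] == "male").astype(float)
    x["profile_intermediate"] = (cohort["clinical_profile"] == "intermediate").astype(float)
    x["profile_poor"] = (cohort["clinical_profile"] == "poor").astype(float)
    x["propensity"] = cohort["propensity"].to_numpy(float)
    return x


def _centered_covariates(cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    x = covariate_matrix(cohort)
    refs = config.covariate_refs()
    for name in COVARIATE_NAMES:
        x[name] = x[name] - refs[name]
    return x


def _assignment_logit(x_centered: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    lp = np.zeros(len(x_centered))
    for name, coef in config.assignment_coefs.items():
        lp += coef * x_centered[name].to_numpy()
    return lp


def calibrate_assignment_intercept(config: GeneratorConfig,
                                   n_ref: int = 20_000) -> float:
    """Intercept of the treatment-assignment logistic model.

    Solves ``E[expit(alpha + a'x)] = spc_share`` over a fixed internal
    reference sample of the covariate distribution, so the intercept is a
    function of the configuration only (not of the cohort realized later).
    """
    if config.spc_share <= 0.0:
        return -np.inf
    if config.spc_share >= 1.0:
        return np.inf
    ref = _draw_covariates(np.arange(n_ref), seed=0, config=config)
    lp = _assignment_logit(_centered_covariates(ref, config), config)

    def share(alpha: float) -> float:
        return float(np.mean(expit(alpha + lp))) - config.spc_share

    return brentq(share, -30.0, 30.0, xtol=1e-10)


def _draw_covariates(patient_ids: np.ndarray, seed: int,
                     config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    p_probs = np.asarray(config.profile_probs, float)
    for pid in patient_ids:
        rng = _patient_rng(seed, pid, _P_COVARIATES)
        # truncated-normal age, lower bound at the entry criterion
        while True:
            age = rng.normal(config.age_mean, config.age_sd)
            if age >= config.age_min:
                break
        sex = "male" if rng.random() < config.male_prob else "female"
        profile = _PROFILES[rng.choice(3, p=p_probs)]
        entry_day = int(rng.integers(0, config.entry_window_days + 1))
        rows.append((int(pid), age, sex, profile, entry_day))
    df = pd.DataFrame(rows, columns=["patient_id", "age_index", "sex",
                                     "clinical_profile", "entry_day"])
    df["admin_censor_day"] = np.minimum(config.study_end_day - df["entry_day"],
                                        MAX_FOLLOWUP_DAYS).astype(int)
    df["propensity"] = 0.5  # placeholder until assignment is drawn
    df["strategy"] = TWO_PILL
    return df[COHORT_COLUMNS]


def generate_cohort(n: int, seed: int, config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate ``n`` patients with covariates and treatment assignment.

    Treatment is assigned by a logistic model on centered covariates with
    the intercept calibrated so the marginal single-pill share equals
    ``config.spc_share`` (default 0.31).  The recorded ``propensity`` is
    the true assignment probability jittered on the logit scale — a proxy
    for a claims-derived propensity score.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    config = config or GeneratorConfig()
    config.validate()
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS).astype(
            {"patient_id": int, "entry_day": int, "admin_censor_day": int})

    ids = np.arange(n)
    cohort = _draw_covariates(ids, seed, config)
    alpha = calibrate_assignment_intercept(config)
    lp = alpha + _assignment_logit(_centered_covariates(cohort, config), config)
    p_true = expit(lp)

    strategies = np.empty(n, dtype=object)
    propensity = np.empty(n)
    for i, pid in enumerate(ids):
        rng = _patient_rng(seed, pid, _P_TREATMENT)
        strategies[i] = SPC if rng.random() < p_true[i] else TWO_PILL
        noisy = logit(np.clip(p_true[i], 1e-12, 1 - 1e-12)) + \
            rng.normal(0.0, config.propensity_noise_sd)
        propensity[i] = float(np.clip(expit(noisy), 1e-6, 1 - 1e-6))
    cohort["strategy"] = strategies
    cohort["propensity"] = propensity
    return cohort


def _linear_predictor(xc_row: np.ndarray, beta: dict[str, float],
                      treated: bool, log_hr: float) -> float:
    lp = 0.0
    for j, name in enumerate(COVARIATE_NAMES):
        lp += beta.get(name, 0.0) * xc_row[j]
    if treated:
        lp += log_hr
    return lp


def _sample_weibull_days(rng: np.random.Generator, shape: float, scale: float,
                         lp: float) -> float:
    """Inverse-transform draw from H(t) = scale * t^shape * exp(lp), t in years."""
    e = rng.exponential(1.0)
    rate = scale * np.exp(lp)
    if rate <= 0.0:
        return np.inf
    t_years = (e / rate) ** (1.0 / shape)
    return t_years * DAYS_PER_YEAR


def simulate_histories(cohort: pd.DataFrame, truth: GeneratorConfig,
                       seed: int) -> pd.DataFrame:
    """Ground-truth event histories under the competing Weibull hazards.

    Clock resets on every state entry; treatment multiplies each
    cause-specific hazard by ``exp(log_hr_treatment)``; follow-up is
    administratively censored at ``admin_censor_day``; death is absorbing.

    Returns a long-format table: patient_id, state, entry_day, exit_day,
    outcome (next state or ``"censored"``); intervals are half-open.
    """
    truth.validate()
    xc = _centered_covariates(cohort, truth).to_numpy()
    records: list[tuple] = []
    strategies = cohort["strategy"].to_numpy()
    censor = cohort["admin_censor_day"].to_numpy(float)
    ids = cohort["patient_id"].to_numpy()

    for i in range(len(cohort)):
        pid = int(ids[i])
        rng = _patient_rng(seed, pid, _P_HISTORY)
        treated = strategies[i] == SPC
        t = 0.0
        state = OUT
        cmax = censor[i]
        while True:
            dests = outgoing(state)
            times = []
            for s in dests:
                tr = truth.transitions[transition_label(state, s)]
                lp = _linear_predictor(xc[i], tr.beta, treated, tr.log_hr_treatment)
                times.append(_sample_weibull_days(rng, tr.shape, tr.scale, lp))
            times = np.asarray(times)
            j = int(np.argmin(times))
            # exact ties: death wins (conservative)
            if DEAD in dests:
                jd = dests.index(DEAD)
                if abs(times[jd] - times[j]) <= 1e-9:
                    j = jd
            sojourn = times[j]
            if t + sojourn >= cmax:
                records.append((pid, state, t, cmax, CENSORED))
                break
            nxt = dests[j]
            records.append((pid, state, t, t + sojourn, nxt))
            t = t + sojourn
            state = nxt
            if state == DEAD:
                break

    return pd.DataFrame(records, columns=HISTORY_COLUMNS)


def person_days(histories: pd.DataFrame) -> pd.DataFrame:
    """Per-patient person-days spent in each transient state."""
    h = histories[histories["state"] != DEAD].copy()
    h["days"] = h["exit_day"] - h["entry_day"]
    out = (h.pivot_table(index="patient_id", columns="state", values="days",
                         aggfunc="sum", fill_value=0.0)
           .reindex(columns=[OUT, HOSP], fill_value=0.0))
    out.columns = ["days_out", "days_hosp"]
    return out.reset_index()


def attach_costs(histories: pd.DataFrame, truth: GeneratorConfig, seed: int,
                 cohort: pd.DataFrame | None = None) -> pd.DataFrame:
    """Accrue per-patient cost totals (€) over the simulated histories.

    Hospital days draw Gamma daily costs (method-of-moments from the
    configured mean/SD; the sum over ``d`` days is drawn exactly as
    Gamma(d*shape, scale)).  Out-of-hospital days accrue per-patient
    outpatient and drug daily rates; with ``cost_noise`` the rates are
    themselves Gamma draws around covariate-adjusted means, otherwise they
    are the means exactly.  SD = 0 is treated as a point mass.
    """
    truth.validate()
    pd_days = person_days(histories)
    c = truth.costs

    if cohort is not None:
        merged = pd_days.merge(
            cohort[["patient_id", "strategy"]].assign(
                _drug_lp=_drug_cost_logmean_offset(cohort, truth)),
            on="patient_id", how="left")
        strategies = merged["strategy"].to_numpy()
        drug_lp = merged["_drug_lp"].to_numpy()
    else:
        strategies = np.array([TWO_PILL] * len(pd_days), dtype=object)
        drug_lp = np.zeros(len(pd_days))

    rows = []
    for i in range(len(pd_days)):
        pid = int(pd_days["patient_id"].iloc[i])
        d_out = float(pd_days["days_out"].iloc[i])
        d_hosp = float(pd_days["days_hosp"].iloc[i])
        rng = _patient_rng(seed, pid, _P_COSTS)

        hosp_cost = _gamma_total(rng, d_hosp, c.hosp_daily_mean, c.hosp_daily_sd)

        out_rate = _gamma_rate(rng, c.outpatient_daily_mean,
                               c.outpatient_daily_sd if truth.cost_noise else 0.0)
        drug_mean = c.drug_daily_mean[strategies[i]] * np.exp(drug_lp[i])
        drug_rate = _gamma_rate(rng, drug_mean,
                                c.drug_daily_sd if truth.cost_noise else 0.0)

        rows.append((pid, drug_rate * d_out, hosp_cost, out_rate * d_out,
                     d_out, d_hosp, drug_rate, out_rate))

    return pd.DataFrame(rows, columns=[
        "patient_id", "drug_cost", "hosp_cost", "outpatient_cost",
        "days_out", "days_hosp", "drug_daily_rate", "outpatient_daily_rate"])


def _drug_cost_logmean_offset(cohort: pd.DataFrame, truth: GeneratorConfig) -> np.ndarray:
    xc = _centered_covariates(cohort, truth)
    lp = np.zeros(len(cohort))
    for name, coef in truth.costs.drug_covariate_effects.items():
        lp += coef * xc[name].to_numpy()
    return lp


def _gamma_total(rng: np.random.Generator, n_days: float, mean: float, sd: float) -> float:
    """Total cost over ``n_days`` iid Gamma daily draws (drawn as one Gamma)."""
    if n_days <= 0.0 or mean <= 0.0:
        return 0.0
    if sd <= 0.0:
        return n_days * mean
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return float(rng.gamma(shape * n_days, scale))


def _gamma_rate(rng: np.random.Generator, mean: float, sd: float) -> float:
    if mean <= 0.0:
        return 0.0
    if sd <= 0.0:
        return mean
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, mean / shape))
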