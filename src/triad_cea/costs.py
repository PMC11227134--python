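"""Daily cost parameter estimation.

State costs (hospitalization, outpatient) are summarized as the mean
daily cost across patients with positive person-days in the state,
together with SD and SE of the mean.  The daily drug cost is adjusted for
case mix with a Gamma log-link GLM on strategy plus covariates; adjusted
per-strategy means come from g-computation (average of the predictions
with everyone assigned to each strategy), with delta-method SEs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .states import SPC, TWO_PILL, STRATEGIES

log = logging.getLogger(__name__)

#: covariates the drug-cost GLM adjusts for
DRUG_COST_COVARIATES = ("age10", "male", "profile_intermediate", "profile_poor",
                        "propensity")


@dataclass
class CategoryCost:
    """Mean daily cost of one category (€/day) with spread across patients."""

    mean: float
    sd: float
    se: float
    n: int
    missing: bool = False  # True when no patient contributed person-days


@dataclass
class CostParameters:
    """Everything the microsimulation needs to price a trajectory."""

    hospitalization: CategoryCost
    outpatient: CategoryCost
    drug: dict[str, CategoryCost] = field(default_factory=dict)

    def daily_rates(self) -> dict[str, float]:
        return {
            "hosp": self.hospitalization.mean,
            "outpatient": self.outpatient.mean,
            SPC: self.drug[SPC].mean,
            TWO_PILL: self.drug[TWO_PILL].mean,
        }

    def to_dict(self) -> dict:
        return {
            "hospitalization": asdict(self.hospitalization),
            "outpatient": asdict(self.outpatient),
            "drug": {k: asdict(v) for k, v in self.drug.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CostParameters":
        return cls(
            hospitalization=CategoryCost(**d["hospitalization"]),
            outpatient=CategoryCost(**d["outpatient"]),
            drug={k: CategoryCost(**v) for k, v in d["drug"].items()},
        )


def _daily_summary(total: np.ndarray, days: np.ndarray, category: str) -> CategoryCost:
    pos = days > 0
    n = int(pos.sum())
    if n == 0:
        log.warning("no person-days in category %s; parameter flagged missing", category)
        return CategoryCost(mean=np.nan, sd=np.nan, se=np.nan, n=0, missing=True)
    rates = total[pos] / days[pos]
    mean = float(rates.mean())
    if n == 1:
        log.warning("category %s estimated from a single patient; SE undefined", category)
        return CategoryCost(mean=mean, sd=np.nan, se=np.nan, n=1)
    sd = float(rates.std(ddof=1))
    return CategoryCost(mean=mean, sd=sd, se=sd / np.sqrt(n), n=n)


def estimate_state_costs(cost_table: pd.DataFrame) -> tuple[CategoryCost, CategoryCost]:
    """(hospitalization, outpatient) daily-cost parameters.

    ``cost_table`` is the per-patient table with columns ``hosp_cost``,
    ``outpatient_cost``, ``days_hosp``, ``days_out`` (as produced by
    :func:`triad_cea.cohort.attach_costs`).  The daily rate is computed
    per patient (total / person-days) and averaged across patients; a
    category with zero person-days everywhere is flagged missing rather
    than silently zero.
    """
    hosp = _daily_summary(cost_table["hosp_cost"].to_numpy(float),
                          cost_table["days_hosp"].to_numpy(float), "hospitalization")
    outp = _daily_summary(cost_table["outpatient_cost"].to_numpy(float),
                          cost_table["days_out"].to_numpy(float), "outpatient")
    return hosp, outp


def fit_drug_cost_model(daily_cost: pd.Series | np.ndarray,
                        strategy: pd.Series | np.ndarray,
                        covariates: pd.DataFrame | None = None,
                        family: str = "gamma") -> dict[str, CategoryCost]:
    """Case-mix-adjusted mean daily drug cost per strategy.

    Fits a GLM of the per-patient daily drug cost on strategy plus
    covariates (Gamma family with log link by default, matching the right
    skew of cost data; ``family="gaussian"`` is the identity-link
    fallback) and returns the g-computation adjusted mean per strategy:
    the average model prediction over the whole cohort with strategy set
    to each level, with delta-method standard errors.
    """
    y = np.asarray(daily_cost, float)
    strat = np.asarray(strategy, dtype=object)
    keep = np.isfinite(y)
    if family == "gamma":
        nonpos = keep & (y <= 0)
        if nonpos.any():
            raise ValueError(
                f"{int(nonpos.sum())} non-positive daily drug costs are incompatible "
                "with the Gamma family; drop zero-drug-day patients or use the "
                "additive-noise (gaussian) configuration")
    y = y[keep]
    strat = strat[keep]

    x_parts = [pd.Series((strat == SPC).astype(float), name="treat")]
    if covariates is not None:
        cov = covariates.reset_index(drop=True)[np.asarray(keep)].reset_index(drop=True)
        for name in cov.columns:
            x_parts.append(pd.Series(cov[name].to_numpy(float), name=name))
    x = pd.concat(x_parts, axis=1)
    x = sm.add_constant(x, has_constant="add")

    if family == "gamma":
        model = sm.GLM(y, x, family=sm.families.Gamma(link=sm.families.links.Log()))
    elif family == "gaussian":
        model = sm.GLM(y, x, family=sm.families.Gaussian())
    else:
        raise ValueError(f"unknown family {family!r}")
    res = model.fit()

    out: dict[str, CategoryCost] = {}
    v = np.asarray(res.cov_params())
    for s in STRATEGIES:
        xs = x.copy()
        xs["treat"] = 1.0 if s == SPC else 0.0
        xm = xs.to_numpy(float)
        eta = xm @ res.params.to_numpy()
        if family == "gamma":
            mu = np.exp(eta)
            grad = (mu[:, None] * xm).mean(axis=0)
        else:
            mu = eta
            grad = xm.mean(axis=0)
        mean = float(mu.mean())
        se = float(np.sqrt(grad @ v @ grad))
        out[s] = CategoryCost(mean=mean, sd=float(np.std(y, ddof=1)), se=se, n=len(y))
    return out


def estimate_cost_parameters(cost_table: pd.DataFrame,
                             cohort: pd.DataFrame,
                             family: str = "gamma") -> CostParameters:
    """Full cost parametrization from the per-patient cost table."""
    from .cohort import covariate_matrix  # local import to avoid cycle

    hosp, outp = estimate_state_costs(cost_table)
    merged = cost_table.merge(cohort[["patient_id", "strategy", "age_index", "sex",
                                      "clinical_profile", "propensity"]],
                              on="patient_id", how="inner")
    with_drug_days = merged["days_out"] > 0
    n_excluded = int((~with_drug_days).sum())
    if n_excluded:
        log.info("excluding %d patients with zero drug days from the drug-cost fit",
                 n_excluded)
    merged = merged[with_drug_days].reset_index(drop=True)
    cov = covariate_matrix(merged)[list(DRUG_COST_COVARIATES)]
    drug = fit_drug_cost_model(merged["drug_daily_rate"], merged["strategy"],
                               covariates=cov, family=family)
    return CostParameters(hospitalization=hosp, outpatient=outp, drug=drug)
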