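"""Incremental cost-effectiveness: ICER, dominance, NMB, CEAC, subgroups.

Conventions: increments are single-pill minus two-pill, so a positive
incremental effect (life-years) and negative incremental cost put the
single-pill strategy in the dominant quadrant of the cost-effectiveness
plane.  The reference willingness-to-pay is €23,000 per life-year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .states import SPC, TWO_PILL

DEFAULT_WTP = 23_000.0

DOMINANT = "dominant"
DOMINATED = "dominated"
TRADE_OFF_NE = "trade-off-NE"
TRADE_OFF_SW = "trade-off-SW"
INDIFFERENT = "indifferent"

_TOL = 1e-12


def icer(delta_cost: float, delta_effect: float) -> tuple[float | None, str]:
    """ICER (€ per life-year) and cost-effectiveness-plane class.

    Total function: with zero incremental effect no ratio is returned and
    the class follows the sign of the incremental cost.  Ratios are
    reported even in the dominant/dominated quadrants.
    """
    dc, de = float(delta_cost), float(delta_effect)
    if abs(de) <= _TOL and abs(dc) <= _TOL:
        return None, INDIFFERENT
    if abs(de) <= _TOL:
        return None, DOMINATED if dc > 0 else DOMINANT
    ratio = dc / de
    if de > 0:
        cls = DOMINANT if dc < -_TOL else TRADE_OFF_NE
    else:
        cls = DOMINATED if dc > _TOL else TRADE_OFF_SW
    return ratio, cls


def nmb(wtp: float, delta_cost: float, delta_effect: float) -> float:
    """Net monetary benefit ``wtp * dE - dC`` (€) at willingness-to-pay ``wtp``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * delta_effect - delta_cost


@dataclass
class IncrementalResult:
    """Increments (single-pill minus two-pill) with decision quantities."""

    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: str
    nmb: float
    wtp: float = DEFAULT_WTP
    n_patients: int = 0
    means: dict = field(default_factory=dict)      # per-strategy category means
    ci: dict = field(default_factory=dict)         # PSA percentile CIs, if any

    def to_dict(self) -> dict:
        return asdict(self)


def incremental_summary(outcomes: pd.DataFrame, wtp: float = DEFAULT_WTP) -> IncrementalResult:
    """Mean increments from a paired outcomes table (two rows per patient).

    Effectiveness is the mean discounted life-years, cost the mean total
    discounted cost; per-category and per-strategy means are reported
    alongside.  Every patient must appear under both strategies.
    """
    counts = outcomes.groupby("patient_id")["strategy"].nunique()
    if (counts != 2).any():
        bad = counts.index[counts != 2].tolist()[:5]
        raise ValueError(f"unpaired patients in outcomes table (e.g. {bad})")

    means = {}
    g = outcomes.groupby("strategy")
    for s in (SPC, TWO_PILL):
        m = g.get_group(s)
        means[s] = {
            "ly_disc": float(m["ly_disc"].mean()),
            "ly_undisc": float(m["ly_undisc"].mean()),
            "cost_drug": float(m["cost_drug"].mean()),
            "cost_hosp": float(m["cost_hosp"].mean()),
            "cost_outpatient": float(m["cost_outpatient"].mean()),
            "cost_total": float(m["cost_total"].mean()),
        }
    de = means[SPC]["ly_disc"] - means[TWO_PILL]["ly_disc"]
    dc = means[SPC]["cost_total"] - means[TWO_PILL]["cost_total"]
    ratio, cls = icer(dc, de)
    return IncrementalResult(
        delta_cost=dc, delta_effect=de, icer=ratio, dominance=cls,
        nmb=nmb(wtp, dc, de), wtp=wtp,
        n_patients=int(outcomes["patient_id"].nunique()), means=means)


def ceac(delta_costs: np.ndarray, delta_effects: np.ndarray,
         wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over PSA samples.

    For each willingness-to-pay value, the fraction of samples with
    positive net monetary benefit.  Default grid: €0–100,000 by €1,000.
    """
    dc = np.asarray(delta_costs, float)
    de = np.asarray(delta_effects, float)
    if dc.size == 0:
        raise ValueError("need at least one PSA sample")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 100_001.0, 1000.0)
    wtp_grid = np.asarray(wtp_grid, float)
    if wtp_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    prob = [(w * de - dc > 0).mean() for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": prob})


AGE_BANDS = ((40, 64), (65, 80), (80, np.inf))


def _stratify(outcomes: pd.DataFrame, cohort: pd.DataFrame, by: str) -> pd.Series:
    info = cohort.set_index("patient_id")
    if by == "sex":
        return outcomes["patient_id"].map(info["sex"])
    if by == "clinical_profile":
        return outcomes["patient_id"].map(info["clinical_profile"])
    if by == "age":
        ages = outcomes["patient_id"].map(info["age_index"])
        labels = pd.Series(index=outcomes.index, dtype=object)
        labels[ages <= 64] = "40-64"
        labels[(ages > 64) & (ages <= 80)] = "65-80"
        labels[ages > 80] = ">80"
        return labels
    raise ValueError(f"unknown stratifier {by!r}; use sex, age or clinical_profile")


def subgroup_summary(outcomes: pd.DataFrame, cohort: pd.DataFrame, by: str,
                     wtp: float = DEFAULT_WTP) -> dict[str, IncrementalResult]:
    """Per-stratum incremental results for sex, age band or clinical profile.

    Strata are taken from the cohort table; an empty stratum raises
    rather than being silently dropped.
    """
    strata = _stratify(outcomes, cohort, by)
    if strata.isna().any():
        raise ValueError(f"stratifier {by!r} undefined for some patients")
    expected = {
        "sex": ["male", "female"],
        "age": ["40-64", "65-80", ">80"],
        "clinical_profile": ["good", "intermediate", "poor"],
    }[by]
    out: dict[str, IncrementalResult] = {}
    for level in expected:
        sub = outcomes[strata == level]
        if len(sub) == 0:
            raise ValueError(f"stratum {level!r} of {by!r} is empty")
        out[level] = incremental_summary(sub, wtp=wtp)
    return out
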