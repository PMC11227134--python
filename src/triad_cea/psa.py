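"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by sampling model inputs from their
estimation distributions — multivariate normal on each transition's
stacked spline/covariate coefficients (asymptotic MLE distribution),
Gamma (method of moments) on the cost means — re-running the
microsimulation for every draw, and summarizing the per-sample increments
with 2.5th/97.5th percentile intervals.  Draws producing a negative
hazard anywhere on the fitted event-time range are rejected and redrawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costs import CategoryCost, CostParameters
from .decision import DEFAULT_WTP, IncrementalResult, icer, incremental_summary, nmb
from .disease import TransitionFit, rp_basis
from .microsim import SimSettings, run_cohort
from .states import SPC, TWO_PILL

log = logging.getLogger(__name__)


def gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) by the method of moments: analytic mean is exact."""
    if mean <= 0 or sd <= 0:
        raise ValueError(f"gamma_moments needs mean > 0 and sd > 0, got ({mean}, {sd})")
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return shape, scale


@dataclass
class PSASample:
    """One joint draw of all model inputs."""

    index: int
    theta: dict[str, np.ndarray]
    cost_means: dict[str, float]          # "hosp", "outpatient", SPC, TWO_PILL
    n_redraws: int = 0


def _safe_cholesky(cov: np.ndarray) -> np.ndarray:
    cov = (cov + cov.T) / 2.0
    if not np.any(cov):
        return np.zeros_like(cov)
    jitter = 0.0
    base = max(np.trace(cov) / len(cov), 1e-12)
    for _ in range(12):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(len(cov)))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12 * base)
    raise np.linalg.LinAlgError("covariance not positive semi-definite within jitter tolerance")


def _hazard_nonneg(fit: TransitionFit, theta: np.ndarray, grid_size: int = 128) -> bool:
    grid = np.linspace(fit.spec.knots[0], fit.spec.knots[-1], grid_size)
    _, deriv = rp_basis(grid, fit.spec)
    return bool(np.all(deriv @ theta[: fit.n_spline] >= 0.0))


def draw_parameters(fits: dict[str, TransitionFit], cost_params: CostParameters,
                    rng: np.random.Generator, spread: str = "SE",
                    index: int = 0, max_attempts: int = 100) -> PSASample:
    """One PSA draw of transition coefficients and cost means.

    ``spread`` chooses the scale of the cost Gamma: ``"SE"`` (standard
    error of the mean — parameter uncertainty, the default) or ``"SD"``
    (between-patient spread).  A spread of zero degenerates to the point
    estimate.
    """
    if spread not in ("SE", "SD"):
        raise ValueError("spread must be 'SE' or 'SD'")
    theta = {}
    n_redraws = 0
    for label, fit in fits.items():
        chol = _safe_cholesky(fit.cov)
        for attempt in range(max_attempts):
            draw = fit.theta + chol @ rng.standard_normal(len(fit.theta))
            if _hazard_nonneg(fit, draw):
                break
            n_redraws += 1
        else:
            raise RuntimeError(f"{label}: no hazard-feasible draw in {max_attempts} attempts")
        theta[label] = draw

    def cost_draw(cc: CategoryCost) -> float:
        s = cc.se if spread == "SE" else cc.sd
        if cc.missing or not np.isfinite(cc.mean) or cc.mean <= 0:
            return float(cc.mean if np.isfinite(cc.mean) else 0.0)
        if not np.isfinite(s) or s <= 0:
            return float(cc.mean)
        shape, scale = gamma_moments(cc.mean, s)
        return float(rng.gamma(shape, scale))

    cost_means = {
        "hosp": cost_draw(cost_params.hospitalization),
        "outpatient": cost_draw(cost_params.outpatient),
        SPC: cost_draw(cost_params.drug[SPC]),
        TWO_PILL: cost_draw(cost_params.drug[TWO_PILL]),
    }
    if n_redraws:
        log.info("PSA sample %d: %d negative-hazard redraws", index, n_redraws)
    return PSASample(index=index, theta=theta, cost_means=cost_means,
                     n_redraws=n_redraws)


def _apply_sample(sample: PSASample, fits: dict[str, TransitionFit],
                  cost_params: CostParameters
                  ) -> tuple[dict[str, TransitionFit], CostParameters]:
    new_fits = {k: f.replace_theta(sample.theta[k]) for k, f in fits.items()}

    def repl(cc: CategoryCost, mean: float) -> CategoryCost:
        return CategoryCost(mean=mean, sd=cc.sd, se=cc.se, n=cc.n, missing=cc.missing)

    new_costs = CostParameters(
        hospitalization=repl(cost_params.hospitalization, sample.cost_means["hosp"]),
        outpatient=repl(cost_params.outpatient, sample.cost_means["outpatient"]),
        drug={s: repl(cost_params.drug[s], sample.cost_means[s]) for s in (SPC, TWO_PILL)},
    )
    return new_fits, new_costs


@dataclass
class PSAResult:
    samples: pd.DataFrame                  # per-sample dC, dE, ICER, dominant flag
    base: IncrementalResult | None
    marginal_icer: float
    ci: dict[str, tuple[float, float]]
    prob_dominant: float
    n_samples: int
    wtp: float = DEFAULT_WTP
    summary: dict = field(default_factory=dict)


def run_psa(n_samples: int, cohort: pd.DataFrame, fits: dict[str, TransitionFit],
            cost_params: CostParameters, settings: SimSettings,
            subsample: int | None = 2000, spread: str = "SE",
            wtp: float = DEFAULT_WTP, seed: int | None = None,
            cap_years: float | None = None) -> PSAResult:
    """Full PSA: per-draw microsimulation and percentile summaries.

    Each sample re-simulates a fixed patient subsample (common random
    numbers across samples, so only parameter uncertainty varies) and
    records the mean increments.  95% CIs are the 2.5th/97.5th
    percentiles of the per-sample distribution; the marginal ICER is the
    ratio of the across-sample mean increments.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    master = settings.seed if seed is None else seed
    if subsample is not None and subsample < len(cohort):
        pick_rng = np.random.default_rng(np.random.SeedSequence((int(master), 77)))
        idx = pick_rng.choice(len(cohort), size=subsample, replace=False)
        cohort = cohort.iloc[np.sort(idx)].reset_index(drop=True)

    rows = []
    for i in range(n_samples):
        rng = np.random.default_rng(np.random.SeedSequence((int(master), 1000 + i)))
        sample = draw_parameters(fits, cost_params, rng, spread=spread, index=i)
        s_fits, s_costs = _apply_sample(sample, fits, cost_params)
        outcomes = run_cohort(cohort, s_fits, s_costs, settings, cap_years=cap_years)
        inc = incremental_summary(outcomes, wtp=wtp)
        rows.append({
            "sample": i, "delta_cost": inc.delta_cost, "delta_effect": inc.delta_effect,
            "icer": np.nan if inc.icer is None else inc.icer,
            "dominant": inc.dominance == "dominant",
            "nmb": inc.nmb, "n_redraws": sample.n_redraws,
        })
    samples = pd.DataFrame(rows)

    def pct(col: str) -> tuple[float, float]:
        v = samples[col].to_numpy(float)
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    mean_dc = float(samples["delta_cost"].mean())
    mean_de = float(samples["delta_effect"].mean())
    marg, _ = icer(mean_dc, mean_de)
    return PSAResult(
        samples=samples, base=None,
        marginal_icer=np.nan if marg is None else float(marg),
        ci={"delta_cost": pct("delta_cost"), "delta_effect": pct("delta_effect"),
            "icer": pct("icer")},
        prob_dominant=float(samples["dominant"].mean()),
        n_samples=n_samples, wtp=wtp,
        summary={"mean_delta_cost": mean_dc, "mean_delta_effect": mean_de,
                 "mean_nmb": float(samples["nmb"].mean())})
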