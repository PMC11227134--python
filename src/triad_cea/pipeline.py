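"""Pipeline orchestration: generate -> fit -> simulate -> psa -> report -> validate.

Every stage writes its artifacts to the configured output directory,
stamped with the master seed and a hash of the configuration; stage seeds
are derived deterministically from the master seed and the stage name, so
a rerun of the same configuration is bit-identical.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .config import RunConfig, stage_seed
from .costs import CostParameters, estimate_cost_parameters
from .decision import ceac, incremental_summary, subgroup_summary
from .disease import fit_all_transitions, load_fits, save_fits
from .microsim import DiscountSpec, SimSettings, run_cohort
from .params import GeneratorConfig
from .psa import run_psa
from .validation import short_horizon_compare

log = logging.getLogger("triad_cea.pipeline")

#: out-of-hospital daily cost scale-up when pricing all outpatient care
#: instead of CV-specific outpatient care only
ALL_OUTPATIENT_SCALE = 5.0

STAGES = ("generate", "fit", "simulate", "psa", "report", "validate")


def _generator_config(config: RunConfig) -> GeneratorConfig:
    gen = GeneratorConfig.from_dict(config.generator) if config.generator \
        else GeneratorConfig()
    if config.all_outpatient_costs:
        gen.costs.outpatient_daily_mean *= ALL_OUTPATIENT_SCALE
        gen.costs.outpatient_daily_sd *= ALL_OUTPATIENT_SCALE
    gen.validate()
    return gen


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the run manifest.

    Any stage failure is re-raised with the stage name attached; partial
    artifacts of earlier stages remain on disk.
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        t0 = time.time()
        seed = stage_seed(config.seed, stage)
        log.info("stage %s (seed %d) ...", stage, seed)
        try:
            info = _STAGE_FUNCS[stage](config, seed, out, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        info["seed"] = seed
        info["elapsed_s"] = round(time.time() - t0, 3)
        manifest["stages"][stage] = info
        log.info("stage %s done in %.1fs", stage, info["elapsed_s"])
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_generate(config: RunConfig, seed: int, out: Path, state: dict) -> dict:
    gen = _generator_config(config)
    cohort = cohort_mod.generate_cohort(config.n, seed, gen)
    histories = cohort_mod.simulate_histories(cohort, gen, seed)
    costs = cohort_mod.attach_costs(histories, gen, seed, cohort=cohort)
    cohort.to_csv(out / "cohort.csv", index=False)
    histories.to_csv(out / "histories.csv", index=False)
    costs.to_csv(out / "cost_records.csv", index=False)
    gen.to_json(out / "generator_config.json")
    state.update(cohort=cohort, histories=histories, costs=costs, gen=gen)
    return {"n_patients": len(cohort), "n_sojourns": len(histories)}


def _stage_fit(config: RunConfig, seed: int, out: Path, state: dict) -> dict:
    fits = fit_all_transitions(state["histories"], state["cohort"],
                               n_knots=config.n_knots)
    cost_params = estimate_cost_parameters(state["costs"], state["cohort"])
    save_fits(fits, out / "fitted_params.json", cost_params=cost_params.to_dict(),
              meta={"seed": seed, "config_hash": config.config_hash()})
    state.update(fits=fits, cost_params=cost_params)
    return {"n_events": {k: f.n_events for k, f in fits.items()},
            "converged": {k: f.converged for k, f in fits.items()}}


def _sim_cohort(config: RunConfig, seed: int, state: dict) -> pd.DataFrame:
    cohort = state["cohort"]
    if config.sim_subsample and config.sim_subsample < len(cohort):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 99)))
        idx = np.sort(rng.choice(len(cohort), config.sim_subsample, replace=False))
        cohort = cohort.iloc[idx].reset_index(drop=True)
    return cohort

def _stage_simulate(config: RunConfig, seed: int, out: Path, state: dict) -> dict:
    rate = 0.0 if config.no_discount else config.discount_rate
    settings = SimSettings(discount=DiscountSpec(rate),
                           horizon_years=config.horizon_years,
                           max_age=config.max_age, seed=seed)
    sim_cohort = _sim_cohort(config, seed, state)
    outcomes = run_cohort(sim_cohort, state["fits"], state["cost_params"], settings)
    outcomes.to_csv(out / "outcomes.csv", index=False)
    state.update(outcomes=outcomes, settings=settings, sim_cohort=sim_cohort)
    return {"n_simulated": int(outcomes["patient_id"].nunique()),
            "discount_rate": rate}


def _stage_psa(config: RunConfig, seed: int, out: Path, state: dict) -> dict:
    res = run_psa(config.psa_samples, state["sim_cohort"], state["fits"],
                  state["cost_params"], state["settings"],
                  subsample=config.psa_subsample, wtp=config.wtp, seed=seed)
    res.samples.to_csv(out / "psa_samples.csv", index=False)
    summary = {
        "marginal_icer": res.marginal_icer,
        "ci": res.ci, "prob_dominant": res.prob_dominant,
        "n_samples": res.n_samples, **res.summary,
        "config_hash": config.config_hash(), "master_seed": config.seed,
    }
    (out / "psa_summary.json").write_text(json.dumps(summary, indent=2))
    state["psa"] = res
    return {"n_samples": res.n_samples, "prob_dominant": res.prob_dominant}


def _stage_report(config: RunConfig, seed: int, out: Path, state: dict) -> dict:
    inc = incremental_summary(state["outcomes"], wtp=config.wtp)
    res = state["psa"]
    inc.ci = res.ci
    subgroups = {
        by: {level: r.to_dict() for level, r in
             subgroup_summary(state["outcomes"], state["sim_cohort"], by,
                              wtp=config.wtp).items()}
        for by in ("sex", "age", "clinical_profile")
    }
    curve = ceac(res.samples["delta_cost"].to_numpy(),
                 res.samples["delta_effect"].to_numpy())
    curve.to_csv(out / "ceac.csv", index=False)
    res.samples[["delta_effect", "delta_cost"]].to_csv(out / "ce_plane.csv", index=False)
    report = {"base_case": inc.to_dict(), "subgroups": subgroups,
              "config_hash": config.config_hash(), "master_seed": config.seed}
    (out / "results.json").write_text(json.dumps(report, indent=2))
    return {"icer": inc.icer, "dominance": inc.dominance}


def _stage_validate(config: RunConfig, seed: int, out: Path, state: dict) -> dict:
    res = short_horizon_compare(state["sim_cohort"],
                                state["histories"], state["costs"],
                                state["fits"], state["cost_params"],
                                seed=seed, tau_months=config.tau_months)
    payload = {**res.to_dict(), "config_hash": config.config_hash(),
               "master_seed": config.seed}
    (out / "validation.json").write_text(json.dumps(payload, indent=2, default=str))
    text = (f"Short-horizon check at tau = {config.tau_months} months\n"
            f"  observed  dRMST = {res.observed_delta_rmst:+.4f} y "
            f"(SE {res.observed_delta_rmst_se:.4f})\n"
            f"  simulated dLY   = {res.simulated_delta_ly:+.4f} y "
            f"({'agree' if res.rmst_agree else 'DISAGREE'})\n"
            f"  observed  dCost = {res.observed_delta_cost:+.2f} EUR "
            f"(SE {res.observed_delta_cost_se:.2f})\n"
            f"  simulated dCost = {res.simulated_delta_cost:+.2f} EUR "
            f"({'agree' if res.cost_agree else 'DISAGREE'})\n")
    (out / "validation.txt").write_text(text)
    return {"rmst_agree": res.rmst_agree, "cost_agree": res.cost_agree}


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "fit": _stage_fit,
    "simulate": _stage_simulate,
    "psa": _stage_psa,
    "report": _stage_report,
    "validate": _stage_validate,
}
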