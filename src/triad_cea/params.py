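"""Ground-truth generator parameters and their JSON (de)serialization.

The synthetic-cohort generator is driven by a :class:`GeneratorConfig`:
per-transition Weibull baseline hazards with log-linear covariate effects
and a treatment log hazard ratio, plus right-skewed daily cost
distributions and the covariate mixture of the cohort.

Default values reproduce the structure of a regional claims cohort of
triple-therapy initiators: treatment hazard ratios of 0.91 (CV
hospitalization), 0.79 (death out of hospital), 1.09 (hospital discharge)
and 0.88 (in-hospital death) for the single-pill combination versus the
two-pill combination, daily costs of 602.01 €/day in hospital, 0.15 €/day
of CV outpatient care, and adjusted daily drug costs of 0.54 (SPC) vs
0.52 (two-pill) €/day.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from scipy import stats

from .states import TRANSITION_LABELS, SPC, TWO_PILL

#: covariate order used by every linear predictor in the package
COVARIATE_NAMES = ("age10", "male", "profile_intermediate", "profile_poor", "propensity")


@dataclass
class TransitionTruth:
    """Weibull cause-specific hazard for one transition.

    The baseline hazard, on the scale of years since state entry, is
    ``h0(t) = shape * scale * t**(shape - 1)`` so the cumulative baseline
    hazard is ``H0(t) = scale * t**shape``.  Covariates act
    proportionally: ``h(t|x) = h0(t) * exp(beta'(x - x_ref) + trt*log_hr)``.
    """

    shape: float
    scale: float
    beta: dict[str, float] = field(default_factory=dict)
    log_hr_treatment: float = 0.0

    def validate(self, label: str = "") -> None:
        if not self.shape > 0:
            raise ValueError(f"transition {label}: Weibull shape must be > 0, got {self.shape}")
        if not self.scale > 0:
            raise ValueError(f"transition {label}: Weibull scale must be > 0, got {self.scale}")
        for k in self.beta:
            if k not in COVARIATE_NAMES:
                raise ValueError(f"transition {label}: unknown covariate {k!r} in beta")


@dataclass
class CostTruth:
    """Daily cost distributions, in €/day.

    Hospital and outpatient daily costs are Gamma at the patient level
    (method-of-moments from mean/SD); drug daily cost depends on strategy
    and, mildly, on covariates through log-linear effects (the confounding
    the adjusted drug-cost model must remove).  An SD of 0 degenerates to
    a point mass.
    """

    hosp_daily_mean: float = 602.01
    hosp_daily_sd: float = 684.00
    outpatient_daily_mean: float = 0.15
    outpatient_daily_sd: float = 0.33
    drug_daily_mean: dict[str, float] = field(default_factory=lambda: {SPC: 0.54, TWO_PILL: 0.52})
    drug_daily_sd: float = 0.35
    drug_covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age10": 0.02,
            "male": 0.01,
            "profile_intermediate": 0.03,
            "profile_poor": 0.05,
        }
    )

    def validate(self) -> None:
        for name in ("hosp_daily_mean", "outpatient_daily_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("hosp_daily_sd", "outpatient_daily_sd", "drug_daily_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for s in (SPC, TWO_PILL):
            if s not in self.drug_daily_mean:
                raise ValueError(f"drug_daily_mean missing strategy {s!r}")
            if self.drug_daily_mean[s] < 0:
                raise ValueError(f"drug_daily_mean[{s!r}] must be >= 0")
        for k in self.drug_covariate_effects:
            if k not in COVARIATE_NAMES:
                raise ValueError(f"unknown covariate {k!r} in drug_covariate_effects")


def _default_transitions() -> dict[str, TransitionTruth]:
    ln = math.log
    return {
        "OUT->HOSP": TransitionTruth(
            shape=1.05,
            scale=0.07,
            beta={"age10": 0.25, "male": 0.10, "profile_intermediate": 0.35,
                  "profile_poor": 0.70, "propensity": 0.20},
            log_hr_treatment=ln(0.91),
        ),
        "OUT->DEAD": TransitionTruth(
            shape=1.15,
            scale=0.030,
            beta={"age10": 0.55, "male": 0.15, "profile_intermediate": 0.60,
                  "profile_poor": 1.10, "propensity": 0.20},
            log_hr_treatment=ln(0.79),
        ),
        "HOSP->OUT": TransitionTruth(
            shape=0.90,
            scale=28.0,
            beta={"age10": -0.05, "male": 0.0, "profile_intermediate": -0.10,
                  "profile_poor": -0.20, "propensity": 0.0},
            log_hr_treatment=ln(1.09),
        ),
        "HOSP->DEAD": TransitionTruth(
            shape=1.0,
            scale=1.2,
            beta={"age10": 0.40, "male": 0.10, "profile_intermediate": 0.40,
                  "profile_poor": 0.80, "propensity": 0.10},
            log_hr_treatment=ln(0.88),
        ),
    }


@dataclass
class GeneratorConfig:
    """Truth parameters plus cohort mixture settings.

    Covariate effects in hazards and costs are expressed relative to the
    reference covariate values (population means), so the baseline
    hazards/costs describe an average patient.
    """

    transitions: dict[str, TransitionTruth] = field(default_factory=_default_transitions)
    costs: CostTruth = field(default_factory=CostTruth)

    # cohort mixture
    spc_share: float = 0.31
    age_mean: float = 68.0
    age_sd: float = 11.0
    age_min: float = 40.0
    male_prob: float = 0.47
    profile_probs: tuple[float, float, float] = (0.70, 0.25, 0.05)  # good/intermediate/poor
    #: treatment-assignment log-odds per covariate (SPC users younger,
    #: more often male, healthier)
    assignment_coefs: dict[str, float] = field(
        default_factory=lambda: {"age10": -0.15, "male": 0.15,
                                 "profile_intermediate": -0.20, "profile_poor": -0.40}
    )
    #: SD of the logit-scale jitter turning the true assignment
    #: probability into the recorded propensity-score proxy
    propensity_noise_sd: float = 0.30
    #: index dates spread uniformly over this many days (2015-2018 window)
    entry_window_days: int = 1460
    #: days from the first possible index date to the administrative end
    #: of observation (2019-12-31)
    study_end_day: int = 1826
    #: if True per-patient cost rates are Gamma draws; if False every
    #: patient accrues the mean rates exactly
    cost_noise: bool = True

    def validate(self) -> None:
        for label in TRANSITION_LABELS:
            if label not in self.transitions:
                raise ValueError(f"transitions missing {label!r}")
            self.transitions[label].validate(label)
        self.costs.validate()
        for name in ("spc_share", "male_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.profile_probs) != 3 or any(p < 0 for p in self.profile_probs):
            raise ValueError("profile_probs must be 3 non-negative probabilities")
        if abs(sum(self.profile_probs) - 1.0) > 1e-9:
            raise ValueError("profile_probs must sum to 1")
        if self.age_min < 40.0:
            raise ValueError("age_min must be >= 40 (cohort entry criterion)")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be > 0")
        if self.propensity_noise_sd < 0:
            raise ValueError("propensity_noise_sd must be >= 0")
        if self.entry_window_days < 0 or self.study_end_day <= self.entry_window_days:
            raise ValueError("study_end_day must exceed entry_window_days >= 0")

    # ---- reference covariate values -------------------------------------
    def age_ref10(self) -> float:
        """Population mean of age/10 under the truncated-normal age law."""
        a = (self.age_min - self.age_mean) / self.age_sd
        mean_age = stats.truncnorm.mean(a, math.inf, loc=self.age_mean, scale=self.age_sd)
        return float(mean_age) / 10.0

    def covariate_refs(self) -> dict[str, float]:
        """Reference (population-mean) value of each covariate."""
        return {
            "age10": self.age_ref10(),
            "male": self.male_prob,
            "profile_intermediate": self.profile_probs[1],
            "profile_poor": self.profile_probs[2],
            "propensity": self.spc_share,
        }

    # ---- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["profile_probs"] = list(self.profile_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown generator-config keys: {sorted(unknown)}")
        if "transitions" in d:
            d["transitions"] = {
                label: TransitionTruth(**t) if not isinstance(t, TransitionTruth) else t
                for label, t in d["transitions"].items()
            }
        if "costs" in d and not isinstance(d["costs"], CostTruth):
            d["costs"] = CostTruth(**d["costs"])
        if "profile_probs" in d:
            d["profile_probs"] = tuple(d["profile_probs"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_config() -> GeneratorConfig:
    cfg = GeneratorConfig()
    cfg.validate()
    return cfg
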