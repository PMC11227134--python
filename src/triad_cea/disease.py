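"""Three-state clock-reset multi-state model with flexible parametric hazards.

Each of the four transitions (OUT->HOSP, OUT->DEAD, HOSP->OUT,
HOSP->DEAD) gets its own proportional-hazards survival model in which the
log cumulative hazard is a restricted cubic spline in log sojourn time
(the Royston–Parmar construction):

    ln H(t | x) = s(ln t; gamma) + beta' x

with s a natural cubic spline with ``n_knots`` knots (default 4: two
boundary knots at the extremes of the log event times and two internal
knots at the 33rd/67th percentiles).  Competing transitions censor each
other at the shared sojourn time; time is reset to zero on every state
entry, so the fitted hazards are cause-specific semi-Markov intensities.

Fitting maximizes the right-censored log likelihood

    sum_i  d_i [ ln(ds/du (u_i)) - u_i + eta_i ] - exp(eta_i),

u = ln t, eta = s(u) + beta'x, by quasi-Newton with analytic gradient;
the covariance of the estimate is the inverse observed information
(analytic Hessian).  With both internal-knot coefficients fixed at zero
the model is exactly Weibull, which provides the initialization point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .states import DEAD, SPC, TRANSIENT_STATES, TRANSITION_LABELS, outgoing, transition_label
from .cohort import CENSORED, covariate_matrix

#: covariates the transition models adjust for, in design order
DEFAULT_COVARIATES = ("age10", "male", "profile_intermediate", "profile_poor",
                      "propensity", "treat")

#: covariates centered before fitting (continuous ones)
CONTINUOUS_COVARIATES = ("age10", "propensity")


# --------------------------------------------------------------------------
# restricted cubic spline basis
# --------------------------------------------------------------------------

@dataclass
class SplineSpec:
    """Knots (strictly increasing, on the log-time scale)."""

    knots: np.ndarray

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, float)
        if self.knots.ndim != 1 or len(self.knots) < 2:
            raise ValueError("need at least 2 knots (boundary knots)")
        if not np.all(np.diff(self.knots) > 0):
            raise ValueError(f"knots must be strictly increasing, got {self.knots}")

    @property
    def n_params(self) -> int:
        return len(self.knots)


def rp_basis(u: np.ndarray, spec: SplineSpec) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline basis of the log cumulative hazard and its du-derivative.

    Columns: 1, u, then one restricted truncated-power term per internal
    knot, ``v_j(u) = (u-k_j)+^3 - lam_j (u-k_min)+^3 - (1-lam_j)(u-k_max)+^3``
    with ``lam_j = (k_max-k_j)/(k_max-k_min)``; the construction is linear
    beyond the boundary knots.
    """
    u = np.atleast_1d(np.asarray(u, float))
    if not np.all(np.isfinite(u)):
        raise ValueError("log-time values must be finite")
    k = spec.knots
    kmin, kmax = k[0], k[-1]
    n, m = len(u), len(k)
    basis = np.empty((n, m))
    deriv = np.empty((n, m))
    basis[:, 0] = 1.0
    deriv[:, 0] = 0.0
    basis[:, 1] = u
    deriv[:, 1] = 1.0
    p_min = np.clip(u - kmin, 0.0, None)
    p_max = np.clip(u - kmax, 0.0, None)
    for j, kj in enumerate(k[1:-1], start=2):
        lam = (kmax - kj) / (kmax - kmin)
        pj = np.clip(u - kj, 0.0, None)
        basis[:, j] = pj ** 3 - lam * p_min ** 3 - (1.0 - lam) * p_max ** 3
        deriv[:, j] = 3.0 * (pj ** 2 - lam * p_min ** 2 - (1.0 - lam) * p_max ** 2)
    return basis, deriv


# --------------------------------------------------------------------------
# transition datasets (clock-reset, cause-specific censoring)
# --------------------------------------------------------------------------

def build_transition_datasets(histories: pd.DataFrame,
                              cohort: pd.DataFrame | None = None
                              ) -> dict[str, pd.DataFrame]:
    """Long-format survival datasets, one per transition.

    Every sojourn in a transient state contributes one row to *each*
    competing transition out of that state: the sojourn duration is the
    time (clock reset at state entry), and the event indicator is 1 only
    for the transition actually taken.  Death sojourns contribute nothing.
    If ``cohort`` is given, its covariates (plus ``treat`` = 1 for the
    single-pill strategy) are merged onto every row.
    """
    h = histories
    dur = h["exit_day"].to_numpy(float) - h["entry_day"].to_numpy(float)
    if np.any(dur < 0):
        raise ValueError("history has exit before entry")
    trans_rows = h[h["state"].isin(TRANSIENT_STATES)]
    if np.any((trans_rows["exit_day"] - trans_rows["entry_day"]).to_numpy(float) <= 0):
        raise ValueError("transient sojourn with non-positive duration")
    _check_contiguity(h)

    cov = None
    if cohort is not None:
        cov = covariate_matrix(cohort).copy()
        cov["treat"] = (cohort["strategy"] == SPC).astype(float)
        cov["patient_id"] = cohort["patient_id"].to_numpy()

    out: dict[str, pd.DataFrame] = {}
    for label in TRANSITION_LABELS:
        r, s = label.split("->")
        rows = h[h["state"] == r]
        df = pd.DataFrame({
            "patient_id": rows["patient_id"].to_numpy(),
            "time": rows["exit_day"].to_numpy(float) - rows["entry_day"].to_numpy(float),
            "event": (rows["outcome"] == s).astype(int).to_numpy(),
        })
        if cov is not None:
            df = df.merge(cov, on="patient_id", how="left")
        out[label] = df
    return out


def _check_contiguity(h: pd.DataFrame) -> None:
    if len(h) == 0:
        return
    for pid, grp in h.groupby("patient_id", sort=False):
        g = grp.sort_values("entry_day")
        entries = g["entry_day"].to_numpy(float)
        exits = g["exit_day"].to_numpy(float)
        if entries[0] != 0.0 or g["state"].iloc[0] not in TRANSIENT_STATES:
            raise ValueError(f"patient {pid}: first sojourn must start in a transient "
                             "state at time 0")
        if np.any(entries[1:] != exits[:-1]):
            raise ValueError(f"patient {pid}: sojourns are not contiguous")


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class TransitionFit:
    """Fitted spline-hazard model for one transition."""

    label: str
    spec: SplineSpec
    covariates: tuple[str, ...]
    centers: dict[str, float]
    theta: np.ndarray                 # (gamma..., beta...) stacked
    cov: np.ndarray                   # covariance of theta (observed information)
    loglik: float
    n_events: int
    n_rows: int
    converged: bool
    monotone: bool = True             # ds/du >= 0 over the event-time range
    warnings: list[str] = field(default_factory=list)

    @property
    def n_spline(self) -> int:
        return self.spec.n_params

    @property
    def gamma(self) -> np.ndarray:
        return self.theta[: self.n_spline]

    @property
    def beta(self) -> np.ndarray:
        return self.theta[self.n_spline:]

    # ---- evaluation -----------------------------------------------------
    def _design_row(self, x: dict[str, float] | pd.Series) -> np.ndarray:
        out = np.empty(len(self.covariates))
        for j, name in enumerate(self.covariates):
            try:
                v = float(x[name])
            except (KeyError, IndexError) as exc:
                raise KeyError(f"covariate {name!r} missing from x") from exc
            out[j] = v - self.centers.get(name, 0.0)
        return out

    def linear_predictor(self, x) -> float:
        return float(self._design_row(x) @ self.beta)

    def spline_at(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(s(u), ds/du) for the fitted gamma."""
        basis, deriv = rp_basis(u, self.spec)
        return basis @ self.gamma, deriv @ self.gamma

    def cumulative_hazard(self, t, x) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        if np.any(t <= 0):
            raise ValueError("t must be > 0")
        s, _ = self.spline_at(np.log(t))
        return np.exp(s + self.linear_predictor(x))

    def hazard(self, t, x) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        if np.any(t <= 0):
            raise ValueError("t must be > 0")
        s, dsdu = self.spline_at(np.log(t))
        h = dsdu * np.exp(s + self.linear_predictor(x)) / t
        if np.any(dsdu < 0):
            warnings.warn(f"{self.label}: ds/du < 0 at some times; hazard clipped at 0",
                          RuntimeWarning, stacklevel=2)
            h = np.clip(h, 0.0, None)
        return h

    def hazard_ratio(self, covariate: str = "treat") -> tuple[float, tuple[float, float]]:
        """exp(beta) with 95% Wald CI for one covariate."""
        if covariate not in self.covariates:
            raise KeyError(f"covariate {covariate!r} not in fit ({self.covariates})")
        j = self.n_spline + self.covariates.index(covariate)
        b = self.theta[j]
        se = float(np.sqrt(self.cov[j, j]))
        return float(np.exp(b)), (float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se)))

    # ---- (de)serialization ---------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "knots": self.spec.knots.tolist(),
            "covariates": list(self.covariates),
            "centers": self.centers,
            "theta": self.theta.tolist(),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "n_events": self.n_events,
            "n_rows": self.n_rows,
            "converged": self.converged,
            "monotone": self.monotone,
            "warnings": self.warnings,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionFit":
        return cls(
            label=d["label"],
            spec=SplineSpec(np.asarray(d["knots"], float)),
            covariates=tuple(d["covariates"]),
            centers={k: float(v) for k, v in d["centers"].items()},
            theta=np.asarray(d["theta"], float),
            cov=np.asarray(d["cov"], float),
            loglik=float(d["loglik"]),
            n_events=int(d["n_events"]),
            n_rows=int(d["n_rows"]),
            converged=bool(d["converged"]),
            monotone=bool(d.get("monotone", True)),
            warnings=list(d.get("warnings", [])),
        )

    def replace_theta(self, theta: np.ndarray) -> "TransitionFit":
        """Copy of the fit with a new parameter vector (used by the PSA)."""
        return TransitionFit(
            label=self.label, spec=self.spec, covariates=self.covariates,
            centers=self.centers, theta=np.asarray(theta, float), cov=self.cov,
            loglik=np.nan, n_events=self.n_events, n_rows=self.n_rows,
            converged=self.converged, monotone=self.monotone,
            warnings=list(self.warnings))


class _Likelihood:
    """Negative log likelihood with analytic gradient and Hessian."""

    _EPS = 1e-10
    _PENALTY = 1e6

    def __init__(self, u, d, basis, deriv, x):
        self.u = u
        self.d = d.astype(float)
        self.basis = basis
        self.deriv = deriv
        self.x = x
        self.z = np.hstack([basis, x]) if x.shape[1] else basis
        self.m = basis.shape[1]
        self.ev = d.astype(bool)

    def _parts(self, theta):
        gamma = theta[: self.m]
        eta = self.z @ theta
        dsdu = self.deriv @ gamma
        return eta, dsdu

    def negloglik(self, theta):
        eta, dsdu = self._parts(theta)
        dsdu_e = dsdu[self.ev]
        safe = np.clip(dsdu_e, self._EPS, None)
        ll = np.sum(np.log(safe) - self.u[self.ev] + eta[self.ev]) - np.sum(np.exp(eta))
        penalty = self._PENALTY * np.sum(np.clip(-dsdu_e, 0.0, None))
        return -ll + penalty

    def grad(self, theta):
        eta, dsdu = self._parts(theta)
        w = self.d - np.exp(eta)
        g = self.z.T @ w
        dsdu_e = dsdu[self.ev]
        safe = np.clip(dsdu_e, self._EPS, None)
        gs = np.zeros_like(theta)
        gs[: self.m] = self.deriv[self.ev].T @ (1.0 / safe)
        # penalty gradient where ds/du < 0 at an event
        viol = dsdu_e < 0
        if np.any(viol):
            gs[: self.m] -= self._PENALTY * np.sum(-self.deriv[self.ev][viol], axis=0)
        return -(g + gs)

    def hessian(self, theta):
        eta, dsdu = self._parts(theta)
        w = np.exp(eta)
        h = -(self.z * w[:, None]).T @ self.z
        dsdu_e = np.clip(dsdu[self.ev], self._EPS, None)
        de = self.deriv[self.ev]
        h_s = -(de / dsdu_e[:, None] ** 2).T @ de
        h[: self.m, : self.m] += h_s
        return -h  # Hessian of the NEGATIVE log likelihood


def default_knots(log_event_times: np.ndarray, n_knots: int = 4) -> SplineSpec:
    """Boundary knots at the extremes of the log event times, internal
    knots at equally spaced percentiles (33rd/67th for the 4-knot default)."""
    if n_knots < 2:
        raise ValueError("need at least 2 knots")
    q = np.linspace(0.0, 1.0, n_knots)
    knots = np.quantile(log_event_times, q)
    knots = np.unique(knots)
    if len(knots) < 2:
        # all event times equal: spread an epsilon so the basis is defined
        knots = np.array([knots[0] - 1e-6, knots[0] + 1e-6])
    return SplineSpec(knots)


def fit_transition(dataset: pd.DataFrame,
                   label: str = "",
                   covariates: tuple[str, ...] | None = DEFAULT_COVARIATES,
                   n_knots: int = 4,
                   weibull_only: bool = False,
                   spec: SplineSpec | None = None,
                   max_iter: int = 500,
                   tol: float = 1e-8) -> TransitionFit:
    """Fit the spline log-cumulative-hazard model to one transition dataset.

    ``dataset`` needs columns ``time`` (sojourn days, > 0), ``event``
    (0/1) and the requested covariates.  ``weibull_only=True`` constrains
    the internal-knot coefficients to zero (exact Weibull), which is also
    the initialization of the unconstrained fit.  An explicit ``spec``
    overrides the data-driven knot rule (needed when refitting with the
    knots of a reference model).
    """
    t = dataset["time"].to_numpy(float)
    d = dataset["event"].to_numpy(int)
    if np.any(t <= 0):
        raise ValueError("all sojourn times must be > 0")
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError(f"transition {label or '?'}: no events; cannot fit")

    covariates = tuple(covariates or ())
    centers = {}
    cols = []
    for name in covariates:
        if name not in dataset.columns:
            raise KeyError(f"covariate {name!r} missing from dataset")
        col = dataset[name].to_numpy(float)
        if name in CONTINUOUS_COVARIATES:
            centers[name] = float(col.mean())
            col = col - centers[name]
        cols.append(col)
    x = np.column_stack(cols) if cols else np.empty((len(t), 0))

    u = np.log(t)
    if spec is None:
        spec = default_knots(u[d == 1], 2 if weibull_only else n_knots)
    basis, deriv = rp_basis(u, spec)
    lik = _Likelihood(u, d, basis, deriv, x)

    # Weibull initialization: H(t) = exp(g0) * t, refined by a short fit
    m = spec.n_params
    p = x.shape[1]
    theta0 = np.zeros(m + p)
    theta0[0] = np.log(n_events / t.sum())
    theta0[1] = 1.0
    if m > 2:
        # stage 1: fit the Weibull submodel, then release the spline terms
        wspec = SplineSpec(spec.knots[[0, -1]])
        wb, wd = rp_basis(u, wspec)
        wlik = _Likelihood(u, d, wb, wd, x)
        w0 = np.concatenate([theta0[:2], theta0[m:]])
        wres = minimize(wlik.negloglik, w0, jac=wlik.grad, method="BFGS",
                        options={"maxiter": max_iter, "gtol": 1e-6})
        theta0[:2] = wres.x[:2]
        theta0[m:] = wres.x[2:]

    res = minimize(lik.negloglik, theta0, jac=lik.grad, method="BFGS",
                   options={"maxiter": max_iter, "gtol": 1e-6})
    # polish with Newton steps using the analytic Hessian
    theta = res.x
    for _ in range(25):
        g = lik.grad(theta)
        h = lik.hessian(theta)
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            break
        new = theta - step
        f_old, f_new = lik.negloglik(theta), lik.negloglik(new)
        shrink = 0
        while f_new > f_old and shrink < 30:
            step *= 0.5
            new = theta - step
            f_new = lik.negloglik(new)
            shrink += 1
        if f_new > f_old:
            break
        theta = new
        if f_old - f_new < tol * (1.0 + abs(f_new)):
            break
    converged = bool(res.success or np.linalg.norm(lik.grad(theta)) < 1e-3 * (1 + n_events))

    fit_warnings: list[str] = []
    n_params = spec.n_params + x.shape[1]
    if n_events <= n_params:
        fit_warnings.append(f"only {n_events} events for {n_params} parameters; "
                            "estimates are unreliable")
        warnings.warn(f"{label or 'transition'}: {n_events} events <= {n_params} "
                      "parameters", RuntimeWarning, stacklevel=2)
    hess = lik.hessian(theta)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        fit_warnings.append("singular information matrix; covariance is a pseudo-inverse")
    # symmetrize against round-off
    cov = (cov + cov.T) / 2.0

    # monotonicity monitor on the event-time range
    grid = np.linspace(spec.knots[0], spec.knots[-1], 512)
    _, dsdu = rp_basis(grid, spec)
    mono = bool(np.all(dsdu @ theta[:m] >= 0.0))
    if not mono:
        fit_warnings.append("ds/du < 0 somewhere on the event-time range; "
                            "hazard evaluations clip at 0")
        warnings.warn(f"{label or 'transition'}: non-monotone log cumulative hazard",
                      RuntimeWarning, stacklevel=2)

    return TransitionFit(
        label=label, spec=spec, covariates=covariates, centers=centers,
        theta=theta, cov=cov, loglik=-lik.negloglik(theta),
        n_events=n_events, n_rows=len(t), converged=converged,
        monotone=mono, warnings=fit_warnings)


def fit_all_transitions(histories: pd.DataFrame, cohort: pd.DataFrame,
                        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                        n_knots: int = 4) -> dict[str, TransitionFit]:
    """Build the four clock-reset datasets and fit each transition."""
    datasets = build_transition_datasets(histories, cohort)
    return {label: fit_transition(ds, label=label, covariates=covariates,
                                  n_knots=n_knots)
            for label, ds in datasets.items()}


# --------------------------------------------------------------------------
# fitted-parameter file I/O
# --------------------------------------------------------------------------

def save_fits(fits: dict[str, TransitionFit], path: str | Path,
              cost_params: dict | None = None, meta: dict | None = None) -> None:
    payload = {"transitions": {k: f.to_dict() for k, f in fits.items()}}
    if cost_params is not None:
        payload["costs"] = cost_params
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=2))


def load_fits(path: str | Path) -> tuple[dict[str, TransitionFit], dict | None]:
    payload = json.loads(Path(path).read_text())
    fits = {k: TransitionFit.from_dict(v) for k, v in payload["transitions"].items()}
    return fits, payload.get("costs")
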