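"""Propensity-score models for the matching pipelines.

Two deliberately simple (and, outside scenario A, misspecified) models:

* a baseline logistic regression of the ever-treated indicator on the main
  effects of x1-x10 at the first interval, treating assignment as if it
  happened at baseline; and
* a Cox proportional-hazards model with time-dependent covariate values,
  whose linear predictor serves as a *proxied* time-dependent propensity
  score — the baseline hazard cancels out of pairwise distances, so matching
  only ever uses differences of linear predictors.

Both models use main effects only; squares and interactions present in the
true assignment model are intentionally omitted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError

from .exceptions import EstimationError
from .panel_sim import NEVER_TREATED, PanelDataset

__all__ = [
    "MATCHING_COVARIATES",
    "BaselinePSModel",
    "TDPropensityModel",
    "fit_baseline_logit",
    "fit_td_cox",
    "linear_predictor",
]

#: the ten covariates entering every matching model (x11, x12 are
#: outcome-only and never matched on)
MATCHING_COVARIATES = [f"x{k}" for k in range(1, 11)]

_DEGENERATE_TOL = 1e-12


def _split_degenerate(X: np.ndarray, names: list):
    """Indices of usable columns; degenerate (zero-variance) columns are
    dropped with a warning and contribute 0 to the linear predictor."""
    sd = X.std(axis=0)
    keep = np.where(sd > _DEGENERATE_TOL)[0]
    dropped = [names[j] for j in np.where(sd <= _DEGENERATE_TOL)[0]]
    if dropped:
        warnings.warn(
            f"degenerate covariates dropped from propensity fit: {dropped}",
            stacklevel=3,
        )
    return keep, dropped


@dataclass
class BaselinePSModel:
    """Fitted baseline logistic propensity model (main effects of x1-x10)."""

    coefficients: dict  # name -> log-odds, including "intercept"
    fitted_scores: np.ndarray  # per-subject probability in (0, 1)
    standard_errors: dict = field(default_factory=dict)
    converged: bool = True
    dropped: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "baseline_logit",
                "coefficients": self.coefficients,
                "standard_errors": self.standard_errors,
                "converged": self.converged,
                "dropped": self.dropped,
            }
        )


@dataclass
class TDPropensityModel:
    """Fitted time-dependent Cox model; only the linear predictor is used."""

    coefficients: dict  # name -> log hazard ratio
    covariate_names: list
    standard_errors: dict = field(default_factory=dict)
    converged: bool = True
    dropped: list = field(default_factory=list)

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients.get(n, 0.0) for n in self.covariate_names])

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "td_cox",
                "coefficients": self.coefficients,
                "standard_errors": self.standard_errors,
                "converged": self.converged,
                "dropped": self.dropped,
            }
        )

    def lp_matrix(self, dataset: PanelDataset) -> np.ndarray:
        """Linear predictor beta'x_i(t) for every subject and interval (n, T)."""
        beta = self.beta
        idx = [dataset.covariate_index(n) for n in self.covariate_names]
        return np.einsum("nkt,k->nt", dataset.X[:, idx, :], beta)


def fit_baseline_logit(dataset: PanelDataset,
                       covariates=None) -> BaselinePSModel:
    """ML logistic fit of the ever-treated indicator on covariates at t0.

    Treatment is treated as if assigned at baseline: time-dependent
    covariates enter with their first-interval values only.
    """
    names = list(MATCHING_COVARIATES if covariates is None else covariates)
    z = dataset.ever_treated.astype(float)
    if z.sum() == 0 or z.sum() == len(z):
        raise EstimationError("need at least one treated and one untreated subject")
    X = dataset.values_at(names, interval=1)
    keep, dropped = _split_degenerate(X, names)
    design = sm.add_constant(X[:, keep], has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = sm.Logit(z, design).fit(disp=0, maxiter=100, tol=1e-8)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise EstimationError(f"baseline logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(result.params)):
        raise EstimationError("baseline logistic fit produced non-finite coefficients")
    kept_names = [names[j] for j in keep]
    coefs = {"intercept": float(result.params[0])}
    ses = {"intercept": float(result.bse[0])}
    for j, name in enumerate(kept_names):
        coefs[name] = float(result.params[j + 1])
        ses[name] = float(result.bse[j + 1])
    scores = np.asarray(result.predict(design))
    return BaselinePSModel(coefficients=coefs, fitted_scores=scores,
                           standard_errors=ses,
                           converged=bool(result.mle_retvals.get("converged", True)),
                           dropped=dropped)


def _counting_process_frame(dataset: PanelDataset, names: list) -> pd.DataFrame:
    """Interval-level rows (id, start, stop, event, x...) with subjects
    censored after their treatment interval."""
    n, T = dataset.n_subjects, dataset.n_intervals
    ti = dataset.treat_interval
    last = np.where(ti == NEVER_TREATED, T, ti)  # last interval at risk
    rows_per_subject = last
    ids = np.repeat(np.arange(n), rows_per_subject)
    stops = np.concatenate([np.arange(1, k + 1) for k in rows_per_subject])
    events = np.zeros(len(ids), dtype=bool)
    events[np.cumsum(rows_per_subject) - 1] = ti != NEVER_TREATED
    frame = pd.DataFrame({"id": ids, "start": stops - 1.0, "stop": stops * 1.0,
                          "event": events})
    idx = [dataset.covariate_index(nm) for nm in names]
    frame[names] = dataset.X[ids, :, :][:, idx, :][np.arange(len(ids)), :, stops - 1]
    return frame


def fit_td_cox(dataset: PanelDataset, covariates=None) -> TDPropensityModel:
    """Cox partial-likelihood fit with time-dependent covariates.

    Subjects contribute one counting-process row per interval at risk; the
    event is treatment at that interval.  Heavy ties at the six coarse event
    times are handled by lifelines' Efron approximation.
    """
    names = list(MATCHING_COVARIATES if covariates is None else covariates)
    if int(dataset.ever_treated.sum()) == 0:
        raise EstimationError("no treated subjects: Cox model has no events")
    X_all = np.concatenate([dataset.values_at(names, t)
                            for t in range(1, dataset.n_intervals + 1)])
    keep, dropped = _split_degenerate(X_all, names)
    kept_names = [names[j] for j in keep]
    if not kept_names:
        raise EstimationError("all covariates degenerate; Cox fit impossible")
    frame = _counting_process_frame(dataset, kept_names)
    fitter = CoxTimeVaryingFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(frame, id_col="id", event_col="event",
                       start_col="start", stop_col="stop")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        raise EstimationError(f"time-dependent Cox fit failed: {exc}") from exc
    params = fitter.params_
    if not np.all(np.isfinite(params.to_numpy())):
        raise EstimationError("Cox fit produced non-finite coefficients")
    coefs = {name: float(params[name]) for name in kept_names}
    ses = {name: float(fitter.standard_errors_[name]) for name in kept_names}
    return TDPropensityModel(coefficients=coefs,
                             covariate_names=kept_names,
                             standard_errors=ses, dropped=dropped)


def linear_predictor(model: TDPropensityModel, x_t: np.ndarray) -> "float | np.ndarray":
    """beta'x(t) for a covariate vector (or matrix with covariates in the
    model's column order).  Pairwise matching distance is |lp_i - lp_j|."""
    x_t = np.asarray(x_t, dtype=float)
    return x_t @ model.beta
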