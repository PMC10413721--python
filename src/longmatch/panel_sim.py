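"""Monte Carlo generation of longitudinal panel data with a static treatment
assigned at multiple time points.

Each replicate simulates ``n`` subjects over ``T`` bi-monthly intervals.
Twelve covariates (six binary, six continuous; six time-dependent) are drawn
through a latent Gaussian copula: an exchangeable pairwise correlation
``rho`` is imposed on the latent normals via a shared subject-level factor,
time-dependent covariates evolve through AR(1)/MA(1)/independent-redraw
latent processes with unit marginal variance, and each latent path is mapped
to its configured marginal (Bernoulli by thresholding, Poisson/Gamma by
inverse CDF, normal by location-scale).

Treatment is assigned interval by interval from a logistic model on current
covariate values; a subject can be treated at most once and leaves the
at-risk pool afterwards, so assignment depends only on covariate histories
(no anticipation).  The continuous outcome is linear in covariates with an
additive treatment effect and Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr
from scipy.stats import gamma as gamma_dist
from scipy.stats import poisson as poisson_dist

from .config import CoefficientSet, CovariateSpec, ScenarioConfig
from .exceptions import CalibrationError, ConfigurationError, DataError

__all__ = [
    "PanelDataset",
    "draw_covariate_paths",
    "assign_treatment",
    "generate_outcome",
    "generate_dataset",
    "generate_replicates",
    "calibrate_intercept",
    "evaluate_terms",
    "read_panel_csv",
]

NEVER_TREATED = 0  # treat_interval sentinel; real intervals are 1..T

_U_EPS = 1e-12


@dataclass
class PanelDataset:
    """One simulated panel: covariate paths, treatment timing, outcomes.

    ``X`` has shape ``(n_subjects, n_covariates, n_intervals)`` with
    time-invariant covariates repeated across intervals.  ``treat_interval``
    is 1-based; 0 means never treated.  ``y`` has shape ``(n, T)``.
    """

    X: np.ndarray
    treat_interval: np.ndarray
    y: np.ndarray
    covariate_names: list
    replicate_id: int = 0
    seed: int = 0
    config: Optional[ScenarioConfig] = None

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.X.shape[2]

    @property
    def ever_treated(self) -> np.ndarray:
        return self.treat_interval != NEVER_TREATED

    def treatment_indicator(self) -> np.ndarray:
        """z_it matrix: 1 from the treatment interval onwards."""
        t_grid = np.arange(1, self.n_intervals + 1)
        return (
            (self.treat_interval[:, None] != NEVER_TREATED)
            & (t_grid[None, :] >= self.treat_interval[:, None])
        ).astype(float)

    def covariate_index(self, name: str) -> int:
        return self.covariate_names.index(name)

    def values_at(self, names, interval: int) -> np.ndarray:
        """Covariate matrix (n, len(names)) at a 1-based interval."""
        idx = [self.covariate_index(n) for n in names]
        return self.X[:, idx, interval - 1]

    def to_long_frame(self) -> pd.DataFrame:
        n, K, T = self.X.shape
        z = self.treatment_indicator()
        frame = pd.DataFrame(
            {
                "replicate": np.repeat(self.replicate_id, n * T),
                "subject": np.repeat(np.arange(n), T),
                "interval": np.tile(np.arange(1, T + 1), n),
            }
        )
        for k, name in enumerate(self.covariate_names):
            frame[name] = self.X[:, k, :].reshape(-1)
        frame["z"] = z.reshape(-1)
        frame["y"] = self.y.reshape(-1)
        frame["treat_interval"] = np.repeat(self.treat_interval, T)
        return frame

    def write_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def read_panel_csv(path) -> PanelDataset:
    """Read a long-format panel CSV written by :meth:`PanelDataset.write_csv`."""
    frame = pd.read_csv(path)
    required = {"subject", "interval", "y", "treat_interval"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"panel file missing columns: {sorted(missing)}")
    reserved = {"replicate", "subject", "interval", "z", "y", "treat_interval"}
    names = [c for c in frame.columns if c not in reserved]
    frame = frame.sort_values(["subject", "interval"])
    subjects = frame["subject"].unique()
    intervals = np.sort(frame["interval"].unique())
    n, T = len(subjects), len(intervals)
    X = np.empty((n, len(names), T))
    for k, name in enumerate(names):
        X[:, k, :] = frame[name].to_numpy().reshape(n, T)
    y = frame["y"].to_numpy().reshape(n, T)
    treat = frame.groupby("subject", sort=True)["treat_interval"].first().to_numpy()
    rep = int(frame["replicate"].iloc[0]) if "replicate" in frame.columns else 0
    return PanelDataset(X=X, treat_interval=treat.astype(int), y=y,
                        covariate_names=names, replicate_id=rep)


# ---------------------------------------------------------------------------
# covariate paths
# ---------------------------------------------------------------------------

def _latent_paths(spec: CovariateSpec, n: int, T: int, config: ScenarioConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Standard-normal latent path (n, T) for one covariate, unit marginal
    variance at every interval."""
    if not spec.time_dependent:
        return np.repeat(rng.standard_normal((n, 1)), T, axis=1)
    if spec.process == "iid_redraw":
        return rng.standard_normal((n, T))
    if spec.process == "ar1":
        phi = config.ar_phi
        if not (-1.0 < phi < 1.0):
            raise ConfigurationError(f"ar_phi must be in (-1, 1), got {phi}")
        a = np.empty((n, T))
        a[:, 0] = rng.standard_normal(n)
        innov_sd = math.sqrt(1.0 - phi * phi)
        for t in range(1, T):
            a[:, t] = phi * a[:, t - 1] + innov_sd * rng.standard_normal(n)
        return a
    if spec.process == "ma1":
        theta = config.ma_theta
        eps = rng.standard_normal((n, T + 1))
        return (eps[:, 1:] + theta * eps[:, :-1]) / math.sqrt(1.0 + theta * theta)
    raise ConfigurationError(f"unknown process {spec.process!r}")


def _transform_marginal(latent: np.ndarray, spec: CovariateSpec) -> np.ndarray:
    p = spec.params
    if spec.marginal == "normal":
        return p.get("mu", 0.0) + p.get("sigma", 1.0) * latent
    u = np.clip(ndtr(latent), _U_EPS, 1.0 - _U_EPS)
    if spec.marginal == "bernoulli":
        return (u < p.get("p", 0.5)).astype(float)
    if spec.marginal == "poisson":
        return poisson_dist.ppf(u, p.get("lam", 1.0))
    if spec.marginal == "gamma":
        shape = p.get("shape", 1.0)
        rate = p.get("rate", 1.0)
        return gamma_dist.ppf(u, shape, scale=1.0 / rate)
    raise ConfigurationError(f"unknown marginal {spec.marginal!r}")


def draw_covariate_paths(config: ScenarioConfig, n: int,
                         rng: "np.random.Generator | int") -> np.ndarray:
    """Draw covariate paths (n, K, T) for one replicate.

    The exchangeable pairwise correlation is induced by an interval-level
    latent factor shared across covariates with loading ``sqrt(rho)``; the
    factor itself follows an AR(1) with coefficient ``ar_phi``, and
    time-invariant covariates load on its first-interval value.  Within any
    interval, covariates drawn at that interval correlate at ``rho`` on the
    latent scale, while a high ``rho`` still leaves time-dependent
    covariates imperfectly predictable from baseline.  At ``rho = 0``
    covariates are mutually independent and AR(1)/MA(1) latent
    autocorrelations pass through exactly for normal marginals.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    K, T = len(config.covariates), config.n_intervals
    rho = config.pairwise_rho
    if rho > 0:
        # interval-level common factor, itself AR(1) with the same
        # persistence as the continuous time-dependent covariates: pairwise
        # correlation is exactly rho within every interval for pairs drawn
        # at the same interval, and decays across intervals, so a high rho
        # does NOT make time-dependent covariates predictable from baseline
        phi = config.ar_phi
        shared = np.empty((n, T))
        shared[:, 0] = rng.standard_normal(n)
        for t in range(1, T):
            shared[:, t] = (phi * shared[:, t - 1]
                            + math.sqrt(1.0 - phi * phi) * rng.standard_normal(n))
    else:
        shared = np.zeros((n, T))
    X = np.empty((n, K, T))
    for k, spec in enumerate(config.covariates):
        a = _latent_paths(spec, n, T, config, rng)
        # time-invariant covariates are drawn once, at the first interval
        factor = shared[:, [0]] if not spec.time_dependent else shared
        latent = math.sqrt(rho) * factor + math.sqrt(1.0 - rho) * a
        X[:, k, :] = _transform_marginal(latent, spec)
    return X


# ---------------------------------------------------------------------------
# linear predictors
# ---------------------------------------------------------------------------

def evaluate_terms(X_t: np.ndarray, name_to_idx: dict, terms,
                   coefs: CoefficientSet) -> np.ndarray:
    """Evaluate a symbolic linear predictor on covariate matrix (n, K)."""
    out = np.zeros(X_t.shape[0])
    for term in terms:
        val = np.full(X_t.shape[0], coefs.resolve(term.coef))
        for name, power in term.factors:
            col = X_t[:, name_to_idx[name]]
            val = val * (col if power == 1 else col**power)
        out += val
    return out


# ---------------------------------------------------------------------------
# treatment and outcome
# ---------------------------------------------------------------------------

def assign_treatment(X: np.ndarray, config: ScenarioConfig,
                     rng: "np.random.Generator | int",
                     uniforms: Optional[np.ndarray] = None) -> np.ndarray:
    """Sequentially assign treatment; returns 1-based interval, 0 = never.

    At each interval, every not-yet-treated subject is treated with
    probability ``expit(alpha_0 + linear predictor)`` evaluated on current
    covariate values; treated subjects leave the risk pool.  ``uniforms``
    (n, T) may be supplied for common-random-number calibration.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n, _, T = X.shape
    name_to_idx = {name: k for k, name in enumerate(config.covariate_names)}
    if uniforms is None:
        uniforms = rng.random((n, T))
    treat_interval = np.full(n, NEVER_TREATED, dtype=int)
    at_risk = np.ones(n, dtype=bool)
    alpha0 = config.coefficients.alpha_0_treat
    for t in range(1, T + 1):
        lp = alpha0 + evaluate_terms(X[:, :, t - 1], name_to_idx,
                                     config.treatment_model, config.coefficients)
        bad = ~np.isfinite(lp)
        if bad.any():
            raise DataError(
                f"non-finite treatment linear predictor at interval {t} "
                f"for subjects {np.where(bad)[0][:5].tolist()}"
            )
        newly = at_risk & (uniforms[:, t - 1] < expit(lp))
        treat_interval[newly] = t
        at_risk &= ~newly
    return treat_interval


def generate_outcome(X: np.ndarray, treat_interval: np.ndarray,
                     config: ScenarioConfig,
                     rng: "np.random.Generator | int") -> np.ndarray:
    """Continuous outcome y_it = theta*z_it + covariate terms + N(0, sigma^2)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n, _, T = X.shape
    name_to_idx = {name: k for k, name in enumerate(config.covariate_names)}
    t_grid = np.arange(1, T + 1)
    z = ((treat_interval[:, None] != NEVER_TREATED)
         & (t_grid[None, :] >= treat_interval[:, None])).astype(float)
    y = np.empty((n, T))
    for t in range(1, T + 1):
        y[:, t - 1] = evaluate_terms(X[:, :, t - 1], name_to_idx,
                                     config.outcome_model, config.coefficients)
    y += config.coefficients.theta_true * z
    if config.noise_sigma > 0:
        y += config.noise_sigma * rng.standard_normal((n, T))
    return y


# ---------------------------------------------------------------------------
# replicates
# ---------------------------------------------------------------------------

def _replicate_rng(master_seed: int, replicate_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, replicate_id]))


def generate_dataset(config: ScenarioConfig, replicate_id: int = 0) -> PanelDataset:
    """Generate one replicate, reproducible from (master_seed, replicate_id)."""
    rng = _replicate_rng(config.master_seed, replicate_id)
    X = draw_covariate_paths(config, config.n_subjects, rng)
    treat_interval = assign_treatment(X, config, rng)
    y = generate_outcome(X, treat_interval, config, rng)
    return PanelDataset(X=X, treat_interval=treat_interval, y=y,
                        covariate_names=config.covariate_names,
                        replicate_id=replicate_id, seed=config.master_seed,
                        config=config)


def generate_replicates(config: ScenarioConfig,
                        n_replicates: Optional[int] = None) -> Iterator[PanelDataset]:
    """Stream independent replicates; replicate r depends only on
    (master_seed, r)."""
    m = config.n_replicates if n_replicates is None else n_replicates
    for r in range(m):
        yield generate_dataset(config, r)


# ---------------------------------------------------------------------------
# intercept calibration
# ---------------------------------------------------------------------------

def calibrate_intercept(config: ScenarioConfig, target_rate: float = 1.0 / 3.0,
                        pilot_reps: int = 5, seed: int = 0,
                        tol: float = 0.005, max_iter: int = 100,
                        bracket: tuple = (-30.0, 10.0)) -> float:
    """Find the treatment-model intercept hitting a target ever-treated rate.

    Bisection on ``alpha_0_treat`` using common random numbers: the pilot
    covariate paths and assignment uniforms are drawn once, so the
    ever-treated fraction is a deterministic, monotone step function of the
    intercept and bisection converges cleanly.  Tolerance is on the pilot
    fraction (default +-0.005, half the contract's +-0.01).
    """
    if not (0.0 < target_rate < 1.0):
        raise CalibrationError(f"target_rate must be in (0, 1), got {target_rate}")
    if target_rate <= tol or target_rate >= 1.0 - tol:
        raise CalibrationError(
            f"target rate {target_rate} is indistinguishable from a degenerate "
            f"design at calibration tolerance {tol}; the intercept would run "
            f"to the bracket edge"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 10_007, seed]))
    pilots = []
    for _ in range(pilot_reps):
        X = draw_covariate_paths(config, config.n_subjects, rng)
        U = rng.random((config.n_subjects, config.n_intervals))
        pilots.append((X, U))

    def frac(alpha0: float) -> float:
        cfg = config.with_intercept(alpha0)
        total = 0
        for X, U in pilots:
            ti = assign_treatment(X, cfg, rng, uniforms=U)
            total += int((ti != NEVER_TREATED).sum())
        return total / (pilot_reps * config.n_subjects)

    lo, hi = bracket
    f_lo, f_hi = frac(lo), frac(hi)
    if not (f_lo <= target_rate <= f_hi):
        raise CalibrationError(
            f"target rate {target_rate:.4f} outside achievable range "
            f"[{f_lo:.4f}, {f_hi:.4f}] for intercepts in [{lo}, {hi}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = frac(mid)
        if abs(f_mid - target_rate) <= tol:
            return mid
        if f_mid < target_rate:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    f_final = frac(0.5 * (lo + hi))
    if abs(f_final - target_rate) <= 2 * tol:
        return 0.5 * (lo + hi)
    raise CalibrationError(
        f"bisection did not reach target {target_rate:.4f}; bracket "
        f"[{lo:.6f}, {hi:.6f}] gives fraction {f_final:.4f}"
    )
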