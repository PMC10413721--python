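"""Registry of the seven simulation scenarios.

The base case uses twelve covariates: x1-x5 and x11 Bernoulli(0.5) (x4, x5,
x11 switching "on-off" every interval), x6-x10 and x12 standard normal (x9,
x10, x12 AR(1)).  The true treatment-assignment logit is non-linear and
non-additive (interaction x4*x5, squares x7^2 and x9^2, product x6*x9^2);
the outcome is linear with an additive unit treatment effect.  x4 and x9
affect treatment only; x11 and x12 affect the outcome only; the remaining
eight covariates are confounders.

Scenario variants: A uses a linear-additive treatment model (so the matching
models are correctly specified); B and C add exchangeable pairwise
correlation 0.2 and 0.7; D swaps the AR(1) on x9/x10 for MA(1); E shifts
x9, x10 to N(2,1); F draws x9 ~ Poisson(2) and x10 ~ Gamma(2,1).
"""

from __future__ import annotations

from dataclasses import replace

from .config import CovariateSpec, ScenarioConfig, parse_term
from .exceptions import ConfigurationError
from .panel_sim import calibrate_intercept

__all__ = ["SCENARIO_IDS", "scenario_registry", "calibrated_scenario"]

SCENARIO_IDS = ("base", "A", "B", "C", "D", "E", "F")

_BASE_TREATMENT = (
    "L*x1", "M*x2", "H*x3",
    "L*x4", "H*x5", "M*x4*x5",
    "L*x6", "M*x7", "L*x7^2",
    "H*x8",
    "L*x9^2", "M*x6*x9^2",
    "H*x10",
)

_LINEAR_TREATMENT = (
    "L*x1", "M*x2", "H*x3", "L*x4", "H*x5",
    "L*x6", "M*x7", "H*x8", "L*x9", "H*x10",
)

_OUTCOME = (
    "L*x1", "M*x2", "H*x3", "H*x5",
    "L*x6", "M*x7", "H*x8", "H*x10",
    "L*x11", "L*x12",
)


def _covariates(x9_x10_process: str = "ar1",
                x9_marginal=("normal", {"mu": 0.0, "sigma": 1.0}),
                x10_marginal=("normal", {"mu": 0.0, "sigma": 1.0})):
    bern = ("bernoulli", {"p": 0.5})
    std_norm = ("normal", {"mu": 0.0, "sigma": 1.0})

    def cov(name, marginal, td=False, process="none", treat=True, outc=True):
        kind, params = marginal
        return CovariateSpec(name=name, marginal=kind, params=params,
                             time_dependent=td, process=process,
                             in_treatment_model=treat, in_outcome_model=outc)

    return (
        cov("x1", bern),
        cov("x2", bern),
        cov("x3", bern, outc=True),
        cov("x4", bern, td=True, process="iid_redraw", outc=False),
        cov("x5", bern, td=True, process="iid_redraw"),
        cov("x6", std_norm),
        cov("x7", std_norm),
        cov("x8", std_norm),
        cov("x9", x9_marginal, td=True, process=x9_x10_process, outc=False),
        cov("x10", x10_marginal, td=True, process=x9_x10_process),
        cov("x11", bern, td=True, process="iid_redraw", treat=False),
        cov("x12", std_norm, td=True, process="ar1", treat=False),
    )


def scenario_registry(scenario_id: str, **overrides) -> ScenarioConfig:
    """Return the fully populated configuration for a scenario id.

    Keyword overrides (``n_subjects``, ``n_replicates``, ``master_seed``,
    ``noise_sigma``, ...) are applied on top of the registry entry.  The
    treatment-model intercept defaults to 0 and is normally set by
    :func:`calibrated_scenario`.
    """
    if scenario_id not in SCENARIO_IDS:
        raise ConfigurationError(
            f"unknown scenario {scenario_id!r}; valid ids: {', '.join(SCENARIO_IDS)}"
        )
    treatment = _BASE_TREATMENT
    covariates = _covariates()
    rho = 0.0
    if scenario_id == "A":
        treatment = _LINEAR_TREATMENT
    elif scenario_id == "B":
        rho = 0.2
    elif scenario_id == "C":
        rho = 0.7
    elif scenario_id == "D":
        covariates = _covariates(x9_x10_process="ma1")
    elif scenario_id == "E":
        shifted = ("normal", {"mu": 2.0, "sigma": 1.0})
        covariates = _covariates(x9_marginal=shifted, x10_marginal=shifted)
    elif scenario_id == "F":
        covariates = _covariates(
            x9_marginal=("poisson", {"lam": 2.0}),
            x10_marginal=("gamma", {"shape": 2.0, "rate": 1.0}),
        )
    config = ScenarioConfig(
        scenario_id=scenario_id,
        covariates=covariates,
        treatment_model=tuple(parse_term(t) for t in treatment),
        outcome_model=tuple(parse_term(t) for t in _OUTCOME),
        pairwise_rho=rho,
    )
    if overrides:
        config = replace(config, **overrides)
    return config


def calibrated_scenario(scenario_id: str, target_rate: float = 1.0 / 3.0,
                        pilot_reps: int = 5, seed: int = 0,
                        **overrides) -> ScenarioConfig:
    """Registry entry with the intercept calibrated to the target ever-treated
    rate (1/3 by default, matching the base-case design)."""
    config = scenario_registry(scenario_id, **overrides)
    alpha0 = calibrate_intercept(config, target_rate=target_rate,
                                 pilot_reps=pilot_reps, seed=seed)
    return config.with_intercept(alpha0)
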