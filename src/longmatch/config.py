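"""Scenario configuration: covariate specs, model terms, and coefficient sets.

A simulation scenario is described by twelve covariates (their marginal
distributions, time dependence, and dynamic process), a latent exchangeable
pairwise correlation, and two symbolic linear predictors: one for the
treatment-assignment logit and one for the continuous outcome.  Linear
predictors are lists of :class:`Term`, each a product of covariate powers
multiplied by a named coefficient (``L``, ``M``, ``H`` for the low, medium
and high effect sizes, or a literal number).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

from .exceptions import ConfigurationError

__all__ = [
    "CoefficientSet",
    "CovariateSpec",
    "Term",
    "ScenarioConfig",
    "parse_term",
]

VALID_MARGINALS = {"bernoulli", "normal", "poisson", "gamma"}
VALID_PROCESSES = {"none", "iid_redraw", "ar1", "ma1"}


@dataclass(frozen=True)
class CoefficientSet:
    """Named effect sizes shared by the treatment and outcome models.

    ``alpha_L``/``alpha_M``/``alpha_H`` are the low/medium/high log-odds
    (treatment model) or additive effects (outcome model); ``alpha_0_treat``
    is the treatment-model intercept, usually set by calibration so that a
    target fraction of subjects is ever treated; ``theta_true`` is the true
    additive treatment effect on the outcome scale.
    """

    alpha_L: float = math.log(1.25)
    alpha_M: float = math.log(1.5)
    alpha_H: float = math.log(1.75)
    alpha_0_treat: float = 0.0
    theta_true: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha_0_treat):
            raise ConfigurationError("alpha_0_treat must be finite")

    def resolve(self, label: "str | float") -> float:
        """Map a coefficient label (``L``/``M``/``H``) or number to a value."""
        if isinstance(label, str):
            try:
                return {"L": self.alpha_L, "M": self.alpha_M, "H": self.alpha_H}[label]
            except KeyError:
                raise ConfigurationError(f"unknown coefficient label {label!r}")
        return float(label)


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: marginal distribution, time dependence, and dynamics.

    ``marginal`` is one of ``bernoulli`` (param ``p``), ``normal`` (``mu``,
    ``sigma``), ``poisson`` (``lam``), ``gamma`` (``shape``, ``rate``).
    ``process`` governs the latent-normal dynamics of time-dependent
    covariates: ``iid_redraw`` (fresh draw each interval), ``ar1`` or ``ma1``
    (coefficients held at scenario level).  Time-invariant covariates must
    use ``none``.
    """

    name: str
    marginal: str
    params: dict = field(default_factory=dict)
    time_dependent: bool = False
    process: str = "none"
    in_treatment_model: bool = True
    in_outcome_model: bool = True

    def __post_init__(self) -> None:
        if self.marginal not in VALID_MARGINALS:
            raise ConfigurationError(
                f"unknown marginal {self.marginal!r} for {self.name}; "
                f"valid: {sorted(VALID_MARGINALS)}"
            )
        if self.process not in VALID_PROCESSES:
            raise ConfigurationError(
                f"unknown process {self.process!r} for {self.name}; "
                f"valid: {sorted(VALID_PROCESSES)}"
            )
        if not self.time_dependent and self.process != "none":
            raise ConfigurationError(
                f"{self.name}: time-invariant covariates must use process='none'"
            )
        if self.time_dependent and self.process == "none":
            raise ConfigurationError(
                f"{self.name}: time-dependent covariates need a process"
            )

    @property
    def is_binary(self) -> bool:
        return self.marginal == "bernoulli"


@dataclass(frozen=True)
class Term:
    """One product term of a linear predictor: coef * prod(x_k^p_k)."""

    coef: "str | float"
    factors: tuple  # tuple of (covariate name, integer power)

    def __str__(self) -> str:
        parts = [str(self.coef)]
        for name, power in self.factors:
            parts.append(name if power == 1 else f"{name}^{power}")
        return "*".join(parts)


def parse_term(spec: str) -> Term:
    """Parse ``"M*x4*x5"`` or ``"L*x9^2"`` into a :class:`Term`."""
    parts = [p.strip() for p in spec.split("*")]
    if len(parts) < 2:
        raise ConfigurationError(f"term {spec!r} needs a coefficient and a factor")
    coef: "str | float" = parts[0]
    if coef not in ("L", "M", "H"):
        try:
            coef = float(coef)
        except ValueError:
            raise ConfigurationError(f"bad coefficient {parts[0]!r} in term {spec!r}")
    factors = []
    for p in parts[1:]:
        if "^" in p:
            name, _, pw = p.partition("^")
            factors.append((name, int(pw)))
        else:
            factors.append((p, 1))
    return Term(coef, tuple(factors))


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one simulation scenario."""

    scenario_id: str
    covariates: tuple  # tuple of CovariateSpec
    treatment_model: tuple  # tuple of Term (intercept handled separately)
    outcome_model: tuple  # tuple of Term (treatment effect handled separately)
    pairwise_rho: float = 0.0
    n_subjects: int = 1000
    n_intervals: int = 6
    n_replicates: int = 200
    master_seed: int = 2023
    noise_sigma: float = 1.0
    ar_phi: float = 0.5
    ma_theta: float = 0.5
    coefficients: CoefficientSet = field(default_factory=CoefficientSet)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pairwise_rho < 1.0):
            raise ConfigurationError(
                f"pairwise_rho must be in [0, 1), got {self.pairwise_rho}"
            )
        if self.n_subjects < 1 or self.n_intervals < 1:
            raise ConfigurationError("n_subjects and n_intervals must be >= 1")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate covariate names")
        known = set(names)
        for model, tag in ((self.treatment_model, "treatment"),
                           (self.outcome_model, "outcome")):
            for term in model:
                for name, power in term.factors:
                    if name not in known:
                        raise ConfigurationError(
                            f"{tag} model references unknown covariate {name!r}"
                        )

    @property
    def covariate_names(self) -> list:
        return [c.name for c in self.covariates]

    def covariate(self, name: str) -> CovariateSpec:
        for c in self.covariates:
            if c.name == name:
                return c
        raise ConfigurationError(f"unknown covariate {name!r}")

    def with_intercept(self, alpha_0_treat: float) -> "ScenarioConfig":
        return replace(self, coefficients=replace(self.coefficients,
                                                  alpha_0_treat=alpha_0_treat))

    # ----- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "n_subjects": self.n_subjects,
            "n_intervals": self.n_intervals,
            "n_replicates": self.n_replicates,
            "master_seed": self.master_seed,
            "rho": self.pairwise_rho,
            "noise_sigma": self.noise_sigma,
            "ar_phi": self.ar_phi,
            "ma_theta": self.ma_theta,
            "coefficients": {
                "alpha_L": self.coefficients.alpha_L,
                "alpha_M": self.coefficients.alpha_M,
                "alpha_H": self.coefficients.alpha_H,
                "alpha_0_treat": self.coefficients.alpha_0_treat,
                "theta_true": self.coefficients.theta_true,
            },
            "covariates": [
                {
                    "name": c.name,
                    "marginal": c.marginal,
                    "params": dict(c.params),
                    "time_dependent": c.time_dependent,
                    "process": c.process,
                    "in_treatment_model": c.in_treatment_model,
                    "in_outcome_model": c.in_outcome_model,
                }
                for c in self.covariates
            ],
            "treatment_model": [str(t) for t in self.treatment_model],
            "outcome_model": [str(t) for t in self.outcome_model],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        coefs = d.get("coefficients", {})
        return cls(
            scenario_id=d["scenario_id"],
            covariates=tuple(
                CovariateSpec(
                    name=c["name"],
                    marginal=c["marginal"],
                    params=dict(c.get("params", {})),
                    time_dependent=bool(c.get("time_dependent", False)),
                    process=c.get("process", "none"),
                    in_treatment_model=bool(c.get("in_treatment_model", True)),
                    in_outcome_model=bool(c.get("in_outcome_model", True)),
                )
                for c in d["covariates"]
            ),
            treatment_model=tuple(parse_term(t) for t in d["treatment_model"]),
            outcome_model=tuple(parse_term(t) for t in d["outcome_model"]),
            pairwise_rho=float(d.get("rho", 0.0)),
            n_subjects=int(d.get("n_subjects", 1000)),
            n_intervals=int(d.get("n_intervals", 6)),
            n_replicates=int(d.get("n_replicates", 200)),
            master_seed=int(d.get("master_seed", 2023)),
            noise_sigma=float(d.get("noise_sigma", 1.0)),
            ar_phi=float(d.get("ar_phi", 0.5)),
            ma_theta=float(d.get("ma_theta", 0.5)),
            coefficients=CoefficientSet(
                alpha_L=float(coefs.get("alpha_L", math.log(1.25))),
                alpha_M=float(coefs.get("alpha_M", math.log(1.5))),
                alpha_H=float(coefs.get("alpha_H", math.log(1.75))),
                alpha_0_treat=float(coefs.get("alpha_0_treat", 0.0)),
                theta_true=float(coefs.get("theta_true", 1.0)),
            ),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
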