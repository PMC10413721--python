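"""Shared fixtures: tiny hand-built panels and scaled simulation pipelines."""

import numpy as np
import pytest

from longmatch.config import CoefficientSet, CovariateSpec, ScenarioConfig, parse_term
from longmatch.panel_sim import PanelDataset
from longmatch.scenarios import calibrated_scenario


def make_panel(X, treat_interval, y=None, names=None, config=None):
    """Assemble a PanelDataset from raw arrays (helper for toy fixtures)."""
    X = np.asarray(X, dtype=float)
    n, k, T = X.shape
    if names is None:
        names = [f"x{i + 1}" for i in range(k)]
    if y is None:
        y = np.zeros((n, T))
    return PanelDataset(X=X, treat_interval=np.asarray(treat_interval, dtype=int),
                        y=np.asarray(y, dtype=float), covariate_names=list(names),
                        config=config)


@pytest.fixture(scope="session")
def base_config():
    """Base-case scenario with a calibrated intercept (n=1000, T=6)."""
    return calibrated_scenario("base", master_seed=20230809)


@pytest.fixture(scope="session")
def null_config():
    """Randomized-treatment design: all covariate effects zero, no noise.

    Treatment probabilities are constant, so matched comparisons are
    unconfounded by construction and y_it = z_it exactly.
    """
    coefs = CoefficientSet(alpha_L=0.0, alpha_M=0.0, alpha_H=0.0,
                           alpha_0_treat=-2.5, theta_true=1.0)
    covs = (
        CovariateSpec("x1", "bernoulli", {"p": 0.5}),
        CovariateSpec("x2", "normal", {"mu": 0.0, "sigma": 1.0}),
        CovariateSpec("x3", "normal", {"mu": 0.0, "sigma": 1.0},
                      time_dependent=True, process="ar1"),
    )
    terms = tuple(parse_term(t) for t in ("L*x1", "M*x2", "H*x3"))
    return ScenarioConfig(scenario_id="base", covariates=covs,
                          treatment_model=terms, outcome_model=terms,
                          noise_sigma=0.0, n_subjects=400, n_intervals=4,
                          master_seed=99, coefficients=coefs)
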