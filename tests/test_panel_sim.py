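"""Data-generation contracts: marginals, dynamics, assignment, outcomes."""

import math

import numpy as np
import pytest
from scipy.special import expit

from longmatch.config import CoefficientSet, CovariateSpec, ScenarioConfig, parse_term
from longmatch.exceptions import CalibrationError, ConfigurationError
from longmatch.panel_sim import (
    NEVER_TREATED,
    assign_treatment,
    calibrate_intercept,
    draw_covariate_paths,
    evaluate_terms,
    generate_dataset,
    generate_outcome,
    read_panel_csv,
)
from longmatch.scenarios import scenario_registry

N_BIG = 50_000


@pytest.fixture(scope="module")
def base_paths():
    config = scenario_registry("base", n_subjects=N_BIG)
    return config, draw_covariate_paths(config, N_BIG, rng=7)


class TestMarginals:
    def test_base_case_marginals_at_first_interval(self, base_paths):
        config, X = base_paths
        se_p = math.sqrt(0.25 / N_BIG)
        se_mu = 1.0 / math.sqrt(N_BIG)
        assert abs(X[:, 0, 0].mean() - 0.5) < 4 * se_p  # x1 ~ Bern(0.5)
        assert abs(X[:, 5, 0].mean()) < 4 * se_mu  # x6 ~ N(0,1)
        assert abs(X[:, 5, 0].var() - 1.0) < 4 * math.sqrt(2.0 / N_BIG)

    def test_time_invariant_covariates_constant_over_intervals(self, base_paths):
        _, X = base_paths
        for k in (0, 1, 2, 5, 6, 7):  # x1-x3, x6-x8
            assert np.all(X[:, k, :] == X[:, k, [0]])

    def test_independence_at_rho_zero(self, base_paths):
        _, X = base_paths
        r = np.corrcoef(X[:, 5, 0], X[:, 6, 0])[0, 1]
        assert abs(r) < 4.0 / math.sqrt(N_BIG)

    @pytest.mark.parametrize("sid,means,variances", [
        ("E", {"x9": 2.0, "x10": 2.0}, {"x9": 1.0, "x10": 1.0}),
        ("F", {"x9": 2.0, "x10": 2.0}, {"x9": 2.0, "x10": 2.0}),
    ])
    def test_scenario_marginals(self, sid, means, variances):
        config = scenario_registry(sid)
        X = draw_covariate_paths(config, N_BIG, rng=3)
        for name, mu in means.items():
            k = config.covariate_names.index(name)
            sd = math.sqrt(variances[name])
            assert abs(X[:, k, 0].mean() - mu) < 4 * sd / math.sqrt(N_BIG)
            assert abs(X[:, k, 0].var() - variances[name]) < 0.1

    def test_exchangeable_correlation_scenario_c(self):
        config = scenario_registry("C")  # rho = 0.7
        X = draw_covariate_paths(config, N_BIG, rng=5)
        # continuous-continuous latent correlation passes through for normals
        r = np.corrcoef(X[:, 5, 0], X[:, 6, 0])[0, 1]
        assert abs(r - 0.7) < 0.02
        # same-interval correlation between time-dependent continuous pairs
        r_td = np.corrcoef(X[:, 8, 3], X[:, 9, 3])[0, 1]
        assert abs(r_td - 0.7) < 0.02


class TestDynamics:
    def test_ar1_autocorrelation_matches_closed_form(self, base_paths):
        _, X = base_paths
        x9 = X[:, 8, :]
        se = 4.0 / math.sqrt(N_BIG)
        lag1 = np.corrcoef(x9[:, 2], x9[:, 3])[0, 1]
        lag2 = np.corrcoef(x9[:, 1], x9[:, 3])[0, 1]
        assert abs(lag1 - 0.5) < se
        assert abs(lag2 - 0.25) < se

    def test_ma1_autocorrelation_matches_closed_form(self):
        config = scenario_registry("D")  # MA(1), theta = 0.5
        X = draw_covariate_paths(config, N_BIG, rng=11)
        x9 = X[:, 8, :]
        rho1_expected = 0.5 / (1 + 0.25)
        se = 4.0 / math.sqrt(N_BIG)
        assert abs(np.corrcoef(x9[:, 2], x9[:, 3])[0, 1] - rho1_expected) < se
        assert abs(np.corrcoef(x9[:, 1], x9[:, 3])[0, 1]) < se  # lag 2 vanishes

    def test_on_off_binaries_redrawn_each_interval(self, base_paths):
        _, X = base_paths
        x4 = X[:, 3, :]
        assert abs(np.corrcoef(x4[:, 0], x4[:, 1])[0, 1]) < 4.0 / math.sqrt(N_BIG)


class TestTreatmentAssignment:
    def test_direct_probability_from_coefficients(self):
        # a subject with x3 = 1 and everything else 0, intercept 0:
        # p = expit(ln 1.75) = 0.6364
        config = scenario_registry("base")
        names = {n: i for i, n in enumerate(config.covariate_names)}
        x = np.zeros((1, 12))
        x[0, names["x3"]] = 1.0
        lp = evaluate_terms(x, names, config.treatment_model, config.coefficients)
        assert expit(lp[0]) == pytest.approx(0.6364, abs=1e-4)

    def test_impossible_treatment_never_assigned(self):
        config = scenario_registry("base", n_subjects=200).with_intercept(-1e6)
        X = draw_covariate_paths(config, 200, rng=0)
        ti = assign_treatment(X, config, rng=1)
        assert np.all(ti == NEVER_TREATED)

    def test_no_anticipation(self):
        """Scrambling covariates at intervals > t leaves assignments up to t
        unchanged."""
        config = scenario_registry("base", n_subjects=500).with_intercept(-4.7)
        X = draw_covariate_paths(config, 500, rng=2)
        rng_u = np.random.default_rng(42)
        U = rng_u.random((500, config.n_intervals))
        ti = assign_treatment(X, config, rng=0, uniforms=U)
        t_cut = 3
        X2 = X.copy()
        X2[:, :, t_cut:] = X2[::-1, :, t_cut:]  # permute future intervals
        ti2 = assign_treatment(X2, config, rng=0, uniforms=U)
        early = ti <= t_cut
        early2 = ti2 <= t_cut
        assert np.array_equal(ti[early & (ti > 0)], ti2[early & (ti > 0)])
        assert np.array_equal(early & (ti > 0), early2 & (ti2 > 0))

    def test_at_most_once_and_absorbing_state(self, base_config):
        ds = generate_dataset(base_config, 0)
        z = ds.treatment_indicator()
        assert np.all(np.diff(z, axis=1) >= 0)  # absorbing
        newly = np.diff(np.column_stack([np.zeros(len(z)), z]), axis=1)
        assert newly.sum(axis=1).max() <= 1  # at most one switch


class TestOutcome:
    def test_closed_form_outcomes_without_noise(self):
        config = scenario_registry("base", noise_sigma=0.0, n_subjects=3,
                                   n_intervals=2)
        X = np.zeros((3, 12, 2))
        names = {n: i for i, n in enumerate(config.covariate_names)}
        X[2, names["x1"], :] = 1.0
        X[2, names["x5"], :] = 1.0
        ti = np.array([NEVER_TREATED, 1, NEVER_TREATED])
        y = generate_outcome(X, ti, config, rng=0)
        assert y[0, 0] == 0.0  # everything zero, untreated
        assert y[1, 0] == pytest.approx(1.0)  # the unit treatment effect
        assert y[2, 1] == pytest.approx(math.log(1.25) + math.log(1.75), abs=1e-12)


class TestReplicates:
    def test_determinism_and_independence(self, base_config):
        a = generate_dataset(base_config, 3)
        b = generate_dataset(base_config, 3)
        c = generate_dataset(base_config, 4)
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.treat_interval, b.treat_interval)
        assert np.array_equal(a.y, b.y)
        assert not np.array_equal(a.treat_interval, c.treat_interval)

    def test_long_csv_round_trip(self, base_config, tmp_path):
        ds = generate_dataset(base_config, 0)
        path = tmp_path / "panel.csv"
        ds.write_csv(path)
        back = read_panel_csv(path)
        assert back.covariate_names == ds.covariate_names
        np.testing.assert_allclose(back.X, ds.X)
        np.testing.assert_allclose(back.y, ds.y)
        assert np.array_equal(back.treat_interval, ds.treat_interval)


class TestCalibration:
    def test_closed_form_when_covariates_vanish(self):
        # with all covariates forced to 0 and one interval the ever-treated
        # rate is expit(alpha0), so calibration returns ~logit(target)
        covs = (CovariateSpec("x1", "normal", {"mu": 0.0, "sigma": 0.0}),)
        config = ScenarioConfig(
            scenario_id="base", covariates=covs,
            treatment_model=(parse_term("L*x1"),),
            outcome_model=(parse_term("L*x1"),),
            n_subjects=20_000, n_intervals=1, master_seed=5)
        alpha0 = calibrate_intercept(config, target_rate=0.25, pilot_reps=4)
        assert expit(alpha0) == pytest.approx(0.25, abs=0.01)

    def test_degenerate_target_raises(self, base_config):
        with pytest.raises(CalibrationError):
            calibrate_intercept(base_config, target_rate=1e-9)
        with pytest.raises(CalibrationError):
            calibrate_intercept(base_config, target_rate=1.5)


class TestConfigValidation:
    def test_unknown_marginal_rejected(self):
        with pytest.raises(ConfigurationError):
            CovariateSpec("x1", "cauchy")

    def test_invalid_rho_rejected(self):
        with pytest.raises(ConfigurationError):
            scenario_registry("base", pairwise_rho=1.2)

    def test_model_referencing_unknown_covariate_rejected(self):
        covs = (CovariateSpec("x1", "bernoulli", {"p": 0.5}),)
        with pytest.raises(ConfigurationError):
            ScenarioConfig(scenario_id="base", covariates=covs,
                           treatment_model=(parse_term("L*x9"),),
                           outcome_model=())

    def test_time_dependence_requires_process(self):
        with pytest.raises(ConfigurationError):
            CovariateSpec("x1", "normal", time_dependent=True, process="none")
        with pytest.raises(ConfigurationError):
            CovariateSpec("x1", "normal", time_dependent=False, process="ar1")
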