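"""Generalized Mahalanobis distance, lexical loss, and the genetic search."""

import numpy as np
import pytest

from longmatch.exceptions import ConfigurationError
from longmatch.genmatch import (
    GeneticSearchConfig,
    RiskSetMatchingProblem,
    WeightMatrix,
    evaluate_candidate,
    evolve_weights,
    generalized_mahalanobis,
    lexical_compare,
    longitudinal_genetic_match,
    match_with_weights,
    _whiten,
)
from longmatch.panel_sim import generate_dataset
from longmatch.propensity import fit_td_cox
from longmatch.scenarios import calibrated_scenario


def random_pd(rng, k):
    A = rng.normal(size=(k, k))
    return A @ A.T + k * np.eye(k) * 0.1


class TestGeneralizedMahalanobis:
    def test_zero_difference(self):
        S = np.eye(3)
        assert generalized_mahalanobis(np.ones(3), np.ones(3), S,
                                       WeightMatrix.identity(3)) == 0.0

    def test_euclidean_case(self):
        d = generalized_mahalanobis(np.array([3.0, 4.0]), np.zeros(2),
                                    np.eye(2), WeightMatrix.identity(2))
        assert d == pytest.approx(5.0)

    def test_identity_weights_equal_classical_mahalanobis(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = rng.integers(2, 6)
            S = random_pd(rng, k)
            x, y = rng.normal(size=k), rng.normal(size=k)
            got = generalized_mahalanobis(x, y, S, WeightMatrix.identity(k))
            expected = np.sqrt((x - y) @ np.linalg.inv(S) @ (x - y))
            assert got == pytest.approx(expected, abs=1e-10)

    def test_weighted_case_matches_dense_oracle(self):
        # oracle: explicit dense inverse of the lower Cholesky factor
        S = np.array([[2.0, 1.0], [1.0, 2.0]])
        W = WeightMatrix(np.array([1.0, 4.0]))
        d_vec = np.array([1.0, 1.0])
        L = np.linalg.cholesky(S)
        A = np.linalg.inv(L)
        expected = np.sqrt(d_vec @ A.T @ np.diag(W.diagonal) @ A @ d_vec)
        got = generalized_mahalanobis(d_vec, np.zeros(2), S, W)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_symmetry_and_self_distance(self):
        rng = np.random.default_rng(1)
        S = random_pd(rng, 4)
        W = WeightMatrix(rng.uniform(0.1, 5.0, size=4))
        x, y = rng.normal(size=4), rng.normal(size=4)
        assert generalized_mahalanobis(x, y, S, W) == pytest.approx(
            generalized_mahalanobis(y, x, S, W))
        assert generalized_mahalanobis(x, x, S, W) == 0.0

    def test_weight_matrix_validation(self):
        with pytest.raises(ConfigurationError):
            WeightMatrix(np.array([-1.0, 1.0]))
        with pytest.raises(ConfigurationError):
            WeightMatrix(np.zeros(3))


class TestLexicalCompare:
    def test_first_element_decides(self):
        assert lexical_compare(np.array([0.30, 0.9]),
                               np.array([0.20, 0.99])) == 1

    def test_tie_broken_at_second_element(self):
        assert lexical_compare(np.array([0.2, 0.5]), np.array([0.2, 0.4])) == 1

    def test_equality_and_antisymmetry(self):
        a, b = np.array([0.2, 0.5]), np.array([0.5, 0.1])
        assert lexical_compare(a, a.copy()) == 0
        assert lexical_compare(a, b) == -lexical_compare(b, a)

    def test_compares_sorted_values_not_positions(self):
        # (0.9, 0.1) sorted is (0.1, 0.9): the worst p-value is compared first
        assert lexical_compare(np.array([0.9, 0.2]), np.array([0.1, 0.99])) == 1


def toy_problem(rng, n_t=8, n_c=16, k=2, boot_seed=5, informative=True):
    """Two-variable risk set where variable 1 separates two clusters."""
    Xt = rng.normal(size=(n_t, k))
    Xc = rng.normal(size=(n_c, k))
    if informative:
        Xt[:, 0] += 2.0
        Xc[: n_c // 2, 0] += 2.0  # half the controls share the treated cluster
    M = np.vstack([Xt, Xc])
    S = np.cov(M, rowvar=False)
    Z = _whiten(M, S)
    return RiskSetMatchingProblem(
        interval=1, treated_ids=np.arange(n_t),
        control_ids=np.arange(n_t, n_t + n_c),
        Z_treated=Z[:n_t], Z_controls=Z[n_t:],
        bal_treated=Xt, bal_controls=Xc,
        binary=np.zeros(k, dtype=bool), boot_seed=boot_seed)


class TestMatchWithWeights:
    def test_scale_invariance_of_matched_cohort(self):
        rng = np.random.default_rng(2)
        prob = toy_problem(rng)
        w = rng.uniform(0.1, 10.0, size=2)
        a = match_with_weights(prob.Z_treated, prob.Z_controls, w)
        b = match_with_weights(prob.Z_treated, prob.Z_controls, 37.0 * w)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y) if x.dtype.kind == "i" \
                else np.testing.assert_allclose(x, y)

    def test_loss_scale_invariance(self):
        rng = np.random.default_rng(3)
        prob = toy_problem(rng)
        w = np.array([1.0, 3.0])
        la = evaluate_candidate(WeightMatrix(w), prob, n_bootstrap=100)
        lb = evaluate_candidate(WeightMatrix(5.0 * w), prob, n_bootstrap=100)
        np.testing.assert_allclose(la, lb)

    def test_perfect_overlap_gives_all_ones_loss(self):
        rng = np.random.default_rng(4)
        Xt = rng.normal(size=(6, 2))
        M = np.vstack([Xt, Xt])  # controls identical point-for-point
        S = np.cov(M, rowvar=False)
        Z = _whiten(M, S)
        prob = RiskSetMatchingProblem(
            interval=1, treated_ids=np.arange(6), control_ids=np.arange(6, 12),
            Z_treated=Z[:6], Z_controls=Z[6:], bal_treated=Xt, bal_controls=Xt,
            binary=np.zeros(2, dtype=bool), boot_seed=1)
        loss = evaluate_candidate(WeightMatrix.identity(2), prob,
                                  n_bootstrap=100)
        np.testing.assert_allclose(loss, 1.0)


class TestEvolveWeights:
    def _search_config(self, **kw):
        defaults = dict(population_size=12, max_generations=8,
                        wait_generations=3, n_bootstrap=100, seed=7)
        defaults.update(kw)
        return GeneticSearchConfig(**defaults)

    def test_elitist_monotone_best_loss(self):
        rng = np.random.default_rng(5)
        prob = toy_problem(rng)
        trace = []
        evolve_weights(prob, self._search_config(), trace=trace)
        losses = [np.array(t["best_loss"]) for t in trace]
        for a, b in zip(losses, losses[1:]):
            assert lexical_compare(b, a) >= 0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        prob = toy_problem(rng)
        w1 = evolve_weights(prob, self._search_config())
        w2 = evolve_weights(prob, self._search_config())
        np.testing.assert_array_equal(w1.diagonal, w2.diagonal)

    def test_reaches_grid_search_optimum(self):
        """The search should do at least as well as a coarse ratio grid."""
        rng = np.random.default_rng(8)
        prob = toy_problem(rng, n_t=10, n_c=20)
        grid_best = None
        for ratio in 10.0 ** np.linspace(-3, 3, 25):
            loss = evaluate_candidate(WeightMatrix(np.array([ratio, 1.0])),
                                      prob, n_bootstrap=100)
            if grid_best is None or lexical_compare(loss, grid_best) > 0:
                grid_best = loss
        found = evolve_weights(prob, self._search_config(max_generations=12))
        ga_loss = evaluate_candidate(found, prob, n_bootstrap=100)
        assert ga_loss[0] >= grid_best[0] - 0.05

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            GeneticSearchConfig(population_size=1)
        with pytest.raises(ConfigurationError):
            GeneticSearchConfig(weight_domain=(5.0, 1.0))
        with pytest.raises(ConfigurationError):
            GeneticSearchConfig(include_ps="everywhere")


@pytest.fixture(scope="module")
def small_scenario():
    return calibrated_scenario("base", n_subjects=250, master_seed=77)


class TestLongitudinalGeneticMatch:
    def test_zero_generations_reduces_to_mahalanobis(self, small_scenario):
        ds = generate_dataset(small_scenario, 0)
        model = fit_td_cox(ds)
        cfg = GeneticSearchConfig(max_generations=0, seed=0)
        cohort = longitudinal_genetic_match(ds, model, cfg)
        assert cohort.n_pairs >= ds.ever_treated.sum()
        # every treated subject appears at exactly one interval
        by_treated = {}
        for tid, t in zip(cohort.treated_id, cohort.interval):
            by_treated.setdefault(tid, set()).add(t)
        assert all(len(v) == 1 for v in by_treated.values())
        assert set(by_treated) == set(np.where(ds.ever_treated)[0])

    def test_full_run_is_reproducible(self, small_scenario):
        ds = generate_dataset(small_scenario, 1)
        model = fit_td_cox(ds)
        cfg = GeneticSearchConfig(population_size=8, max_generations=3,
                                  n_bootstrap=100, seed=3)
        a = longitudinal_genetic_match(ds, model, cfg)
        b = longitudinal_genetic_match(ds, model, cfg)
        np.testing.assert_array_equal(a.treated_id, b.treated_id)
        np.testing.assert_array_equal(a.control_id, b.control_id)
        np.testing.assert_allclose(a.weight, b.weight)

    def test_search_does_not_degrade_identity_balance(self, small_scenario):
        """The optimized cohort's worst mean p-value should not fall below
        the unoptimized (identity Mahalanobis) cohort's by more than noise."""
        from longmatch.balance import aggregate_balance

        ds = generate_dataset(small_scenario, 2)
        model = fit_td_cox(ds)
        ident = longitudinal_genetic_match(
            ds, model, GeneticSearchConfig(max_generations=0, seed=0))
        tuned = longitudinal_genetic_match(
            ds, model, GeneticSearchConfig(population_size=10,
                                           max_generations=5,
                                           n_bootstrap=100, seed=0))
        p_ident = aggregate_balance(ident, ds, n_boot=300, seed=1).p_values()
        p_tuned = aggregate_balance(tuned, ds, n_boot=300, seed=1).p_values()
        assert p_tuned.min() >= p_ident.min() - 0.10
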