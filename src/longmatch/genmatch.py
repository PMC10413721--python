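"""Longitudinal genetic matching.

Within each risk set, candidate diagonal weight matrices ``W`` reshape a
generalized Mahalanobis distance

    d(x_i, x_j; W) = sqrt((x_i - x_j)' (S^{-1/2})' W (S^{-1/2}) (x_i - x_j)),

where ``S^{-1/2}`` is the inverse of the lower Cholesky factor of the sample
covariance ``S`` of the matching variables (the ten covariates at the risk
set's interval, with the proxied time-dependent propensity score included —
on the hazard scale, as the leading column — by default).  A real-coded evolutionary search proposes weight vectors, matches
1:1 with replacement and ties under each candidate, scores the matched
cohort by its sorted vector of balance p-values (bootstrapped KS and paired
t), and compares candidates lexically: the smallest p-value is maximized
first, then the next smallest, and so on.  Elitism guarantees the best loss
vector never degrades across generations.  With ``W = I`` the distance is
the classical Mahalanobis distance, and a zero-generation search reduces the
method to plain Mahalanobis risk-set matching.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .balance import bootstrap_ks_p, paired_t_p, standardized_difference
from .exceptions import ConfigurationError, MatchingError
from .matchers import MatchedCohort, build_risk_sets
from .panel_sim import PanelDataset
from .propensity import MATCHING_COVARIATES, TDPropensityModel

__all__ = [
    "WeightMatrix",
    "GeneticSearchConfig",
    "RiskSetMatchingProblem",
    "generalized_mahalanobis",
    "lexical_compare",
    "match_with_weights",
    "evaluate_candidate",
    "evolve_weights",
    "longitudinal_genetic_match",
]

_RIDGE = 1e-8
_REL_TIE = 1e-9

_DEFAULT_OPERATOR_MIX = {
    "clone_best": 0.10,
    "uniform_mutation": 0.20,
    "boundary_mutation": 0.10,
    "nonuniform_mutation": 0.20,
    "arithmetic_crossover": 0.20,
    "heuristic_crossover": 0.10,
    "resample": 0.10,
}


@dataclass(frozen=True)
class WeightMatrix:
    """Diagonal weight matrix for the generalized Mahalanobis distance."""

    diagonal: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diagonal, dtype=float)
        object.__setattr__(self, "diagonal", d)
        if (d < 0).any():
            raise ConfigurationError("weight matrix entries must be >= 0")
        if not (d > 0).any():
            raise ConfigurationError("weight matrix needs at least one positive entry")

    @classmethod
    def identity(cls, k: int) -> "WeightMatrix":
        return cls(np.ones(k))


@dataclass(frozen=True)
class GeneticSearchConfig:
    """Hyper-parameters of the per-risk-set evolutionary search."""

    population_size: int = 50
    max_generations: int = 30
    wait_generations: int = 4
    weight_domain: tuple = (0.0, 1000.0)
    n_bootstrap: int = 250
    seed: int = 0
    operator_mix: dict = field(default_factory=lambda: dict(_DEFAULT_OPERATOR_MIX))
    include_ps: str = "distance+loss"  # distance+loss | distance | none
    loss: str = "lexical-pv"  # lexical-pv | mean-stddiff

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        lo, hi = self.weight_domain
        if not (lo >= 0.0 and lo < hi):
            raise ConfigurationError("weight_domain must satisfy 0 <= lo < hi")
        if self.include_ps not in ("distance", "distance+loss", "none"):
            raise ConfigurationError(f"unknown include_ps {self.include_ps!r}")
        if self.loss not in ("lexical-pv", "mean-stddiff"):
            raise ConfigurationError(f"unknown loss {self.loss!r}")


# ---------------------------------------------------------------------------
# distance
# ---------------------------------------------------------------------------

def _chol_inverse_factor(S: np.ndarray):
    """Inverse lower Cholesky factor of S, ridge-regularized if needed."""
    S = np.asarray(S, dtype=float)
    k = S.shape[0]
    ridge = 0.0
    for _ in range(4):
        try:
            L = cholesky(S + ridge * np.eye(k), lower=True)
            return solve_triangular(L, np.eye(k), lower=True)
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10.0, _RIDGE * np.trace(S) / k, _RIDGE)
    diag = np.diag(S)
    offenders = [int(i) for i in np.where(diag <= diag.max() * 1e-12)[0]]
    raise np.linalg.LinAlgError(
        f"covariance matrix singular even after regularization; "
        f"near-degenerate variables at positions {offenders}"
    )


def generalized_mahalanobis(x_i, x_j, S, W: WeightMatrix) -> float:
    """Weighted Mahalanobis distance between two covariate vectors.

    With ``W = I`` this is the classical Mahalanobis distance under
    covariance ``S``.
    """
    d = np.asarray(x_i, dtype=float) - np.asarray(x_j, dtype=float)
    A = _chol_inverse_factor(S)
    z = A @ d
    return float(np.sqrt(np.sum(W.diagonal * z * z)))


def _whiten(M: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Transform rows of M so weighted Euclidean distance in the image equals
    the generalized Mahalanobis distance."""
    return M @ _chol_inverse_factor(S).T


def match_with_weights(Z_treated: np.ndarray, Z_controls: np.ndarray,
                       weights: np.ndarray):
    """1:1 NN matching (replacement, ties) under diagonal weights in whitened
    space; returns (treated_pos, control_pos, pair_weight).

    Ties are detected with a relative tolerance so the matched cohort is
    invariant to rescaling all weights by a positive constant.
    """
    # ||z_i - z_j||^2_w expanded into three BLAS-friendly pieces
    tw = Z_treated * weights
    d2 = ((tw * Z_treated).sum(axis=1)[:, None]
          + (Z_controls * weights * Z_controls).sum(axis=1)[None, :]
          - 2.0 * tw @ Z_controls.T)
    np.maximum(d2, 0.0, out=d2)
    dmin = d2.min(axis=1)
    tie_mask = d2 <= dmin[:, None] * (1.0 + _REL_TIE) + 1e-24
    k = tie_mask.sum(axis=1)
    treated_pos = np.repeat(np.arange(len(Z_treated)), k)
    control_pos = np.where(tie_mask)[1]
    pair_weight = np.repeat(1.0 / k, k)
    return treated_pos, control_pos, pair_weight


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def lexical_compare(a: np.ndarray, b: np.ndarray) -> int:
    """Compare two loss vectors lexically on their sorted values.

    Returns 1 if ``a`` is better (larger value at the first index where the
    ascending-sorted vectors differ), -1 if ``b`` is better, 0 on equality.
    """
    sa, sb = np.sort(a), np.sort(b)
    if len(sa) != len(sb):
        raise ValueError("loss vectors must have equal length")
    for va, vb in zip(sa, sb):
        if va > vb:
            return 1
        if va < vb:
            return -1
    return 0


@dataclass
class RiskSetMatchingProblem:
    """Matching data for one risk set, prepared for the genetic search.

    ``Z_treated``/``Z_controls`` are whitened matching matrices (weighted
    Euclidean distance there equals the generalized Mahalanobis distance);
    ``bal_treated``/``bal_controls`` hold the raw values of the variables
    whose balance enters the loss, with ``binary`` flagging which get the
    paired t-test only.
    """

    interval: int
    treated_ids: np.ndarray
    control_ids: np.ndarray
    Z_treated: np.ndarray
    Z_controls: np.ndarray
    bal_treated: np.ndarray
    bal_controls: np.ndarray
    binary: np.ndarray
    boot_seed: int = 0

    @property
    def n_weights(self) -> int:
        return self.Z_treated.shape[1]

    @property
    def loss_length(self) -> int:
        return int(self.binary.sum() + 2 * (~self.binary).sum())


def _batched_paired_t(Vt: np.ndarray, Vc: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted paired t-test p-values for all columns at once."""
    from scipy import stats

    d = Vt - Vc
    wsum = w.sum()
    mean = (w[:, None] * d).sum(axis=0) / wsum
    denom = max(wsum - 1.0, 1e-12)
    var = (w[:, None] * (d - mean) ** 2).sum(axis=0) / denom
    p = np.empty(d.shape[1])
    degenerate = var <= 0.0
    p[degenerate] = np.where(np.isclose(mean[degenerate], 0.0), 1.0, 0.0)
    ok = ~degenerate
    if ok.any():
        t_stat = mean[ok] / np.sqrt(var[ok] / wsum)
        p[ok] = 2.0 * stats.t.sf(np.abs(t_stat), df=wsum - 1.0)
    return p


def _batched_bootstrap_ks(Vt: np.ndarray, Vc: np.ndarray, w: np.ndarray,
                          n_boot: int, seed: int) -> np.ndarray:
    """Bootstrapped KS p-values for all (continuous) columns at once.

    Same statistic and pooled-resample null as
    :func:`longmatch.balance.bootstrap_ks_p`, batched over columns: one set
    of pooled pair indices is drawn and reused across columns, and the
    per-column sorts run as a single 3-D argsort.
    """
    n_pairs, n_cols = Vt.shape
    pool = np.vstack([Vt, Vc])  # (2P, J)
    pw = np.concatenate([w, w])
    # observed weighted KS per column
    contrib = np.concatenate([w / w.sum(), -w / w.sum()])
    order = np.argsort(pool, axis=0, kind="stable")
    v_sorted = np.take_along_axis(pool, order, axis=0)
    cdf = np.cumsum(contrib[order], axis=0)
    valid = np.empty(pool.shape, dtype=bool)
    valid[:-1] = v_sorted[:-1] != v_sorted[1:]
    valid[-1] = True
    d_obs = np.max(np.abs(cdf) * valid, axis=0)
    # pooled-resample null, common pair indices across columns
    n1 = n2 = max(2, int(round(w.sum())))
    m = n1 + n2
    rng = np.random.default_rng(seed)
    cum = np.cumsum(pw / pw.sum())
    cum[-1] = 1.0
    idx = np.searchsorted(cum, rng.random((n_boot, m)))
    draws = pool[idx]  # (n_boot, m, J)
    labels = np.concatenate([np.full(n1, 1.0 / n1), np.full(n2, -1.0 / n2)])
    order_b = np.argsort(draws, axis=1, kind="stable")
    z = np.take_along_axis(draws, order_b, axis=1)
    cdf_b = np.cumsum(labels[order_b], axis=1)
    valid_b = np.empty(z.shape, dtype=bool)
    valid_b[:, :-1] = z[:, :-1] != z[:, 1:]
    valid_b[:, -1] = True
    d_boot = np.max(np.abs(cdf_b) * valid_b, axis=1)  # (n_boot, J)
    return (d_boot >= d_obs[None, :] - 1e-12).mean(axis=0)


def evaluate_candidate(W: WeightMatrix, problem: RiskSetMatchingProblem,
                       n_bootstrap: int = 250,
                       loss: str = "lexical-pv") -> np.ndarray:
    """Loss vector for one candidate weight matrix (sorted ascending).

    Matches the risk set under ``W``, then scores balance of each loss
    variable on the matched cohort: binary variables contribute their paired
    t-test p-value; continuous variables contribute both the bootstrapped KS
    and the paired t-test p-values.  The bootstrap seed is fixed per risk
    set, so the loss is a deterministic function of ``W``.
    """
    if len(problem.control_ids) == 0:
        return np.zeros(problem.loss_length if loss == "lexical-pv" else 1)
    tp, cp, w = match_with_weights(problem.Z_treated, problem.Z_controls,
                                   W.diagonal)
    if loss == "mean-stddiff":
        sds = [standardized_difference(problem.bal_treated[tp, j],
                                       problem.bal_controls[cp, j], w, w)
               for j in range(problem.bal_treated.shape[1])]
        return np.array([-float(np.mean(sds))])
    Vt = problem.bal_treated[tp]
    Vc = problem.bal_controls[cp]
    p_t = _batched_paired_t(Vt, Vc, w)
    cont = ~problem.binary
    if cont.any():
        p_ks = _batched_bootstrap_ks(Vt[:, cont], Vc[:, cont], w,
                                     n_bootstrap, problem.boot_seed)
        pvals = np.concatenate([p_t, p_ks])
    else:
        pvals = p_t
    return np.sort(pvals)


# ---------------------------------------------------------------------------
# evolutionary search
# ---------------------------------------------------------------------------

def _tournament(rng, population, losses):
    i, j = rng.integers(len(population), size=2)
    return population[i] if lexical_compare(losses[i], losses[j]) >= 0 else population[j]


def _make_child(op: str, rng, population, losses, best, lo, hi, frac_done):
    k = len(best)
    if op == "clone_best":
        return best.copy()
    if op == "resample":
        return rng.uniform(lo, hi, size=k)
    parent = _tournament(rng, population, losses).copy()
    if op == "uniform_mutation":
        parent[rng.integers(k)] = rng.uniform(lo, hi)
        return parent
    if op == "boundary_mutation":
        parent[rng.integers(k)] = lo if rng.random() < 0.5 else hi
        return parent
    if op == "nonuniform_mutation":
        j = rng.integers(k)
        span = (hi - lo) * (1.0 - frac_done) ** 2
        parent[j] = np.clip(parent[j] + rng.uniform(-span, span), lo, hi)
        return parent
    other = _tournament(rng, population, losses)
    if op == "arithmetic_crossover":
        lam = rng.random()
        return lam * parent + (1.0 - lam) * other
    if op == "heuristic_crossover":
        better, worse = (parent, other) if rng.random() < 0.5 else (other, parent)
        return np.clip(better + rng.random() * (better - worse), lo, hi)
    raise ConfigurationError(f"unknown operator {op!r}")


def evolve_weights(problem: RiskSetMatchingProblem,
                   config: GeneticSearchConfig,
                   trace: "list | None" = None) -> WeightMatrix:
    """Evolutionary maximization of the lexical balance loss for one risk set.

    Elitism carries the best candidate into every generation, so the
    best-so-far loss vector is lexically non-decreasing.  The search stops
    at ``max_generations`` or after ``wait_generations`` without
    improvement; it is a pure function of (problem, config).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, problem.interval, 7919]))
    lo, hi = config.weight_domain
    k = problem.n_weights
    ops = list(config.operator_mix.keys())
    probs = np.array([config.operator_mix[o] for o in ops], dtype=float)
    probs = probs / probs.sum()

    def sanitize(w):
        w = np.clip(w, lo, hi)
        if not (w > 0).any():
            w = rng.uniform(max(lo, 1e-6 * hi), hi, size=k)
        return w

    population = [np.ones(k)]
    population += [sanitize(rng.uniform(lo, hi, size=k))
                   for _ in range(config.population_size - 1)]
    losses = [evaluate_candidate(WeightMatrix(w), problem, config.n_bootstrap,
                                 config.loss) for w in population]
    best_idx = max(range(len(population)),
                   key=functools.cmp_to_key(lambda i, j: lexical_compare(losses[i], losses[j])))
    best_w, best_loss = population[best_idx].copy(), losses[best_idx]
    if trace is not None:
        trace.append({"generation": 0, "best_loss": best_loss.tolist(),
                      "best_weights": best_w.tolist()})
    stall = 0
    for gen in range(1, config.max_generations + 1):
        frac_done = gen / max(config.max_generations, 1)
        new_pop = [best_w.copy()]
        while len(new_pop) < config.population_size:
            op = rng.choice(ops, p=probs)
            new_pop.append(sanitize(_make_child(op, rng, population, losses,
                                                best_w, lo, hi, frac_done)))
        population = new_pop
        losses = [evaluate_candidate(WeightMatrix(w), problem,
                                     config.n_bootstrap, config.loss)
                  for w in population]
        improved = False
        for w, loss in zip(population, losses):
            if lexical_compare(loss, best_loss) > 0:
                best_w, best_loss, improved = w.copy(), loss, True
        stall = 0 if improved else stall + 1
        if trace is not None:
            trace.append({"generation": gen, "best_loss": best_loss.tolist(),
                          "best_weights": best_w.tolist()})
        if stall >= config.wait_generations:
            break
    return WeightMatrix(best_w)


# ---------------------------------------------------------------------------
# full longitudinal run
# ---------------------------------------------------------------------------

def _build_problem(dataset: PanelDataset, lp: np.ndarray, rs,
                   config: GeneticSearchConfig) -> RiskSetMatchingProblem:
    names = MATCHING_COVARIATES
    t = rs.interval
    M_t = dataset.values_at(names, t)[rs.treated_ids]
    M_c = dataset.values_at(names, t)[rs.control_ids]
    if config.include_ps != "none":
        # proxied PS on the hazard scale, exp(beta'x): the raw linear
        # predictor is exactly collinear with the ten covariates, which
        # would void the PS direction after whitening.  The column goes
        # FIRST: under triangular (Cholesky) whitening the first whitened
        # coordinate is the PS itself, so a large first weight lets the
        # search reproduce pure propensity-score matching.
        M_t = np.column_stack([np.exp(lp[rs.treated_ids, t - 1]), M_t])
        M_c = np.column_stack([np.exp(lp[rs.control_ids, t - 1]), M_c])
    M_all = np.vstack([M_t, M_c])
    S = np.cov(M_all, rowvar=False)
    Z_all = _whiten(M_all, S)
    n_t = len(rs.treated_ids)
    binary = np.array([dataset.config.covariate(n).is_binary if dataset.config
                       else False for n in names])
    bal_t = dataset.values_at(names, t)[rs.treated_ids]
    bal_c = dataset.values_at(names, t)[rs.control_ids]
    if config.include_ps == "distance+loss":
        bal_t = np.column_stack([bal_t, lp[rs.treated_ids, t - 1]])
        bal_c = np.column_stack([bal_c, lp[rs.control_ids, t - 1]])
        binary = np.append(binary, False)  # loss assesses lp as continuous
    return RiskSetMatchingProblem(
        interval=t, treated_ids=rs.treated_ids, control_ids=rs.control_ids,
        Z_treated=Z_all[:n_t], Z_controls=Z_all[n_t:],
        bal_treated=bal_t, bal_controls=bal_c, binary=binary,
        boot_seed=config.seed * 613 + t,
    )


def longitudinal_genetic_match(dataset: PanelDataset,
                               td_model: TDPropensityModel,
                               config: "GeneticSearchConfig | None" = None,
                               trace_log: "list | None" = None) -> MatchedCohort:
    """Genetic-algorithm matching within every risk set, in time order.

    For each risk set the matching matrix is the ten covariates at the risk
    set's interval plus (by default) the Cox linear predictor; the weight
    matrix is optimized by :func:`evolve_weights` and the final 1:1 match
    uses the optimized distance with replacement and ties.  Matched controls
    stay eligible at later intervals, including as treated subjects.
    """
    config = GeneticSearchConfig() if config is None else config
    lp = td_model.lp_matrix(dataset)
    pairs_t, pairs_c, pairs_int, pairs_w = [], [], [], []
    unmatched = []
    for rs in build_risk_sets(dataset):
        if len(rs.control_ids) == 0:
            unmatched.append(rs.treated_ids)
            continue
        problem = _build_problem(dataset, lp, rs, config)
        trace = [] if trace_log is not None else None
        if config.max_generations > 0 and config.population_size > 1:
            W = evolve_weights(problem, config, trace=trace)
        else:
            W = WeightMatrix.identity(problem.n_weights)
        if trace_log is not None:
            trace_log.append({"interval": rs.interval, "trace": trace})
        tp, cp, w = match_with_weights(problem.Z_treated, problem.Z_controls,
                                       W.diagonal)
        pairs_t.append(rs.treated_ids[tp])
        pairs_c.append(rs.control_ids[cp])
        pairs_int.append(np.full(len(tp), rs.interval))
        pairs_w.append(w)
    if not pairs_t:
        raise MatchingError("no risk set could be matched")
    return MatchedCohort(
        treated_id=np.concatenate(pairs_t),
        control_id=np.concatenate(pairs_c),
        interval=np.concatenate(pairs_int),
        weight=np.concatenate(pairs_w),
        method="genmatch",
        replicate_id=dataset.replicate_id,
        unmatched_ids=(np.concatenate(unmatched) if unmatched
                       else np.array([], dtype=int)),
    )
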