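"""Covariate-balance diagnostics for matched cohorts.

All statistics are weight-aware: matching with replacement and ties hands
each pair a weight (1/k for k tied controls), and those weights enter means,
variances, ECDFs and paired differences as frequency weights.

Balance is summarized three ways, following common practice in longitudinal
matching studies:

* absolute standardized differences (x100), thresholds <10 balanced,
  10-20 weakly imbalanced, >20 strongly imbalanced;
* bootstrapped two-sample Kolmogorov-Smirnov p-values for continuous
  covariates (pooled-resample null, robust to ties);
* paired t-test p-values for binary covariates;

with p > 0.10 balanced, 0.05-0.10 weakly imbalanced, < 0.05 strongly
imbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matchers import MatchedCohort
from .panel_sim import PanelDataset
from .propensity import MATCHING_COVARIATES

__all__ = [
    "standardized_difference",
    "bootstrap_ks_p",
    "paired_t_p",
    "classify_p",
    "classify_std_diff",
    "BalanceReport",
    "aggregate_balance",
    "mean_balance",
]


def _weighted_mean_var(values: np.ndarray, weights: np.ndarray):
    """Frequency-weighted mean and unbiased variance."""
    w = np.asarray(weights, dtype=float)
    v = np.asarray(values, dtype=float)
    wsum = w.sum()
    mean = float(np.sum(w * v) / wsum)
    denom = wsum - 1.0
    if denom <= 0:
        return mean, 0.0
    var = float(np.sum(w * (v - mean) ** 2) / denom)
    return mean, var


def standardized_difference(treated: np.ndarray, control: np.ndarray,
                            treated_weights=None, control_weights=None) -> float:
    """Absolute standardized difference x100:
    100 * |mean_t - mean_c| / sqrt((var_t + var_c) / 2).

    Returns 0 when both pooled variances vanish and the means agree, and
    ``inf`` when the means differ with zero pooled variance.
    """
    tw = np.ones(len(treated)) if treated_weights is None else treated_weights
    cw = np.ones(len(control)) if control_weights is None else control_weights
    mt, vt = _weighted_mean_var(treated, tw)
    mc, vc = _weighted_mean_var(control, cw)
    pooled = np.sqrt((vt + vc) / 2.0)
    if pooled == 0.0:
        return 0.0 if np.isclose(mt, mc) else float("inf")
    return float(100.0 * abs(mt - mc) / pooled)


def _ks_stat_weighted(v1, w1, v2, w2) -> float:
    """Two-sample KS statistic between weighted ECDFs, tie-aware."""
    values = np.concatenate([v1, v2])
    contrib = np.concatenate([w1 / w1.sum(), -w2 / w2.sum()])
    order = np.argsort(values, kind="stable")
    v = values[order]
    cdf = np.cumsum(contrib[order])
    valid = np.empty(len(v), dtype=bool)
    valid[:-1] = v[:-1] != v[1:]
    valid[-1] = True
    return float(np.max(np.abs(cdf[valid])))


def bootstrap_ks_p(treated: np.ndarray, control: np.ndarray,
                   control_weights=None, treated_weights=None,
                   n_boot: int = 1000, seed: int = 0) -> float:
    """Bootstrapped two-sample KS p-value on weighted matched samples.

    The observed statistic compares weighted ECDFs; the null distribution
    resamples both arms from the pooled weighted empirical distribution,
    which remains valid in the presence of ties.  The p-value is the
    fraction of resampled statistics at least as large as the observed one.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    tw = np.ones(len(t)) if treated_weights is None else np.asarray(treated_weights, float)
    cw = np.ones(len(c)) if control_weights is None else np.asarray(control_weights, float)
    d_obs = _ks_stat_weighted(t, tw, c, cw)
    if d_obs == 0.0:
        return 1.0
    pooled = np.concatenate([t, c])
    probs = np.concatenate([tw, cw])
    probs = probs / probs.sum()
    n1 = max(2, int(round(tw.sum())))
    n2 = max(2, int(round(cw.sum())))
    rng = np.random.default_rng(seed)
    draws = pooled[rng.choice(len(pooled), size=(n_boot, n1 + n2), p=probs)]
    labels = np.concatenate([np.full(n1, 1.0 / n1), np.full(n2, -1.0 / n2)])
    order = np.argsort(draws, axis=1, kind="stable")
    z = np.take_along_axis(draws, order, axis=1)
    cdf = np.cumsum(labels[order], axis=1)
    valid = np.empty(z.shape, dtype=bool)
    valid[:, :-1] = z[:, :-1] != z[:, 1:]
    valid[:, -1] = True
    d_boot = np.max(np.abs(cdf) * valid, axis=1)
    return float(np.mean(d_boot >= d_obs - 1e-12))


def paired_t_p(treated: np.ndarray, control: np.ndarray,
               weights=None) -> float:
    """Weighted paired t-test p-value on within-pair differences.

    Weights are frequency weights: the effective sample size is their sum
    (the number of matched treated subjects when ties carry weight 1/k).
    Zero-variance differences give p = 1 if all differences are 0, else 0.
    """
    d = np.asarray(treated, dtype=float) - np.asarray(control, dtype=float)
    w = np.ones(len(d)) if weights is None else np.asarray(weights, float)
    mean, var = _weighted_mean_var(d, w)
    n = w.sum()
    if var == 0.0 or n <= 1:
        return 1.0 if np.isclose(mean, 0.0) else 0.0
    t_stat = mean / np.sqrt(var / n)
    return float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))


def classify_p(p: float) -> str:
    if p < 0.05:
        return "strongly imbalanced"
    if p <= 0.10:
        return "weakly imbalanced"
    return "balanced"


def classify_std_diff(sd: float) -> str:
    if sd > 20.0:
        return "strongly imbalanced"
    if sd >= 10.0:
        return "weakly imbalanced"
    return "balanced"


@dataclass
class BalanceReport:
    """Per-covariate balance table for one matched cohort.

    ``table`` columns: covariate, std_diff, sd_class, p_value, test,
    p_class.  ``scope`` is ``treatment-time`` (values at each pair's
    matching interval) or ``baseline`` (values at the first interval).
    """

    table: pd.DataFrame
    method: str
    scope: str
    replicate_id: int = 0

    def n_balanced(self, on: str = "p") -> int:
        col = "p_class" if on == "p" else "sd_class"
        return int((self.table[col] == "balanced").sum())

    def p_values(self) -> pd.Series:
        return self.table.set_index("covariate")["p_value"]

    def write_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "scope", self.scope)
        out.insert(0, "method", self.method)
        out.to_csv(path, index=False)


def _is_binary(dataset: PanelDataset, name: str, values: np.ndarray) -> bool:
    if dataset.config is not None:
        return dataset.config.covariate(name).is_binary
    return bool(np.isin(np.unique(values), (0.0, 1.0)).all())


def aggregate_balance(cohort: MatchedCohort, dataset: PanelDataset,
                      at: str = "treatment-time", covariates=None,
                      n_boot: int = 1000, seed: int = 0) -> BalanceReport:
    """Pooled (across-interval) balance report for a matched cohort.

    Each pair contributes its treated and control covariate values at the
    pair's matching interval (or at the first interval for the ``baseline``
    scope), weighted by the pair weight.  Continuous covariates are tested
    with the bootstrapped KS test, binary covariates with the weighted
    paired t-test.
    """
    if at not in ("treatment-time", "baseline"):
        raise ValueError(f"unknown balance scope {at!r}")
    names = list(MATCHING_COVARIATES if covariates is None else covariates)
    if cohort.n_pairs == 0:
        raise ValueError("empty matched cohort")
    t_idx = cohort.interval - 1 if at == "treatment-time" else np.zeros(
        cohort.n_pairs, dtype=int)
    w = cohort.weight
    rows = []
    for j, name in enumerate(names):
        k = dataset.covariate_index(name)
        tv = dataset.X[cohort.treated_id, k, t_idx]
        cv = dataset.X[cohort.control_id, k, t_idx]
        sd = standardized_difference(tv, cv, w, w)
        if _is_binary(dataset, name, dataset.X[:, k, :]):
            test = "paired-t"
            p = paired_t_p(tv, cv, w)
        else:
            test = "KS"
            p = bootstrap_ks_p(tv, cv, control_weights=w, treated_weights=w,
                               n_boot=n_boot, seed=seed * 1009 + j)
        rows.append({"covariate": name, "std_diff": sd,
                     "sd_class": classify_std_diff(sd),
                     "p_value": p, "test": test, "p_class": classify_p(p)})
    return BalanceReport(table=pd.DataFrame(rows), method=cohort.method,
                         scope=at, replicate_id=cohort.replicate_id)


def mean_balance(reports) -> pd.DataFrame:
    """Average balance across replicates and classify the means.

    Returns one row per covariate with the mean standardized difference,
    mean p-value, and classifications applied to those means — the
    convention used when reporting how many covariates a method balanced.
    """
    tables = [r.table for r in reports]
    stacked = pd.concat(tables, ignore_index=True)
    grouped = stacked.groupby("covariate", sort=False).agg(
        mean_std_diff=("std_diff", "mean"),
        mean_p=("p_value", "mean"),
        test=("test", "first"),
    ).reset_index()
    grouped["sd_class"] = grouped["mean_std_diff"].map(classify_std_diff)
    grouped["p_class"] = grouped["mean_p"].map(classify_p)
    return grouped
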