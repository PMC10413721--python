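"""Experiment orchestration: scenarios x replicates x matching methods.

A plan names the scenarios, the matching methods to compare, and the Monte
Carlo size.  For every scenario the treatment-model intercept is calibrated
once (ever-treated rate 1/3 by default); each replicate then generates a
panel, fits the requested propensity models, builds matched cohorts,
estimates the treatment effect, and optionally computes aggregate balance.
Replicate-level work is a pure function of (master_seed, scenario,
replicate), so results are independent of execution order and can be
parallelized across replicates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import balance as bal
from .evaluate import estimate_effect, summarize
from .exceptions import ConfigurationError, LongmatchError
from .genmatch import GeneticSearchConfig, longitudinal_genetic_match
from .matchers import nn_match_baseline, sequential_rsm
from .panel_sim import generate_dataset
from .propensity import fit_baseline_logit, fit_td_cox
from .scenarios import calibrated_scenario

__all__ = ["ExperimentPlan", "run_replicate", "run_experiment"]

VALID_METHODS = ("baseline_ps", "td_ps", "genmatch")


@dataclass
class ExperimentPlan:
    """What to run: scenarios, methods, sizes, seed, output location."""

    scenarios: tuple = ("base",)
    methods: tuple = ("baseline_ps", "td_ps")
    n_replicates: int = 200
    n_subjects: int = 1000
    master_seed: int = 2023
    out_dir: "str | Path | None" = None
    n_jobs: int = 1
    compute_balance: bool = False
    balance_boot: int = 1000
    target_rate: float = 1.0 / 3.0
    genetic: GeneticSearchConfig = field(default_factory=GeneticSearchConfig)
    max_failure_rate: float = 0.05

    def __post_init__(self) -> None:
        if not self.methods:
            raise ConfigurationError("methods must be non-empty")
        for m in self.methods:
            if m not in VALID_METHODS:
                raise ConfigurationError(
                    f"unknown method {m!r}; valid: {VALID_METHODS}")


def run_replicate(config, replicate_id: int, methods,
                  genetic: "GeneticSearchConfig | None" = None,
                  compute_balance: bool = False, balance_boot: int = 1000):
    """All requested methods on one replicate; returns
    {method: (EffectEstimate, BalanceReport | None)}."""
    dataset = generate_dataset(config, replicate_id)
    out = {}
    needs_cox = any(m in methods for m in ("td_ps", "genmatch"))
    td_model = fit_td_cox(dataset) if needs_cox else None
    for method in methods:
        if method == "baseline_ps":
            cohort = nn_match_baseline(fit_baseline_logit(dataset), dataset)
        elif method == "td_ps":
            cohort = sequential_rsm(td_model, dataset)
        else:
            gcfg = genetic if genetic is not None else GeneticSearchConfig()
            cohort = longitudinal_genetic_match(dataset, td_model, gcfg)
        estimate = estimate_effect(cohort, dataset)
        report = None
        if compute_balance:
            report = bal.aggregate_balance(cohort, dataset,
                                           n_boot=balance_boot,
                                           seed=replicate_id)
        out[method] = (estimate, report)
    return out


def _replicate_worker(plan, config, r):
    try:
        return r, run_replicate(config, r, plan.methods, plan.genetic,
                                plan.compute_balance, plan.balance_boot), None
    except LongmatchError as exc:  # per-replicate failures are logged, not fatal
        return r, None, str(exc)


def run_experiment(plan: ExperimentPlan) -> dict:
    """Run the full plan; returns a result bundle and optionally writes files.

    The bundle maps scenario id to ``{"summaries": {method:
    SimulationSummary}, "estimates": DataFrame, "balance": DataFrame | None,
    "failures": list}``.  If more than ``max_failure_rate`` of replicates
    fail in a scenario, the run aborts.
    """
    out_dir = Path(plan.out_dir) if plan.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    bundle = {}
    for scenario_id in plan.scenarios:
        config = calibrated_scenario(
            scenario_id, target_rate=plan.target_rate,
            n_subjects=plan.n_subjects, n_replicates=plan.n_replicates,
            master_seed=plan.master_seed)
        results, failures = [], []
        if plan.n_jobs > 1:
            from joblib import Parallel, delayed

            jobs = Parallel(n_jobs=plan.n_jobs)(
                delayed(_replicate_worker)(plan, config, r)
                for r in range(plan.n_replicates))
        else:
            jobs = (_replicate_worker(plan, config, r)
                    for r in range(plan.n_replicates))
        for r, res, err in jobs:
            if err is not None:
                failures.append({"replicate": r, "error": err})
                warnings.warn(f"replicate {r} failed: {err}")
            else:
                results.append(res)
        if len(failures) > plan.max_failure_rate * plan.n_replicates:
            raise LongmatchError(
                f"scenario {scenario_id}: {len(failures)} of "
                f"{plan.n_replicates} replicates failed")
        estimates = {m: [res[m][0] for res in results] for m in plan.methods}
        summaries = {m: summarize(estimates[m],
                                  theta_true=config.coefficients.theta_true,
                                  scenario_id=scenario_id)
                     for m in plan.methods}
        est_frame = pd.DataFrame(
            [{"scenario": scenario_id, "method": m, "replicate": e.replicate_id,
              "theta_hat": e.theta_hat, "var_hat": e.var_hat, "se_hat": e.se_hat,
              "n_subjects": e.n_subjects, "n_unmatched": e.n_unmatched}
             for m in plan.methods for e in estimates[m]])
        balance_frame = None
        if plan.compute_balance:
            per_method = []
            for m in plan.methods:
                reports = [res[m][1] for res in results]
                mean_tab = bal.mean_balance(reports)
                mean_tab.insert(0, "method", m)
                mean_tab.insert(0, "scenario", scenario_id)
                per_method.append(mean_tab)
            balance_frame = pd.concat(per_method, ignore_index=True)
        bundle[scenario_id] = {
            "config": config,
            "summaries": summaries,
            "estimates": est_frame,
            "balance": balance_frame,
            "failures": failures,
        }
        if out_dir is not None:
            est_frame.to_csv(out_dir / f"estimates_{scenario_id}.csv", index=False)
            pd.concat([s.to_frame() for s in summaries.values()],
                      ignore_index=True).to_csv(
                out_dir / f"summary_{scenario_id}.csv", index=False)
            if balance_frame is not None:
                balance_frame.to_csv(out_dir / f"balance_{scenario_id}.csv",
                                     index=False)
            with open(out_dir / f"log_{scenario_id}.json", "w") as fh:
                json.dump({"scenario": scenario_id,
                           "alpha_0_treat": config.coefficients.alpha_0_treat,
                           "n_replicates": plan.n_replicates,
                           "failures": failures}, fh, indent=2)
    return bundle
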