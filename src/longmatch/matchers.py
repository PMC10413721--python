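"""Risk-set construction and 1:1 nearest-neighbour matchers.

Matching is always with replacement and with ties: all controls whose
distance to a treated subject is within ``1e-12`` of the minimum are kept,
each carrying weight 1/k so the total control weight per treated subject is
one.  The baseline matcher compares ever-treated to never-treated subjects
on the fitted baseline propensity score; the sequential risk-set matcher
walks intervals in time order and matches within each risk set on the
absolute difference of Cox linear predictors, so matched controls remain
eligible later — including as treated subjects at their own treatment
interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import MatchingError
from .panel_sim import NEVER_TREATED, PanelDataset
from .propensity import BaselinePSModel, TDPropensityModel

__all__ = [
    "RiskSet",
    "MatchedCohort",
    "build_risk_sets",
    "nearest_neighbour_pairs",
    "nn_match_baseline",
    "sequential_rsm",
]

TIE_TOL = 1e-12


@dataclass(frozen=True)
class RiskSet:
    """Subjects eligible at interval t: newly treated vs not-yet-treated."""

    interval: int
    treated_ids: np.ndarray
    control_ids: np.ndarray


@dataclass
class MatchedCohort:
    """Flat pair list (treated, control, interval, weight) for one method."""

    treated_id: np.ndarray
    control_id: np.ndarray
    interval: np.ndarray
    weight: np.ndarray
    method: str = ""
    replicate_id: int = 0
    unmatched_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_pairs(self) -> int:
        return len(self.treated_id)

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": self.replicate_id,
                "method": self.method,
                "interval": self.interval,
                "treated_id": self.treated_id,
                "control_id": self.control_id,
                "weight": self.weight,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_risk_sets(dataset: PanelDataset) -> list:
    """One risk set per interval with >= 1 newly treated subject.

    Controls at t are subjects not yet treated at t: treated strictly later
    or never.  A subject treated at t never reappears as a control at any
    later interval, so control pools shrink over time.
    """
    ti = dataset.treat_interval
    if not dataset.ever_treated.any():
        warnings.warn("dataset has no treated subjects; no risk sets")
        return []
    risk_sets = []
    for t in range(1, dataset.n_intervals + 1):
        treated = np.where(ti == t)[0]
        if len(treated) == 0:
            continue
        controls = np.where((ti == NEVER_TREATED) | (ti > t))[0]
        risk_sets.append(RiskSet(interval=t, treated_ids=treated,
                                 control_ids=controls))
    return risk_sets


def nearest_neighbour_pairs(treated_scores: np.ndarray,
                            control_scores: np.ndarray,
                            tie_tol: float = TIE_TOL):
    """1:1 nearest-neighbour match on a scalar score, with replacement/ties.

    Returns ``(treated_pos, control_pos, weight)`` index arrays into the
    input score vectors; each treated subject's tied controls share weight
    1/k.  Vectorized via a sorted-control binary search.
    """
    treated_scores = np.asarray(treated_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    if control_scores.size == 0:
        raise MatchingError("no controls available")
    order = np.argsort(control_scores, kind="stable")
    sc = control_scores[order]
    pos = np.searchsorted(sc, treated_scores)
    left = np.clip(pos - 1, 0, len(sc) - 1)
    right = np.clip(pos, 0, len(sc) - 1)
    dmin = np.minimum(np.abs(treated_scores - sc[left]),
                      np.abs(treated_scores - sc[right]))
    lo = np.searchsorted(sc, treated_scores - dmin - tie_tol, side="left")
    hi = np.searchsorted(sc, treated_scores + dmin + tie_tol, side="right")
    k = hi - lo
    total = int(k.sum())
    starts = np.repeat(lo, k)
    offsets = np.arange(total) - np.repeat(np.cumsum(k) - k, k)
    control_pos = order[starts + offsets]
    treated_pos = np.repeat(np.arange(len(treated_scores)), k)
    weight = np.repeat(1.0 / k, k)
    return treated_pos, control_pos, weight


def nn_match_baseline(model: BaselinePSModel,
                      dataset: PanelDataset) -> MatchedCohort:
    """Match ever-treated to never-treated subjects on the baseline PS.

    Pairs are tagged with the treated partner's treatment interval so that
    downstream outcome comparison happens at the same calendar time.
    """
    treated = np.where(dataset.ever_treated)[0]
    controls = np.where(~dataset.ever_treated)[0]
    if len(controls) == 0:
        raise MatchingError("no never-treated subjects to serve as controls")
    if len(treated) == 0:
        raise MatchingError("no treated subjects to match")
    tp, cp, w = nearest_neighbour_pairs(model.fitted_scores[treated],
                                        model.fitted_scores[controls])
    return MatchedCohort(
        treated_id=treated[tp],
        control_id=controls[cp],
        interval=dataset.treat_interval[treated[tp]],
        weight=w,
        method="baseline_ps",
        replicate_id=dataset.replicate_id,
    )


def sequential_rsm(model: TDPropensityModel,
                   dataset: PanelDataset) -> MatchedCohort:
    """Sequential risk-set matching on the proxied time-dependent PS.

    Within each risk set, treated subjects are matched to the not-yet-treated
    control(s) minimizing |beta'x_i(t) - beta'x_j(t)|.  Risk sets with no
    controls leave their treated subjects unmatched (recorded, warned, and
    excluded from effect estimation).
    """
    lp = model.lp_matrix(dataset)
    pairs_t, pairs_c, pairs_int, pairs_w = [], [], [], []
    unmatched = []
    for rs in build_risk_sets(dataset):
        if len(rs.control_ids) == 0:
            warnings.warn(
                f"risk set at interval {rs.interval} has no controls; "
                f"{len(rs.treated_ids)} treated subjects left unmatched"
            )
            unmatched.append(rs.treated_ids)
            continue
        tp, cp, w = nearest_neighbour_pairs(lp[rs.treated_ids, rs.interval - 1],
                                            lp[rs.control_ids, rs.interval - 1])
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
        method="td_ps",
        replicate_id=dataset.replicate_id,
        unmatched_ids=(np.concatenate(unmatched) if unmatched
                       else np.array([], dtype=int)),
    )
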