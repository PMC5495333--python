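"""Construction of the adjustable graft-failure score (AdGFS).

The score combines the conditional survival tree with the forest's variable
importances:

* the raw weight of a risk factor is the ratio of its VIMP to the VIMP of
  the last retained variable; variables splitting at the same tree depth
  share their tier's (rounded mean) weight; rounded weights (>= 1) are
  doubled onto the even-integer scale;
* the baseline score of a terminal node adds, along its root-to-leaf
  branch, the weight of every risk factor for which the branch takes the
  *adverse* side (the daughter with the lower ten-year Kaplan-Meier
  survival); the all-favorable branch scores 0;
* factors ranked by the forest but absent from the tree (typically the two
  time-dependent events, de novo DSA and first acute rejection) receive
  additional even weights by greedy maximization of the ten-year
  time-dependent ROC AUC;
* a patient's score at time t is the baseline branch score plus the event
  weight of every event with onset known by t; it can only grow over
  follow-up, and maps onto four risk groups:
  0 -> low, 2-4 -> intermediate, 6-8 -> high, 10-12 -> very high.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_io import PatientRecord, landmark_record
from .conditional_tree import ConditionalTreeModel, assign_node
from .survival_forest import SurvivalDataset, VimpTable
from .survival_metrics import time_dependent_auc

__all__ = [
    "WeightTable",
    "ScoreSystem",
    "derive_weights",
    "attach_tree",
    "augment_with_events",
    "compute_score",
    "stratify",
    "RISK_GROUPS",
]

RISK_GROUPS = {0: "low", 2: "intermediate", 4: "intermediate",
               6: "high", 8: "high", 10: "very high", 12: "very high"}

EVENT_FACTORS = ("dndsa_any", "rejection_any")


@dataclass
class WeightTable:
    """Even-integer weights of the baseline factors and the event factors."""

    baseline: dict  # factor -> even integer weight (0 = not yet weighted)
    dndsa_weight: int = 4
    rejection_weight: int = 2

    def __post_init__(self) -> None:
        for f, w in self.baseline.items():
            if w < 0 or w % 2:
                raise ValueError(f"weight of {f} must be a non-negative even integer")
        for name in ("dndsa_weight", "rejection_weight"):
            w = getattr(self, name)
            if w < 0 or w % 2:
                raise ValueError(f"{name} must be a non-negative even integer")

    def event_weight(self, factor: str) -> int:
        if factor == "dndsa_any":
            return self.dndsa_weight
        if factor == "rejection_any":
            return self.rejection_weight
        raise KeyError(factor)


@dataclass
class ScoreSystem:
    """The fitted scoring system: tree + weights + per-leaf branch scores."""

    tree: ConditionalTreeModel
    weights: WeightTable
    node_scores: dict  # terminal node id -> baseline branch score
    horizon: float = 10.0

    def baseline_score(self, record: PatientRecord) -> int:
        return self.node_scores[assign_node(record, self.tree)]


def derive_weights(vimp: VimpTable, tree: ConditionalTreeModel) -> WeightTable:
    """VIMP-ratio weights with equal weights per tree depth.

    raw(v) = VIMP(v) / VIMP(last retained variable); variables splitting at
    the same (smallest) depth share the rounded mean of their raw ratios;
    every weight is clipped to >= 1 and doubled onto the even scale.
    Factors ranked by the forest but not splitting the tree get a
    provisional weight 0 (pending event augmentation).
    """
    depth = tree.variable_depth()
    missing = [v for v in depth if v not in vimp.variables]
    if missing:
        raise ValueError(f"tree splits on variables without VIMP: {missing}")
    ranked = vimp.variables
    if not depth:
        # single-node tree: no retained baseline predictors, every branch
        # scores 0 and the event weights carry the whole system
        return WeightTable(baseline={v: 0 for v in ranked})
    # reference: the last (weakest-VIMP) variable retained as a predictor in
    # the tree — every branch weight is a ratio to it, so the weakest
    # retained factor always weighs 1 (2 after doubling)
    tree_ranked = [v for v in ranked if v in depth and vimp[v] > 0]
    if not tree_ranked:
        raise ValueError("no tree variable has positive VIMP: cannot derive weights")
    v_last = vimp[tree_ranked[-1]]
    raw = {v: vimp[v] / v_last for v in ranked}

    tiers: dict = {}
    for v, d in depth.items():
        tiers.setdefault(d, []).append(v)
    weights = {v: 0 for v in ranked}
    for d, members in tiers.items():
        tier_raw = float(np.mean([raw[v] for v in members]))
        w = max(1, int(round(tier_raw))) * 2
        for v in members:
            weights[v] = w
    return WeightTable(baseline=weights)


def _adverse_side(tree: ConditionalTreeModel, node, horizon: float) -> bool:
    """True if the LEFT daughter is the adverse one (lower KM at horizon)."""

    def node_surv(nid: int) -> float:
        nd = tree.nodes[nid]
        if nd.is_terminal:
            return float(nd.km.predict(horizon))
        # weighted average of the terminal members below
        stack, tot, w = [nid], 0.0, 0
        while stack:
            cur = tree.nodes[stack.pop()]
            if cur.is_terminal:
                tot += cur.n * float(cur.km.predict(horizon))
                w += cur.n
            else:
                stack.extend([cur.left, cur.right])
        return tot / w

    return node_surv(node.left) < node_surv(node.right)


def attach_tree(vimp: VimpTable, tree: ConditionalTreeModel,
                weights: Optional[WeightTable] = None,
                horizon: float = 10.0) -> ScoreSystem:
    """Compose per-terminal-node baseline scores from branch weights.

    Walking root to leaf, a risk factor contributes its weight when the
    branch takes the adverse daughter of a split on it; a factor splitting
    several times along one branch is counted once.
    """
    weights = weights if weights is not None else derive_weights(vimp, tree)
    node_scores = {}
    for leaf in tree.terminal_nodes:
        adverse_vars = set()
        for node, went_left in tree.path_to(leaf.node_id):
            left_is_adverse = _adverse_side(tree, node, horizon)
            if went_left == left_is_adverse:
                adverse_vars.add(node.variable)
        node_scores[leaf.node_id] = int(
            sum(weights.baseline.get(v, 0) for v in adverse_vars)
        )
    return ScoreSystem(tree=tree, weights=weights, node_scores=node_scores,
                       horizon=horizon)


def _scores_on_dataset(system: ScoreSystem, data: SurvivalDataset,
                       weights: WeightTable) -> np.ndarray:
    """Scores of every dataset row at the analysis horizon (events included
    whenever the indicator columns say they occurred)."""
    cov = data.covariates
    rows = cov.to_dict("records")
    base = np.array(
        [system.node_scores[assign_node(r, system.tree)] for r in rows],
        dtype=float,
    )
    in_tree = system.tree.variable_depth()
    for factor in EVENT_FACTORS:
        # a factor splitting the tree is already priced into the branch score
        if factor in cov.columns and factor not in in_tree:
            base += weights.event_weight(factor) * cov[factor].to_numpy(float)
    return base


def augment_with_events(system: ScoreSystem, data: SurvivalDataset,
                        candidates: Sequence[str] = EVENT_FACTORS,
                        vimp: Optional[VimpTable] = None,
                        horizon: float = 10.0,
                        auc_tolerance: float = 0.001) -> ScoreSystem:
    """Greedy event-weight search by ten-year AUC maximization.

    For each candidate factor not already weighted (scan order: VIMP rank
    when a table is given, else the given order) try the even weights
    {2, 4, 6}; keep the weight maximizing AUC(horizon) if it beats the
    current AUC by more than ``auc_tolerance``.  Idempotent: re-running on
    the augmented system changes nothing.
    """
    in_tree = system.tree.variable_depth()
    candidates = [c for c in candidates
                  if c in data.covariates.columns and c not in in_tree]
    if vimp is not None:
        order = {v: i for i, v in enumerate(vimp.variables)}
        candidates = sorted(candidates, key=lambda c: order.get(c, len(order)))

    def field_of(factor):
        return "dndsa_weight" if factor == "dndsa_any" else "rejection_weight"

    # candidates start unweighted: each must buy its weight by improving AUC
    weights = replace(system.weights, **{field_of(c): 0 for c in candidates})
    best_auc = time_dependent_auc(
        _scores_on_dataset(system, data, weights), data.time, data.event,
        horizon,
    ).auc
    for factor in candidates:
        best_w, improved = 0, False
        for w in (2, 4, 6):
            trial = replace(weights, **{field_of(factor): w})
            auc = time_dependent_auc(
                _scores_on_dataset(system, data, trial),
                data.time, data.event, horizon,
            ).auc
            if auc > best_auc + auc_tolerance:
                best_auc, best_w, improved = auc, w, True
        if improved:
            weights = replace(weights, **{field_of(factor): best_w})
    return ScoreSystem(tree=system.tree, weights=weights,
                       node_scores=system.node_scores, horizon=system.horizon)


def compute_score(record: PatientRecord, system: ScoreSystem,
                  at_time: float) -> int:
    """AdGFS value of a patient as known at ``at_time`` (years >= 1).

    Baseline branch score via tree routing of the landmarked record, plus
    the event weight of every event with onset <= at_time.
    """
    if at_time < 1:
        raise ValueError("score undefined before one year post-transplant")
    rec = landmark_record(record, at_time)
    score = system.baseline_score(rec)
    in_tree = system.tree.variable_depth()
    if rec.dndsa_time is not None and "dndsa_any" not in in_tree:
        score += system.weights.dndsa_weight
    if rec.rejection_time is not None and "rejection_any" not in in_tree:
        score += system.weights.rejection_weight
    return int(score)


def stratify(score: int, clip: bool = False) -> str:
    """Risk group of an AdGFS value: 0 low, 2-4 intermediate, 6-8 high,
    10-12 very high.  ``clip`` maps scores beyond 12 onto the top group
    (useful for experimental weightings); otherwise they raise."""
    s = int(score)
    if s != score or s % 2:
        raise ValueError(f"AdGFS values are even integers, got {score}")
    if clip:
        s = min(s, 12)
    if s not in RISK_GROUPS:
        raise ValueError(f"AdGFS value out of range 0-12: {score}")
    return RISK_GROUPS[s]
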