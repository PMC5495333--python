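"""Conditional inference survival tree with Kaplan-Meier leaves.

Recursive partitioning for a censored response in the conditional inference
framework: at each node the association between every candidate variable and
the log-rank scores of (time, event) is tested with a standardized linear
statistic (quadratic form for categorical variables), p-values are
Bonferroni-adjusted across candidates, and splitting stops as soon as no
adjusted p-value falls below ``alpha``.  The winning variable is split at
the cutpoint maximizing the two-sample standardized statistic over all
observed midpoints (the tree is fit once on the whole dataset — no random
cut subsampling here).  Terminal nodes carry Kaplan-Meier estimates.

Log-rank scores: s_i = delta_i - H(t_i), with H the Nelson-Aalen cumulative
hazard of the node sample; their permutation moments give the exact
conditional mean and variance of the linear statistic (asymptotic normal /
chi-square reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import PatientRecord
from .survival_forest import SurvivalDataset, _nelson_aalen
from .survival_metrics import km_estimate, KMCurve

__all__ = [
    "ConditionalTreeModel",
    "TreeNode",
    "fit_conditional_tree",
    "assign_node",
]


@dataclass
class TreeNode:
    node_id: int
    depth: int
    n: int
    # internal
    variable: Optional[str] = None
    cutpoint: Optional[float] = None  # continuous: go left if x <= cutpoint
    level_set: Optional[frozenset] = None  # categorical: left if value in set
    p_adjusted: Optional[float] = None
    left: Optional[int] = None
    right: Optional[int] = None
    # terminal
    member_ids: Optional[np.ndarray] = None  # row indices of the training set
    km: Optional[KMCurve] = None

    @property
    def is_terminal(self) -> bool:
        return self.variable is None


@dataclass
class ConditionalTreeModel:
    nodes: list
    variables: list
    alpha: float

    @property
    def terminal_nodes(self) -> list:
        return [nd for nd in self.nodes if nd.is_terminal]

    def variable_depth(self) -> dict:
        """Smallest depth at which each variable splits (root = depth 1)."""
        out: dict = {}
        for nd in self.nodes:
            if not nd.is_terminal:
                d = nd.depth + 1
                out[nd.variable] = min(out.get(nd.variable, d), d)
        return out

    def path_to(self, node_id: int) -> list:
        """(internal node, went_left) pairs from the root to a terminal."""
        parent = {}
        for nd in self.nodes:
            if not nd.is_terminal:
                parent[nd.left] = (nd.node_id, True)
                parent[nd.right] = (nd.node_id, False)
        path = []
        cur = node_id
        while cur in parent:
            pid, went_left = parent[cur]
            path.append((self.nodes[pid], went_left))
            cur = pid
        return list(reversed(path))


def _logrank_scores(time, event):
    """Log-rank (Savage) scores delta_i - H(t_i) for the node sample."""
    na_t, na_h = _nelson_aalen(time, event)
    idx = np.searchsorted(na_t, time, side="right") - 1
    H = np.where(idx >= 0, na_h[np.clip(idx, 0, len(na_h) - 1)], 0.0)
    return event.astype(float) - H


def _linear_test_continuous(x, s):
    """Standardized linear statistic sum(x_i s_i): z and two-sided p."""
    n = len(x)
    T = float(x @ s)
    mu = x.sum() * s.mean()
    var_s = float(((s - s.mean()) ** 2).sum()) / (n - 1)
    sigma2 = var_s * (float((x**2).sum()) - x.sum() ** 2 / n)
    if sigma2 <= 0:
        return 0.0, 1.0
    z = (T - mu) / np.sqrt(sigma2)
    return z, 2.0 * stats.norm.sf(abs(z))


def _linear_test_categorical(codes, s):
    """Quadratic-form statistic over level indicators: chi2 and p."""
    n = len(codes)
    levels = np.unique(codes)
    if len(levels) < 2:
        return 0.0, 1.0
    G = (codes[:, None] == levels[None, :]).astype(float)
    T = G.T @ s
    counts = G.sum(axis=0)
    mu = counts * s.mean()
    var_s = float(((s - s.mean()) ** 2).sum()) / (n - 1)
    # Strasser-Weber conditional covariance of the level sums
    Sigma = var_s * (np.diag(counts) - np.outer(counts, counts) / n)
    diff = T - mu
    Sigma_inv = np.linalg.pinv(Sigma)
    chi2 = float(diff @ Sigma_inv @ diff)
    df = len(levels) - 1
    return chi2, float(stats.chi2.sf(chi2, df))


def _two_sample_stat(s, mask):
    """Standardized two-sample statistic of log-rank scores for a split."""
    n = len(s)
    k = int(mask.sum())
    if k == 0 or k == n:
        return 0.0
    T = float(s[mask].sum())
    mu = k * s.mean()
    var_s = float(((s - s.mean()) ** 2).sum()) / (n - 1)
    sigma2 = var_s * k * (n - k) / n
    if sigma2 <= 0:
        return 0.0
    return (T - mu) / np.sqrt(sigma2)


def _best_cutpoint(x, s, is_cat, min_size):
    """Maximize |two-sample statistic| over admissible cutpoints."""
    best = (0.0, None)
    if is_cat:
        levels = np.unique(x)
        # all non-trivial binary partitions of the levels
        for code in range(1, 2 ** (len(levels) - 1)):
            left = frozenset(
                lv for b, lv in enumerate(levels) if (code >> b) & 1
            )
            mask = np.isin(x, list(left))
            if mask.sum() < min_size or (~mask).sum() < min_size:
                continue
            stat = abs(_two_sample_stat(s, mask))
            if stat > best[0]:
                best = (stat, left)
    else:
        for c in np.unique(x)[:-1]:
            mask = x <= c
            if mask.sum() < min_size or (~mask).sum() < min_size:
                continue
            stat = abs(_two_sample_stat(s, mask))
            if stat > best[0]:
                best = (stat, float(c))
    return best


def fit_conditional_tree(
    data: SurvivalDataset,
    variables: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    min_node_size: int = 20,
) -> ConditionalTreeModel:
    """Fit the conditional inference survival tree.

    Parameters
    ----------
    data
        Training data; ``variables`` restricts the candidate covariates
        (typically the forest-selected set).
    alpha
        Significance level of the Bonferroni-adjusted association test that
        gates every split (two-sided).
    min_node_size
        Minimum patients per daughter; prevents degenerate leaves.
    """
    variables = list(variables) if variables is not None else data.variables
    missing = [v for v in variables if v not in data.variables]
    if missing:
        raise KeyError(f"variables not in dataset: {missing}")
    if data.event.sum() == 0:
        raise ValueError("no events: cannot fit a survival tree")

    cov = data.covariates
    is_cat = {
        v: isinstance(cov[v].dtype, pd.CategoricalDtype) or cov[v].dtype == object
        for v in variables
    }
    xcols = {}
    cat_levels = {}
    for v in variables:
        if is_cat[v]:
            c = pd.Categorical(cov[v])
            xcols[v] = c.codes.astype(float)
            cat_levels[v] = list(c.categories)
        else:
            xcols[v] = cov[v].to_numpy(float)

    t_all, d_all = data.time, data.event
    nodes: list[TreeNode] = []

    def build(idx: np.ndarray, depth: int) -> int:
        node_id = len(nodes)
        node = TreeNode(node_id=node_id, depth=depth, n=len(idx))
        nodes.append(node)

        splittable = (
            len(idx) >= 2 * min_node_size and d_all[idx].sum() >= 2
        )
        winner, winner_p = None, 1.0
        if splittable:
            s = _logrank_scores(t_all[idx], d_all[idx])
            pvals = {}
            for v in variables:
                x = xcols[v][idx]
                if len(np.unique(x)) < 2:
                    continue
                if is_cat[v]:
                    _, p = _linear_test_categorical(x, s)
                else:
                    _, p = _linear_test_continuous(x, s)
                pvals[v] = p
            if pvals:
                m = len(pvals)
                v_min = min(pvals, key=lambda v: pvals[v])
                p_adj = min(1.0, pvals[v_min] * m)  # Bonferroni
                if p_adj <= alpha:
                    winner, winner_p = v_min, p_adj

        if winner is not None:
            x = xcols[winner][idx]
            s = _logrank_scores(t_all[idx], d_all[idx])
            stat, cut = _best_cutpoint(x, s, is_cat[winner], min_node_size)
            if cut is not None:
                node.variable = winner
                node.p_adjusted = winner_p
                if is_cat[winner]:
                    node.level_set = frozenset(
                        cat_levels[winner][int(c)] for c in cut
                    )
                    mask = np.isin(x, list(cut))
                else:
                    node.cutpoint = cut
                    mask = x <= cut
                node.left = build(idx[mask], depth + 1)
                node.right = build(idx[~mask], depth + 1)
                return node_id

        # terminal
        node.member_ids = idx
        node.km = km_estimate(t_all[idx], d_all[idx])
        return node_id

    build(np.arange(data.n), depth=0)
    return ConditionalTreeModel(nodes=nodes, variables=variables, alpha=alpha)


def assign_node(record_or_row, model: ConditionalTreeModel) -> int:
    """Route a patient to a terminal node; returns the node id.

    Accepts a :class:`PatientRecord` (baseline fields + ``scr_cluster``) or
    a mapping of variable name to value.  Boundary values go to the "<="
    daughter.  A missing split variable raises (no surrogate splits).
    """
    if isinstance(record_or_row, PatientRecord):
        rec = record_or_row
        values = {
            "donor_age": rec.donor_age,
            "scr_m12": rec.scr_m12,
            "prot_m12": rec.prot_m12,
            "ndsa_pre": int(rec.ndsa_pre),
            "scr_cluster": rec.scr_cluster,
            "dndsa_any": int(rec.dndsa_time is not None),
            "rejection_any": int(rec.rejection_time is not None),
            **rec.extras,
        }
    else:
        values = dict(record_or_row)

    node = model.nodes[0]
    while not node.is_terminal:
        v = node.variable
        if v not in values or values[v] is None or (
            isinstance(values[v], float) and np.isnan(values[v])
        ):
            raise ValueError(f"cannot route patient: missing split variable {v!r}")
        if node.level_set is not None:
            go_left = values[v] in node.level_set
        else:
            go_left = float(values[v]) <= node.cutpoint
        node = model.nodes[node.left if go_left else node.right]
    return node.node_id
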