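"""Random survival forest with log-rank splitting, OOB error and VIMP.

A from-scratch ensemble of survival trees for right-censored data:

* each tree is grown on a bootstrap sample of size n drawn with replacement
  (so ~63.2% unique patients in-bag, ~37% out-of-bag);
* at every node, ``mtry`` candidate variables are drawn and, for each,
  ``nsplit`` random cutpoints (or random level subsets for categorical
  variables); the (variable, cutpoint) pair maximizing the absolute
  standardized two-sample log-rank statistic between the daughters wins;
* a candidate split is admissible only if both daughters retain at least
  ``min_terminal_events`` events; terminal nodes store the Nelson-Aalen
  cumulative hazard of their in-bag members (Breslow tie handling);
* the ensemble "mortality" of a patient is the sum, over the unique event
  times of the training data, of the OOB-averaged cumulative hazard — a
  rank statistic of predicted risk;
* prediction error is 1 minus Harrell's concordance on OOB mortality, and
  variable importance (VIMP) is the increase in that error after permuting
  a variable's OOB values tree by tree.

Backward elimination then iteratively drops the weakest positive-VIMP
variable and keeps the set with the smallest OOB error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "ForestConfig",
    "ForestModel",
    "VimpTable",
    "grow_forest",
    "harrell_c",
    "oob_error",
    "vimp",
    "backward_select",
    "partial_dependence",
    "logrank_statistic",
    "dataset_from_cohort",
]


# -- data ---------------------------------------------------------------------


@dataclass
class SurvivalDataset:
    """Covariates + right-censored outcome, the forest's training currency."""

    covariates: pd.DataFrame
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event).astype(bool)
        if len(self.covariates) != len(self.time) or len(self.time) != len(self.event):
            raise ValueError("covariates, time and event must align")
        if np.any(~np.isfinite(self.time)):
            raise ValueError("missing or non-finite survival times")
        if len(set(self.covariates.columns)) != len(self.covariates.columns):
            raise ValueError("covariate names must be unique")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def variables(self) -> list[str]:
        return list(self.covariates.columns)

    def subset_vars(self, variables: Sequence[str]) -> "SurvivalDataset":
        return SurvivalDataset(self.covariates[list(variables)], self.time, self.event)


def dataset_from_cohort(cohort, variables: Optional[Sequence[str]] = None,
                        extra: Sequence[str] = ()) -> SurvivalDataset:
    """Build the forest dataset from a cohort (clusters must be assigned).

    Default candidate variables: the five baseline factors plus the two
    event indicators (any dnDSA / any first rejection during follow-up);
    ``extra`` names additional columns of the patients table (e.g.
    cold-ischemia time) to include as candidates.
    """
    pat = cohort.patients
    cols = {}
    default = ["donor_age", "scr_m12", "prot_m12", "ndsa_pre", "scr_cluster",
               "dndsa_any", "rejection_any"]
    for v in (variables if variables is not None else default + list(extra)):
        if v == "dndsa_any":
            cols[v] = pd.to_numeric(pat["dndsa_time"], errors="coerce").notna().astype(int)
        elif v == "rejection_any":
            cols[v] = pd.to_numeric(pat["rejection_time"], errors="coerce").notna().astype(int)
        elif v == "scr_cluster":
            if "scr_cluster" not in pat.columns or pat["scr_cluster"].isna().any():
                raise ValueError("scr_cluster not assigned; run the clustering first")
            cols[v] = pat["scr_cluster"].astype("category")
        else:
            cols[v] = pat[v]
    cov = pd.DataFrame(cols)
    return SurvivalDataset(cov, pat["followup_time"].to_numpy(float),
                           pat["graft_failure"].to_numpy(int))


@dataclass
class ForestConfig:
    n_trees: int = 1000
    nsplit: int = 3
    mtry: Optional[int] = None  # default ceil(sqrt(p))
    min_terminal_events: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.nsplit < 1:
            raise ValueError("n_trees and nsplit must be >= 1")


@dataclass
class _Node:
    # internal: var >= 0; terminal: var == -1
    var: int = -1
    cut: float = np.nan  # continuous threshold (go left if x <= cut)
    levels: Optional[frozenset] = None  # categorical left-set of codes
    left: int = -1
    right: int = -1
    # terminal payload
    chf_times: Optional[np.ndarray] = None
    chf_values: Optional[np.ndarray] = None
    mortality: float = 0.0  # sum of CHF over the global event-time grid


@dataclass
class _Tree:
    nodes: list
    inbag_counts: np.ndarray  # multiset of bootstrap draws per patient


@dataclass
class ForestModel:
    trees: list
    config: ForestConfig
    var_names: list
    is_categorical: np.ndarray
    event_grid: np.ndarray  # unique event times of the training data
    oob_matrix: np.ndarray  # (n_trees, n) bool, True where patient is OOB
    train_shape: tuple

    def mean_oob_fraction(self) -> float:
        return float(self.oob_matrix.mean())


@dataclass
class VimpTable:
    """Per-variable permutation importance, sorted descending."""

    table: pd.DataFrame  # columns: variable, vimp, rank

    def __getitem__(self, variable: str) -> float:
        row = self.table.loc[self.table["variable"] == variable, "vimp"]
        if row.empty:
            raise KeyError(variable)
        return float(row.iloc[0])

    @property
    def variables(self) -> list:
        return self.table["variable"].tolist()

    def positive(self) -> list:
        return self.table.loc[self.table["vimp"] > 0, "variable"].tolist()


# -- log-rank splitting -------------------------------------------------------


def logrank_statistic(time, event, group) -> float:
    """Standardized two-sample log-rank statistic (O-E)/sqrt(V) for `group`
    (boolean: membership of daughter 1), with Breslow handling of ties."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group, bool)
    order = np.argsort(time, kind="stable")
    t, d, g = time[order], event[order], group[order]
    n = len(t)
    # unique event times
    uniq, first = np.unique(t, return_index=True)
    # at-risk counts just before each unique time
    idx = np.searchsorted(t, uniq, side="left")
    at_risk = n - idx
    g_csum = np.concatenate([[0], np.cumsum(g)])
    at_risk1 = g.sum() - g_csum[idx]
    # deaths at each unique time
    dsum = np.concatenate([[0], np.cumsum(d)])
    d1sum = np.concatenate([[0], np.cumsum(d & g)])
    idx_end = np.searchsorted(t, uniq, side="right")
    deaths = dsum[idx_end] - dsum[idx]
    deaths1 = d1sum[idx_end] - d1sum[idx]
    mask = deaths > 0
    Y, Y1, D, D1 = at_risk[mask], at_risk1[mask], deaths[mask], deaths1[mask]
    if len(Y) == 0:
        return 0.0
    frac = Y1 / Y
    O = D1.sum()
    E = (D * frac).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        V = np.where(Y > 1, D * frac * (1 - frac) * (Y - D) / (Y - 1), 0.0).sum()
    if V <= 0:
        return 0.0
    return float((O - E) / np.sqrt(V))


def _nelson_aalen(time, event):
    """Nelson-Aalen cumulative hazard (Breslow ties): (times, H)."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    n = len(t)
    uniq = np.unique(t[d]) if d.any() else np.array([])
    if len(uniq) == 0:
        return np.array([0.0]), np.array([0.0])
    idx = np.searchsorted(t, uniq, side="left")
    idx_end = np.searchsorted(t, uniq, side="right")
    dsum = np.concatenate([[0], np.cumsum(d)])
    deaths = dsum[idx_end] - dsum[idx]
    at_risk = n - idx
    return uniq, np.cumsum(deaths / at_risk)


def _chf_at(times, values, query):
    """Step-function evaluation of a cumulative hazard at query times."""
    idx = np.searchsorted(times, query, side="right") - 1
    out = np.where(idx >= 0, values[np.clip(idx, 0, len(values) - 1)], 0.0)
    return out


# -- growing ------------------------------------------------------------------


def _encode(data: SurvivalDataset):
    """Covariates to a float matrix + categorical flags + level counts."""
    X = np.empty((data.n, len(data.variables)))
    is_cat = np.zeros(len(data.variables), dtype=bool)
    for j, name in enumerate(data.variables):
        col = data.covariates[name]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            codes = pd.Categorical(col).codes.astype(float)
            X[:, j] = codes
            is_cat[j] = True
        elif col.dtype == bool:
            X[:, j] = col.astype(float)
        else:
            X[:, j] = col.astype(float)
    return X, is_cat


def _best_split(X, t, d, idx, candidates, is_cat, nsplit, min_events, rng):
    best = (0.0, None)  # (|stat|, (j, cut/levels, left_idx, right_idx))
    tt, dd = t[idx], d[idx]
    for j in candidates:
        x = X[idx, j]
        obs = np.unique(x)
        if len(obs) < 2:
            continue
        if is_cat[j]:
            trials = []
            for _ in range(nsplit):
                size = rng.integers(1, len(obs))
                left = frozenset(rng.choice(obs, size=size, replace=False).tolist())
                trials.append(left)
            for left in set(trials):
                g = np.isin(x, list(left))
                stat = _admissible_stat(tt, dd, g, min_events)
                if stat is not None and abs(stat) > best[0]:
                    best = (abs(stat), (j, left, idx[g], idx[~g]))
        else:
            cuts = rng.choice(obs[:-1], size=min(nsplit, len(obs) - 1),
                              replace=False)
            for c in np.unique(cuts):
                g = x <= c
                stat = _admissible_stat(tt, dd, g, min_events)
                if stat is not None and abs(stat) > best[0]:
                    best = (abs(stat), (j, float(c), idx[g], idx[~g]))
    return best[1]


def _admissible_stat(tt, dd, g, min_size):
    # daughters must not be degenerate in size; an all-censored daughter is
    # allowed (it simply carries a flat cumulative hazard)
    if g.sum() < min_size or (~g).sum() < min_size:
        return None
    return logrank_statistic(tt, dd, g)


def _grow_tree(X, t, d, is_cat, mtry, nsplit, min_events, event_grid, rng):
    n = len(t)
    draws = rng.integers(0, n, size=n)
    inbag_counts = np.bincount(draws, minlength=n)
    nodes: list[_Node] = []

    def make_terminal(idx):
        times, H = _nelson_aalen(t[idx], d[idx])
        mort = float(_chf_at(times, H, event_grid).sum())
        nodes.append(_Node(var=-1, chf_times=times, chf_values=H, mortality=mort))
        return len(nodes) - 1

    p = X.shape[1]

    def build(idx):
        # stop once the node runs out of events to support a log-rank split
        if d[idx].sum() < min_events or len(idx) < 2 * min_events:
            return make_terminal(idx)
        candidates = rng.choice(p, size=min(mtry, p), replace=False)
        split = _best_split(X, t, d, idx, candidates, is_cat, nsplit,
                            min_events, rng)
        if split is None:
            return make_terminal(idx)
        j, cut, left_idx, right_idx = split
        node_pos = len(nodes)
        if isinstance(cut, frozenset):
            nodes.append(_Node(var=j, levels=cut))
        else:
            nodes.append(_Node(var=j, cut=cut))
        nodes[node_pos].left = build(left_idx)
        nodes[node_pos].right = build(right_idx)
        return node_pos

    root_idx = np.repeat(np.arange(n), inbag_counts)
    if d[root_idx].sum() == 0:
        raise ValueError("all-censored bootstrap sample: cannot grow tree")
    build(root_idx)
    return _Tree(nodes=nodes, inbag_counts=inbag_counts)


def grow_forest(data: SurvivalDataset, config: ForestConfig) -> ForestModel:
    """Grow the bootstrap ensemble of log-rank survival trees."""
    if data.event.sum() < 2:
        raise ValueError("need at least 2 events to grow a forest")
    X, is_cat = _encode(data)
    t, d = data.time, data.event
    p = X.shape[1]
    mtry = config.mtry or int(np.ceil(np.sqrt(p)))
    event_grid = np.unique(t[d])
    root_rng = np.random.default_rng(config.seed)
    seeds = root_rng.integers(0, 2**31 - 1, size=config.n_trees)

    trees, oob = [], np.zeros((config.n_trees, data.n), dtype=bool)
    for b in range(config.n_trees):
        rng = np.random.default_rng(seeds[b])
        tree = _grow_tree(X, t, d, is_cat, mtry, config.nsplit,
                          config.min_terminal_events, event_grid, rng)
        trees.append(tree)
        oob[b] = tree.inbag_counts == 0
    return ForestModel(
        trees=trees, config=config, var_names=data.variables,
        is_categorical=is_cat, event_grid=event_grid, oob_matrix=oob,
        train_shape=(data.n, p),
    )


# -- prediction ---------------------------------------------------------------


def _route(tree: _Tree, X: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Terminal-node index for each row of X (rows: indices into X)."""
    out = np.empty(len(rows), dtype=int)
    stack = [(0, np.arange(len(rows)))]
    while stack:
        node_id, sel = stack.pop()
        node = tree.nodes[node_id]
        if node.var < 0:
            out[sel] = node_id
            continue
        x = X[rows[sel], node.var]
        if node.levels is not None:
            go_left = np.isin(x, list(node.levels))
        else:
            go_left = x <= node.cut
        stack.append((node.left, sel[go_left]))
        stack.append((node.right, sel[~go_left]))
    return out


def _leaf_mortality(tree: _Tree, X, rows) -> np.ndarray:
    leaves = _route(tree, X, rows)
    return np.array([tree.nodes[l].mortality for l in leaves])


def ensemble_mortality(model: ForestModel, data: SurvivalDataset,
                       oob_only: bool = True) -> np.ndarray:
    """Per-patient predicted mortality (OOB-averaged by default).

    Patients that are never OOB get NaN (with ``oob_only``); callers exclude
    them with a warning.
    """
    X, _ = _encode(data)
    n = data.n
    total = np.zeros(n)
    count = np.zeros(n)
    all_rows = np.arange(n)
    for b, tree in enumerate(model.trees):
        rows = all_rows[model.oob_matrix[b]] if oob_only else all_rows
        if len(rows) == 0:
            continue
        total[rows] += _leaf_mortality(tree, X, rows)
        count[rows] += 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def ensemble_survival(model: ForestModel, data: SurvivalDataset,
                      horizon: float) -> np.ndarray:
    """Ensemble survival probability S(horizon) = exp(-mean CHF(horizon)),
    averaged over all trees (in-bag prediction)."""
    X, _ = _encode(data)
    rows = np.arange(data.n)
    chf = np.zeros(data.n)
    for tree in model.trees:
        leaves = _route(tree, X, rows)
        chf += np.array([
            _chf_at(tree.nodes[l].chf_times, tree.nodes[l].chf_values,
                    np.array([horizon]))[0]
            for l in leaves
        ])
    return np.exp(-chf / len(model.trees))


# -- error and importance -----------------------------------------------------


def harrell_c(predicted_mortality, time, event) -> float:
    """Harrell's concordance: over comparable pairs (the shorter time is an
    event), the fraction where higher predicted mortality goes with shorter
    survival; prediction ties count 1/2."""
    m = np.asarray(predicted_mortality, float)
    t = np.asarray(time, float)
    d = np.asarray(event, bool)
    if not (len(m) == len(t) == len(d)):
        raise ValueError("inputs must have equal length")
    # pair (i, j) comparable if t_i < t_j and d_i, or t_i == t_j and d_i != d_j
    conc = ties = npairs = 0.0
    order = np.argsort(t, kind="stable")
    t, d, m = t[order], d[order], m[order]
    n = len(t)
    for i in range(n):
        if not d[i]:
            continue
        later = (t > t[i]) | ((t == t[i]) & ~d)
        later[i] = False
        k = later.sum()
        if k == 0:
            continue
        npairs += k
        conc += np.sum(m[i] > m[later])
        ties += np.sum(m[i] == m[later])
    if npairs == 0:
        raise ValueError("no comparable pairs: concordance undefined")
    return float((conc + 0.5 * ties) / npairs)


def oob_error(model: ForestModel, data: SurvivalDataset) -> float:
    """1 - Harrell's c on the OOB ensemble mortality."""
    mort = ensemble_mortality(model, data, oob_only=True)
    ok = ~np.isnan(mort)
    if not ok.all():
        import warnings

        warnings.warn(f"{(~ok).sum()} patients never OOB; excluded from error")
    return 1.0 - harrell_c(mort[ok], data.time[ok], data.event[ok])


def vimp(model: ForestModel, data: SurvivalDataset, seed: int = 0) -> VimpTable:
    """Permutation VIMP: per-tree OOB permutation of each variable, then
    the increase in OOB ensemble prediction error."""
    X, _ = _encode(data)
    n = data.n
    all_rows = np.arange(n)
    rng = np.random.default_rng(seed)

    base_total = np.zeros(n)
    count = np.zeros(n)
    perm_total = {v: np.zeros(n) for v in model.var_names}
    # consume permutations in a fixed (tree-major) order for determinism
    for b, tree in enumerate(model.trees):
        rows = all_rows[model.oob_matrix[b]]
        if len(rows) == 0:
            continue
        base_total[rows] += _leaf_mortality(tree, X, rows)
        count[rows] += 1
        for j, v in enumerate(model.var_names):
            perm = rng.permutation(len(rows))
            Xp = X[rows].copy()
            Xp[:, j] = Xp[perm, j]
            leaves = _route(tree, Xp, np.arange(len(rows)))
            perm_total[v][rows] += np.array(
                [tree.nodes[l].mortality for l in leaves]
            )
    ok = count > 0
    base_mort = base_total[ok] / count[ok]
    base_err = 1.0 - harrell_c(base_mort, data.time[ok], data.event[ok])
    rows_out = []
    for v in model.var_names:
        pm = perm_total[v][ok] / count[ok]
        err = 1.0 - harrell_c(pm, data.time[ok], data.event[ok])
        rows_out.append((v, err - base_err))
    tab = pd.DataFrame(rows_out, columns=["variable", "vimp"])
    tab = tab.sort_values("vimp", ascending=False, kind="stable").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return VimpTable(table=tab)


def backward_select(data: SurvivalDataset, config: ForestConfig,
                    seed: Optional[int] = None, parsimony_se: float = 1.0):
    """Iterative backward elimination on the positive-VIMP ranking.

    Fits a forest, drops all variables with VIMP <= 0, then removes the
    weakest positive-VIMP variable one at a time, refitting after each
    removal; returns ``(selected variables, trace)`` where the trace records
    (variable set, OOB error) per iteration.  The *minimal combination of
    variables with the smallest OOB error* is returned: error values within
    ``parsimony_se`` standard errors of the minimum count as ties, resolved
    toward the smaller set (the one-standard-error parsimony convention;
    set ``parsimony_se=0`` for strict minimization).
    """
    if len(data.variables) < 1:
        raise ValueError("no candidate variables")
    seed = config.seed if seed is None else seed
    current = list(data.variables)
    trace = []
    it = 0
    while True:
        sub = data.subset_vars(current)
        # common random numbers across refits: identical bootstrap patterns
        # make successive OOB errors directly comparable
        model = grow_forest(sub, ForestConfig(
            n_trees=config.n_trees, nsplit=config.nsplit, mtry=config.mtry,
            min_terminal_events=config.min_terminal_events, seed=seed,
        ))
        tab = vimp(model, sub, seed=seed + 1000)
        err = oob_error(model, sub)
        trace.append((list(current), err))
        if len(current) == 1:
            break
        positive = tab.positive()
        if it == 0 and not positive:
            raise ValueError("no variable has positive VIMP: nothing to select")
        if len(positive) < len(current):
            current = positive if positive else [tab.variables[0]]
        else:
            current = positive[:-1]  # drop the weakest positive variable
        if not current:
            break
        it += 1
    best_err = min(err for _, err in trace)
    # rough concordance SE (binomial on the event count) sets the tie band
    n_ev = max(int(data.event.sum()), 1)
    c_best = 1.0 - best_err
    se = np.sqrt(max(c_best * (1.0 - c_best), 1e-12) / n_ev)
    tol = parsimony_se * se + 1e-12
    selected = min((s for s, e in trace if e <= best_err + tol), key=len)
    return selected, trace


def partial_dependence(model: ForestModel, data: SurvivalDataset,
                       variable: str, grid, horizon: float = 10.0):
    """Partial-dependence survival curve: for each grid value v, set the
    variable to v for every patient and average ensemble survival at the
    horizon.  Returns a DataFrame (value, survival, se, extrapolated)."""
    if variable not in data.variables:
        raise KeyError(variable)
    j = data.variables.index(variable)
    if model.is_categorical[j]:
        raise ValueError("partial dependence is defined for continuous variables")
    observed = data.covariates[variable].to_numpy(float)
    lo, hi = np.nanmin(observed), np.nanmax(observed)
    out = []
    for v in np.asarray(grid, float):
        mod = data.covariates.copy()
        mod[variable] = v
        surv = ensemble_survival(
            model, SurvivalDataset(mod, data.time, data.event), horizon
        )
        extrap = bool(v < lo or v > hi)
        if extrap:
            import warnings

            warnings.warn(f"grid value {v} outside observed range [{lo}, {hi}]")
        out.append((v, float(surv.mean()),
                    float(surv.std(ddof=1) / np.sqrt(len(surv))), extrap))
    return pd.DataFrame(out, columns=["value", "survival", "se", "extrapolated"])
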