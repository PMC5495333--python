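"""K-means clustering of first-year creatinine trajectories.

Longitudinal k-means on the raw monthly creatinine vectors (shared units, no
standardization), with missing visits handled by a pairwise-available
Euclidean distance rescaled to the full grid.  The number of clusters is
selected by the Calinski-Harabasz criterion, and fitted models carry
per-cluster 10th-90th percentile bands so a *new* patient can be allocated
to a cluster by the fraction of their visits falling inside each band (the
graphical allocation rule), without refitting.

Clusters are relabeled after fitting by ascending month-12 mean so that "A"
is always the lowest (most favorable) curve, making labels seed-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort_io import CohortTable, LongitudinalSeries

__all__ = [
    "TrajectoryMatrix",
    "ClusterModel",
    "UndefinedCriterionError",
    "trajectory_matrix",
    "fit_kml",
    "calinski_harabasz",
    "select_k",
    "allocate",
]

CLUSTER_NAMES = "ABCDEFGHIJ"


class UndefinedCriterionError(ValueError):
    """Calinski-Harabasz undefined (zero within-cluster scatter)."""


@dataclass(frozen=True)
class TrajectoryMatrix:
    """Patients x months matrix of creatinine values; NaN marks missed visits."""

    patient_ids: np.ndarray  # (n,) str
    grid: np.ndarray  # (g,) int months
    values: np.ndarray  # (n, g) float, NaN allowed

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.patient_ids), len(self.grid)):
            raise ValueError("values shape must be (n_patients, n_months)")
        if np.any(np.all(np.isnan(self.values), axis=1)):
            raise ValueError("every patient needs at least one observed value")

    @property
    def n(self) -> int:
        return len(self.patient_ids)


@dataclass(frozen=True)
class ClusterModel:
    """Fitted trajectory clusters: mean curves, labels and percentile bands."""

    k: int
    grid: np.ndarray  # (g,)
    mean_curves: np.ndarray  # (k, g)
    labels: np.ndarray  # (n,) int in 0..k-1
    patient_ids: np.ndarray  # (n,)
    ch_value: Optional[float]  # None when k == 1
    bands: np.ndarray  # (k, 2, g): 10th and 90th percentile per month
    wss: float
    ch_by_k: Optional[dict] = None  # filled by select_k
    ambiguous_k: bool = False  # best CH < 1.1 x runner-up

    def label_names(self) -> np.ndarray:
        """Labels as letters (A = lowest month-12 mean curve)."""
        return np.array([CLUSTER_NAMES[i] for i in self.labels])

    def label_map(self) -> dict:
        """patient_id -> cluster letter."""
        return dict(zip(map(str, self.patient_ids), self.label_names()))


def trajectory_matrix(cohort: CohortTable, grid: Sequence[int] = range(13)) -> TrajectoryMatrix:
    """Align a cohort's creatinine series onto a common month grid."""
    grid = np.asarray(list(grid), dtype=int)
    ids = np.asarray(cohort.patient_ids)
    values = np.full((len(ids), len(grid)), np.nan)
    pos = {m: j for j, m in enumerate(grid)}
    by_pid = {
        pid: g for pid, g in cohort.series.groupby(cohort.series["patient_id"].astype(str))
    }
    for i, pid in enumerate(ids):
        g = by_pid.get(str(pid))
        if g is None:
            continue
        for m, v in zip(g["month"].to_numpy(int), g["scr"].to_numpy(float)):
            if m in pos:
                values[i, pos[m]] = v
    return TrajectoryMatrix(patient_ids=ids, grid=grid, values=values)


# -- distances ----------------------------------------------------------------


def _pairwise_dist2(values: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared distances patients x centers over jointly observed months,
    rescaled to the full grid length (pairwise-available Euclidean)."""
    obs = ~np.isnan(values)
    v = np.where(obs, values, 0.0)
    g = values.shape[1]
    # centers are complete by construction
    d2 = (
        (v**2).sum(axis=1)[:, None]
        - 2.0 * v @ centers.T
        + obs @ (centers.T**2)
    )
    n_obs = obs.sum(axis=1)[:, None].astype(float)
    return np.maximum(d2, 0.0) * (g / n_obs)


def _nanmean_rows(values: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    g = values.shape[1]
    centers = np.empty((k, g))
    for c in range(k):
        member = values[labels == c]
        if member.size == 0:
            raise _EmptyCluster()
        col = np.nanmean(member, axis=0)
        if np.any(np.isnan(col)):  # month unobserved in the whole cluster
            overall = np.nanmean(values, axis=0)
            col = np.where(np.isnan(col), overall, col)
        centers[c] = col
    return centers


class _EmptyCluster(Exception):
    pass


def _kmeans_once(values: np.ndarray, k: int, rng: np.random.Generator,
                 max_iter: int = 200):
    n = values.shape[0]
    # k-means++-style seeding on observed-rescaled distances
    first = rng.integers(n)
    centers = [np.where(np.isnan(values[first]), np.nanmean(values, axis=0),
                        values[first])]
    for _ in range(1, k):
        d2 = _pairwise_dist2(values, np.array(centers)).min(axis=1)
        p = d2 / d2.sum() if d2.sum() > 0 else None
        idx = rng.choice(n, p=p)
        centers.append(np.where(np.isnan(values[idx]),
                                np.nanmean(values, axis=0), values[idx]))
    centers = np.array(centers)

    labels = np.full(n, -1)
    for _ in range(max_iter):
        d2 = _pairwise_dist2(values, centers)
        new_labels = d2.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        centers = _nanmean_rows(values, labels, k)
    wss = float(_pairwise_dist2(values, centers)[np.arange(n), labels].sum())
    return labels, centers, wss


def fit_kml(traj: TrajectoryMatrix, k: int, restarts: int = 20,
            seed: int = 0) -> ClusterModel:
    """Longitudinal k-means: best of ``restarts`` seeded initializations.

    Clusters are relabeled by ascending month-12 (last grid point) mean so
    the ordering A < B < ... reflects final creatinine severity.
    """
    n_distinct = len({tuple(np.nan_to_num(r, nan=-1.0)) for r in traj.values})
    if not (1 <= k <= n_distinct):
        raise ValueError(f"k must be in 1..{n_distinct} (distinct trajectories)")
    rng = np.random.default_rng(seed)
    best = None
    failures = 0
    for _ in range(restarts):
        try:
            labels, centers, wss = _kmeans_once(traj.values, k, rng)
        except _EmptyCluster:
            failures += 1
            continue
        if best is None or wss < best[2]:
            best = (labels, centers, wss)
    if best is None:
        raise RuntimeError(f"all {restarts} restarts produced an empty cluster")
    labels, centers, wss = best

    order = np.argsort(centers[:, -1], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    centers = centers[order]

    bands = np.empty((k, 2, len(traj.grid)))
    for c in range(k):
        member = traj.values[labels == c]
        with np.errstate(all="ignore"):
            bands[c, 0] = np.nanpercentile(member, 10, axis=0)
            bands[c, 1] = np.nanpercentile(member, 90, axis=0)

    ch = calinski_harabasz(traj, labels) if k >= 2 else None
    return ClusterModel(
        k=k, grid=traj.grid, mean_curves=centers, labels=labels,
        patient_ids=traj.patient_ids, ch_value=ch, bands=bands, wss=wss,
    )


def calinski_harabasz(traj: TrajectoryMatrix, labels) -> float:
    """[trace(B)/(k-1)] / [trace(W)/(n-k)] on complete-case months."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = len(uniq), len(labels)
    if k < 2:
        raise ValueError("criterion needs at least 2 clusters")
    complete = ~np.isnan(traj.values).any(axis=0)
    if not complete.any():
        raise ValueError("no month observed for all patients")
    X = traj.values[:, complete]
    overall = X.mean(axis=0)
    trace_b = trace_w = 0.0
    for c in uniq:
        member = X[labels == c]
        mu = member.mean(axis=0)
        trace_b += len(member) * float(((mu - overall) ** 2).sum())
        trace_w += float(((member - mu) ** 2).sum())
    if trace_w <= 0.0:
        raise UndefinedCriterionError(
            "zero within-cluster scatter: criterion undefined"
        )
    return (trace_b / (k - 1)) / (trace_w / (n - k))


def select_k(traj: TrajectoryMatrix, k_min: int = 2, k_max: int = 6,
             restarts: int = 20, seed: int = 0) -> ClusterModel:
    """Fit each k in [k_min, k_max] and keep the Calinski-Harabasz maximizer.

    The per-k criterion table is retained on the returned model; when the
    best value is within 10% of the runner-up the selection is flagged as
    ambiguous (near-flat criterion, e.g. a single homogeneous bundle).
    """
    if not (2 <= k_min <= k_max):
        raise ValueError("need 2 <= k_min <= k_max")
    models, ch_table = {}, {}
    for j, k in enumerate(range(k_min, k_max + 1)):
        model = fit_kml(traj, k, restarts=restarts, seed=seed + j)
        models[k] = model
        ch_table[k] = model.ch_value
    best_k = max(ch_table, key=lambda k: ch_table[k])
    values = sorted(ch_table.values(), reverse=True)
    ambiguous = len(values) > 1 and values[0] < 1.1 * values[1]
    best = models[best_k]
    return ClusterModel(
        k=best.k, grid=best.grid, mean_curves=best.mean_curves,
        labels=best.labels, patient_ids=best.patient_ids,
        ch_value=best.ch_value, bands=best.bands, wss=best.wss,
        ch_by_k=ch_table, ambiguous_k=ambiguous,
    )


def allocate(series: LongitudinalSeries, model: ClusterModel) -> str:
    """Allocate a prospective patient to a cluster by the percentile-band rule.

    For each cluster, count the patient's visits falling inside that
    cluster's 10th-90th band at the matching month and assign the cluster
    with the highest within-band fraction; ties go to the nearest mean curve
    (Euclidean over the observed months).
    """
    pos = {int(m): j for j, m in enumerate(model.grid)}
    cols = [pos[int(m)] for m in series.months if int(m) in pos]
    vals = np.array([v for m, v in zip(series.months, series.values)
                     if int(m) in pos])
    if not cols:
        raise ValueError("series has no month overlapping the model grid")
    lo = model.bands[:, 0, cols]  # (k, v)
    hi = model.bands[:, 1, cols]
    inside = ((vals >= lo) & (vals <= hi)).mean(axis=1)
    best = np.flatnonzero(inside == inside.max())
    if len(best) > 1:
        d2 = ((model.mean_curves[best][:, cols] - vals) ** 2).sum(axis=1)
        best = best[[int(np.argmin(d2))]]
    return CLUSTER_NAMES[int(best[0])]
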