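"""Estimation and testing layer for right-censored outcomes.

Kaplan-Meier estimation (with Greenwood variance) and the log-rank test are
delegated to lifelines; on top of them this module implements the
time-dependent cumulative/dynamic ROC machinery with inverse-probability-of-
censoring weights (IPCW) from the Kaplan-Meier estimator of the censoring
distribution — AUC(t), paired AUC comparison, and time-dependent Se / Sp /
PPV / NPV at a score cutpoint — plus the Hosmer-Lemeshow-type calibration
chi-square for survival data (D'Agostino-Nam): expected events per risk
group are n_i * (1 - KM_i(t)) under a reference survival curve, and the
statistic sums (O-E)^2/E over both the failure and the non-failure margins
with groups - 2 degrees of freedom.

Standard errors use a linearized (influence-function) representation of the
weighted ratio estimators, treating the censoring weights as fixed (exact
DeLong under no censoring); a seeded bootstrap is available as fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "KMCurve",
    "TimeROCResult",
    "ConfusionAtTime",
    "CalibrationResult",
    "km_estimate",
    "logrank_test",
    "time_dependent_auc",
    "compare_auc",
    "confusion_at_time",
    "dagostino_nam",
    "expected_events",
]


# -- Kaplan-Meier -------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival curve with Greenwood variance."""

    times: np.ndarray  # unique observed times (events and censorings)
    survival: np.ndarray  # S(t) just after each time
    variance: np.ndarray  # Greenwood variance of S(t)
    at_risk: np.ndarray  # n at risk just before each time
    n: int

    def predict(self, t) -> np.ndarray | float:
        """S(t) by right-continuous step lookup; S = 1 before the first time."""
        q = np.atleast_1d(np.asarray(t, float))
        idx = np.searchsorted(self.times, q, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, len(self.times) - 1)], 1.0)
        return out if np.ndim(t) else float(out[0])

    def se(self, t) -> float:
        q = float(t)
        idx = np.searchsorted(self.times, q, side="right") - 1
        if idx < 0:
            return 0.0
        return float(np.sqrt(self.variance[min(idx, len(self.times) - 1)]))


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate (Greenwood variance)."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    if len(time) < 1:
        raise ValueError("need at least one observation")
    if np.any(time < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tab = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and \
        0 not in time else kmf.event_table
    times = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
    # drop the synthetic t=0 row unless 0 is an observed time
    if times[0] == 0.0 and not np.any(time == 0.0):
        times, surv = times[1:], surv[1:]
    # Greenwood variance via the confidence-interval-free formula
    et = kmf.event_table
    risk = et["at_risk"].to_numpy(float)
    obs = et["observed"].to_numpy(float)
    tt = et.index.to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(risk * (risk - obs) > 0, obs / (risk * (risk - obs)), 0.0)
    csum = np.cumsum(terms)
    s_all = kmf.survival_function_.iloc[:, 0].reindex(et.index).to_numpy(float)
    var_all = s_all**2 * csum
    keep = np.isin(tt, times)
    risk_keep = risk[keep]
    return KMCurve(times=times, survival=surv, variance=var_all[keep],
                   at_risk=risk_keep, n=len(time))


def logrank_test(groups: Sequence[tuple]) -> tuple[float, int, float]:
    """k-sample log-rank test on a list of (time, event) arrays.

    Returns (chi-square, df, p).  Groups with nobody at risk are dropped
    with a warning.
    """
    cleaned = []
    for g, (t, d) in enumerate(groups):
        t = np.asarray(t, float)
        d = np.asarray(d).astype(bool)
        if len(t) == 0:
            warnings.warn(f"group {g} empty: dropped from log-rank test")
            continue
        cleaned.append((t, d))
    if len(cleaned) < 2:
        raise ValueError("need at least 2 non-empty groups")
    times = np.concatenate([t for t, _ in cleaned])
    events = np.concatenate([d for _, d in cleaned])
    labels = np.concatenate(
        [np.full(len(t), i) for i, (t, _) in enumerate(cleaned)]
    )
    res = multivariate_logrank_test(times, labels, events)
    df = len(cleaned) - 1
    return float(res.test_statistic), df, float(res.p_value)


# -- IPCW machinery -----------------------------------------------------------


def _censoring_km(time, event):
    """KM of the censoring distribution G(t) (censoring as the event)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), event_observed=~np.asarray(event).astype(bool))
    times = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
    return times, surv

def _G_at(times, surv, q, before=False):
    """G(q) (or the left limit G(q-)) by step lookup."""
    q = np.atleast_1d(np.asarray(q, float))
    side = "left" if before else "right"
    idx = np.searchsorted(times, q, side=side) - 1
    return np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)


def _ipcw_case_control(marker, time, event, horizon):
    """Cases (event by t), controls (beyond t) and their IPCW weights."""
    marker = np.asarray(marker, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    gt, gs = _censoring_km(time, event)
    case = (time <= horizon) & event
    # subjects censored exactly at the horizon are known event-free at t:
    # they count as dynamic controls (matters when administrative censoring
    # ends follow-up exactly at the analysis horizon)
    control = (time > horizon) | ((time == horizon) & ~event)
    w = np.zeros(len(time))
    gw_case = _G_at(gt, gs, time[case], before=True)
    gw_ctrl = _G_at(gt, gs, np.full(int(control.sum()), horizon), before=True)
    if np.any(gw_case <= 0) or np.any(gw_ctrl <= 0):
        raise ValueError("censoring survival reaches 0 before the horizon")
    w[case] = 1.0 / gw_case
    w[control] = 1.0 / gw_ctrl
    return case, control, w


@dataclass
class TimeROCResult:
    horizon: float
    auc: float
    se: float
    n_cases: int
    n_controls: int
    weights: dict = field(default_factory=dict)


def _weighted_auc_parts(marker, case, control, w):
    """Weighted Mann-Whitney numerator terms via rank sums (O(n log n)).

    Returns (auc, per_case_placement, per_control_placement) where the
    placements are the conditional win-fractions used by the linearized SE.
    """
    mc, wc = marker[case], w[case]
    md, wd = marker[control], w[control]
    Wc, Wd = wc.sum(), wd.sum()
    order = np.argsort(md, kind="stable")
    md_s, wd_s = md[order], wd[order]
    cw = np.concatenate([[0.0], np.cumsum(wd_s)])
    lo = np.searchsorted(md_s, mc, side="left")
    hi = np.searchsorted(md_s, mc, side="right")
    below = cw[lo]
    ties = cw[hi] - cw[lo]
    place_case = (below + 0.5 * ties) / Wd  # P_w(M_ctrl < M_case | case)
    num = float((wc * (below + 0.5 * ties)).sum())
    auc = num / (Wc * Wd)
    # control placements: fraction of case weight above each control
    order_c = np.argsort(mc, kind="stable")
    mc_s, wc_s = mc[order_c], wc[order_c]
    cwc = np.concatenate([[0.0], np.cumsum(wc_s)])
    lo_c = np.searchsorted(mc_s, md, side="left")
    hi_c = np.searchsorted(mc_s, md, side="right")
    above = Wc - cwc[hi_c]
    ties_c = cwc[hi_c] - cwc[lo_c]
    place_ctrl = (above + 0.5 * ties_c) / Wc
    return auc, place_case, place_ctrl


def time_dependent_auc(marker, time, event, horizon,
                       se_method: str = "iid", n_boot: int = 200,
                       seed: int = 0) -> TimeROCResult:
    """Cumulative-cases / dynamic-controls AUC(t) with KM censoring weights.

    Cases are subjects with an event by the horizon, controls those still
    event-free beyond it; both are reweighted by the inverse of the
    Kaplan-Meier censoring survival (at the event time for cases, at the
    horizon for controls).  ``se_method``: "iid" (linearized, weights
    treated as fixed) or "bootstrap" (seeded, ``n_boot`` resamples).
    """
    marker = np.asarray(marker, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    case, control, w = _ipcw_case_control(marker, time, event, horizon)
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError("AUC undefined: no cases or no controls at horizon")
    auc, place_case, place_ctrl = _weighted_auc_parts(marker, case, control, w)

    if se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(time)
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                ca, co, wb = _ipcw_case_control(marker[idx], time[idx],
                                                event[idx], horizon)
                if ca.sum() == 0 or co.sum() == 0:
                    continue
                a, _, _ = _weighted_auc_parts(marker[idx], ca, co, wb)
                vals.append(a)
            except ValueError:
                continue
        se = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
    else:
        se = float(np.sqrt(_auc_iid_variance(case, control, w, auc,
                                             place_case, place_ctrl)))
    return TimeROCResult(horizon=float(horizon), auc=float(auc), se=se,
                         n_cases=int(case.sum()), n_controls=int(control.sum()))


def _auc_iid_contrib(case, control, w, auc, place_case, place_ctrl):
    """Per-subject linearized contributions of the weighted-ratio AUC."""
    Wc, Wd = w[case].sum(), w[control].sum()
    psi = np.zeros(len(w))
    psi[case] = w[case] * (place_case - auc) / Wc
    psi[control] = w[control] * (place_ctrl - auc) / Wd
    return psi


def _auc_iid_variance(case, control, w, auc, place_case, place_ctrl):
    psi = _auc_iid_contrib(case, control, w, auc, place_case, place_ctrl)
    return float((psi**2).sum())


def compare_auc(marker1, marker2, time, event, horizon,
                seed: int = 0) -> tuple[float, float, float]:
    """Two-sided test of AUC(t) difference for two markers on the same
    patients (joint linearized representation).

    Returns (auc1, auc2, p).
    """
    marker1 = np.asarray(marker1, float)
    marker2 = np.asarray(marker2, float)
    if np.array_equal(marker1, marker2):
        r = time_dependent_auc(marker1, time, event, horizon)
        return r.auc, r.auc, 1.0
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    case, control, w = _ipcw_case_control(marker1, time, event, horizon)
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError("AUC undefined at this horizon")
    a1, pc1, pd1 = _weighted_auc_parts(marker1, case, control, w)
    a2, pc2, pd2 = _weighted_auc_parts(marker2, case, control, w)
    psi1 = _auc_iid_contrib(case, control, w, a1, pc1, pd1)
    psi2 = _auc_iid_contrib(case, control, w, a2, pc2, pd2)
    var_diff = float(((psi1 - psi2) ** 2).sum())
    if var_diff <= 0:
        return float(a1), float(a2), 1.0
    z = (a1 - a2) / np.sqrt(var_diff)
    return float(a1), float(a2), float(2.0 * stats.norm.sf(abs(z)))


# -- time-dependent confusion table ------------------------------------------


@dataclass
class ConfusionAtTime:
    cutpoint: float
    horizon: float
    se_sensitivity: tuple  # (estimate, standard error)
    sp_specificity: tuple
    ppv: tuple  # (estimate, se) or (nan, nan) when undefined
    npv: tuple
    n_positive: int
    n_negative: int


def _ratio_se(num_mask_w, den_mask_w, est):
    """Linearized SE of a weighted proportion sum(w*1A)/sum(w*1B), A in B."""
    W = den_mask_w.sum()
    if W <= 0:
        return np.nan
    psi = (num_mask_w - est * den_mask_w) / W
    return float(np.sqrt((psi**2).sum()))


def confusion_at_time(score, time, event, cutpoint, horizon) -> ConfusionAtTime:
    """IPCW time-dependent Se, Sp, PPV, NPV at a score cutpoint.

    Test positive means score > cutpoint.  With no censoring before the
    horizon the estimates reduce to the classical 2x2 table at t.  PPV/NPV
    are NaN (flagged, not zero) when no test is positive/negative.
    """
    score = np.asarray(score, float)
    case, control, w = _ipcw_case_control(score, time, event, horizon)
    pos = score > cutpoint
    neg = ~pos
    wc = np.where(case, w, 0.0)
    wd = np.where(control, w, 0.0)

    def prop(num_w, den_w):
        W = den_w.sum()
        if W <= 0:
            return np.nan, np.nan
        est = num_w.sum() / W
        return float(est), _ratio_se(num_w, den_w, est)

    se_est = prop(wc * pos, wc)
    sp_est = prop(wd * neg, wd)
    # predictive values condition on the test result
    wall = wc + wd
    ppv = prop(wc * pos, wall * pos) if pos.any() else (np.nan, np.nan)
    npv = prop(wd * neg, wall * neg) if neg.any() else (np.nan, np.nan)
    return ConfusionAtTime(
        cutpoint=float(cutpoint), horizon=float(horizon),
        se_sensitivity=se_est, sp_specificity=sp_est, ppv=ppv, npv=npv,
        n_positive=int(pos.sum()), n_negative=int(neg.sum()),
    )


# -- calibration --------------------------------------------------------------


@dataclass
class CalibrationResult:
    groups: list  # group labels, in input order
    n: np.ndarray
    observed: np.ndarray  # observed failures O_i
    expected: np.ndarray  # expected failures E_i = n_i (1 - KM_ref_i(t))
    chi2: float
    df: int
    p_value: float
    merged: list = field(default_factory=list)  # groups merged into neighbors


def expected_events(n_i: float, km_ref: float) -> float:
    """Expected failures in a group: n_i * (1 - KM_ref(t))."""
    if not (0.0 <= km_ref <= 1.0):
        raise ValueError("survival probability must lie in [0, 1]")
    return float(n_i) * (1.0 - float(km_ref))


def dagostino_nam(
    groups,
    horizon: Optional[float] = None,
    reference_km: Optional[Sequence[float]] = None,
    labels: Optional[Sequence] = None,
) -> CalibrationResult:
    """Hosmer-Lemeshow goodness of fit adapted to survival (D'Agostino-Nam).

    Two input forms per risk group:

    * aggregated: ``(n_i, O_i, E_i)`` tuples — observed and expected
      failure counts directly (e.g. a published table);
    * raw: ``(time, event)`` arrays plus ``horizon`` and ``reference_km``
      (development-cohort survival per group); then
      O_i = n_i (1 - KM_i,val(t)) and E_i = n_i (1 - KM_i,ref(t)).

    chi2 sums (O-E)^2/E over the failure and non-failure margins of every
    group; df = groups - 2.  Groups with degenerate expectations (E=0 or
    E=n) are merged into their neighbor with a warning.
    """
    merged: list = []
    rows = []
    if reference_km is not None or horizon is not None:
        if reference_km is None or horizon is None:
            raise ValueError("raw form needs both horizon and reference_km")
        if len(groups) != len(reference_km):
            raise ValueError("one reference survival per group")
        for (t, d), km_ref in zip(groups, reference_km):
            t = np.asarray(t, float)
            d = np.asarray(d).astype(bool)
            n_i = len(t)
            km_val = km_estimate(t, d).predict(horizon)
            rows.append((n_i, n_i * (1.0 - km_val), expected_events(n_i, km_ref)))
    else:
        for g in groups:
            n_i, O_i, E_i = g
            rows.append((float(n_i), float(O_i), float(E_i)))
    if len(rows) < 3:
        raise ValueError("need at least 3 risk groups")

    # merge degenerate groups into the following (or preceding) neighbor
    i = 0
    while i < len(rows):
        n_i, O_i, E_i = rows[i]
        if E_i <= 0 or E_i >= n_i:
            j = i + 1 if i + 1 < len(rows) else i - 1
            warnings.warn(f"group {i} has degenerate expectation; merged")
            merged.append(i)
            nj, Oj, Ej = rows[j]
            rows[j] = (nj + n_i, Oj + O_i, Ej + E_i)
            rows.pop(i)
        else:
            i += 1
    if len(rows) < 3:
        raise ValueError("fewer than 3 usable groups after merging")

    n = np.array([r[0] for r in rows])
    O = np.array([r[1] for r in rows])
    E = np.array([r[2] for r in rows])
    chi2 = float((((O - E) ** 2) / E + ((n - O) - (n - E)) ** 2 / (n - E)).sum())
    df = len(rows) - 2
    p = float(stats.chi2.sf(chi2, df))
    if labels is None:
        labels = list(range(len(rows)))
    return CalibrationResult(groups=list(labels), n=n, observed=O, expected=E,
                             chi2=chi2, df=df, p_value=p, merged=merged)
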