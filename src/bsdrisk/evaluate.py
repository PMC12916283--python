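"""Time-resolved discrimination and AIC-based risk stratification.

The discrimination metric is the cumulative-case / dynamic-control AUC
at each month m: cases are subjects with an observed onset by m,
controls are subjects still at risk (event-free and uncensored) at m,
and the AUC is the probability that a randomly chosen case outscores a
randomly chosen control, ties counting one half. Subjects censored
before m without an event are excluded at that month (simple censoring
handling; an inverse-probability-of-censoring-weighted variant is
available behind a flag for sensitivity analysis). Confidence bands are
percentile intervals — across bootstrap replications when
per-replication scores exist, otherwise across a seeded bootstrap over
subjects — and a month is flagged significant when its 95% CI excludes
0.5 (two-tailed).

Risk stratification dichotomises the out-of-sample score at the
threshold minimising the AIC of a one-parameter Cox model on the
high/low indicator, searching the midpoints between consecutive
distinct scores with both groups kept at a minimum size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import KMCurve, breslow_loglik, cox_newton, km_estimate
from .validate import OutOfSampleRisk

__all__ = [
    "TimeAUCCurve",
    "RiskGroupSplit",
    "cumulative_auc_at",
    "auc_curve_with_ci",
    "aic_threshold_split",
]


# ---------------------------------------------------------------------------
# Cumulative/dynamic AUC
# ---------------------------------------------------------------------------

def _risk_sets(times, events, month):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    case = (events == 1) & (times <= month)
    control = (times >= month) & ~case
    return case, control


def _auc_from_sets(scores, case, control) -> float:
    """Probability a random case outscores a random control (ties 1/2),
    by counting against the sorted control scores."""
    s_case = scores[case]
    s_ctrl = np.sort(scores[control])
    left = np.searchsorted(s_ctrl, s_case, side="left")
    right = np.searchsorted(s_ctrl, s_case, side="right")
    u = left.sum() + 0.5 * (right - left).sum()
    return float(u) / (s_case.size * s_ctrl.size)


def cumulative_auc_at(scores, times, events, month: float, *,
                      ipcw: bool = False) -> float:
    """Cumulative-case/dynamic-control AUC at one month.

    Returns NaN (the undefined-at-month marker) when there is no case
    or no control, or when a participating score is missing. With
    ``ipcw=True`` case/control pairs are weighted by inverse
    Kaplan-Meier censoring probabilities instead of excluding
    early-censored subjects.
    """
    if month <= 0:
        raise ValueError("month must be positive")
    scores = np.asarray(scores, dtype=float)
    case, control = _risk_sets(times, events, month)
    if not case.any() or not control.any():
        return np.nan
    if np.isnan(scores[case | control]).any():
        return np.nan
    if not ipcw:
        return _auc_from_sets(scores, case, control)
    return _ipcw_auc(scores, np.asarray(times, float),
                     np.asarray(events, int), month, case, control)


def _ipcw_auc(scores, times, events, month, case, control) -> float:
    """IPCW-weighted variant: case weights 1/G(T_i-), where G is the
    Kaplan-Meier estimate of the censoring survival function."""
    cens_curve = km_estimate(times, 1 - events)
    g_case = np.array([max(cens_curve.survival_at(t - 1e-9), 1e-8)
                       for t in times[case]])
    w_case = 1.0 / g_case
    s_case = scores[case]
    s_ctrl = scores[control]
    num = 0.0
    for s, w in zip(s_case, w_case):
        num += w * (np.sum(s > s_ctrl) + 0.5 * np.sum(s == s_ctrl))
    return float(num / (w_case.sum() * s_ctrl.size))


# ---------------------------------------------------------------------------
# AUC over months with confidence band
# ---------------------------------------------------------------------------

@dataclass
class TimeAUCCurve:
    """Monthly AUC with percentile 95% band and significance flags."""

    months: np.ndarray
    auc: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_events_by_month: np.ndarray
    significant: np.ndarray       # CI excludes 0.5 (two-tailed, alpha=0.05)
    low_confidence: np.ndarray    # < 3 cumulative events at that month

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "month": self.months, "auc": self.auc,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_events": self.n_events_by_month,
            "significant": self.significant.astype(int),
            "low_confidence": self.low_confidence.astype(int),
        })


def auc_curve_with_ci(risk: OutOfSampleRisk | np.ndarray, times, events,
                      months=None, *, seed: int = 0, n_boot: int = 500,
                      alpha: float = 0.05) -> TimeAUCCurve:
    """AUC point estimate and percentile CI per month.

    With per-replication bootstrap scores (bootstrap out-of-bag
    strategy) the point estimate is the mean of per-replication AUCs and
    the CI their percentile interval; replications undefined at a month
    (e.g. no out-of-bag event yet) are excluded at that month. With a
    single score vector (leave-one-out strategy) the point estimate is
    the plain AUC and the CI comes from a seeded bootstrap over
    subjects. Months before the first event are undefined; months with
    fewer than 3 cumulative events are flagged low-confidence.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if months is None:
        months = np.arange(1, int(np.floor(times.max())) + 1)
    months = np.asarray(months)

    replications = getattr(risk, "replications", None)
    scores = risk.scores if isinstance(risk, OutOfSampleRisk) else np.asarray(
        risk, dtype=float)

    n = times.size
    auc = np.full(months.size, np.nan)
    lo = np.full(months.size, np.nan)
    hi = np.full(months.size, np.nan)
    n_ev = np.array([int(((events == 1) & (times <= m)).sum()) for m in months])

    if replications is not None:
        for k, m in enumerate(months):
            vals = []
            for oob, rep_scores in replications:
                a = cumulative_auc_at(rep_scores, times[oob], events[oob], m)
                if not np.isnan(a):
                    vals.append(a)
            if vals:
                vals = np.asarray(vals)
                auc[k] = float(vals.mean())
                lo[k] = float(np.percentile(vals, 100 * alpha / 2))
                hi[k] = float(np.percentile(vals, 100 * (1 - alpha / 2)))
    else:
        rng = np.random.default_rng(seed)
        boot_idx = rng.integers(0, n, size=(n_boot, n))
        for k, m in enumerate(months):
            a = cumulative_auc_at(scores, times, events, m)
            if np.isnan(a):
                continue
            auc[k] = a
            case, control = _risk_sets(times, events, m)
            vals = []
            for idx in boot_idx:
                c1 = case[idx]
                c0 = control[idx]
                if c1.any() and c0.any():
                    vals.append(_auc_from_sets(scores[idx], c1, c0))
            if len(vals) >= 20:
                lo[k] = float(np.percentile(vals, 100 * alpha / 2))
                hi[k] = float(np.percentile(vals, 100 * (1 - alpha / 2)))
    significant = (~np.isnan(lo)) & ((lo > 0.5) | (hi < 0.5))
    return TimeAUCCurve(months=months, auc=auc, ci_low=lo, ci_high=hi,
                        n_events_by_month=n_ev, significant=significant,
                        low_confidence=n_ev < 3)


# ---------------------------------------------------------------------------
# AIC threshold split
# ---------------------------------------------------------------------------

@dataclass
class RiskGroupSplit:
    """Dichotomisation of the risk score at the minimum-AIC threshold."""

    threshold: float
    labels: np.ndarray            # 'high' / 'low' per subject
    aic: float
    profile: pd.DataFrame         # candidate threshold -> AIC
    km_low: KMCurve
    km_high: KMCurve
    hazard_ratio: float
    wald_p: float


def aic_threshold_split(scores, times, events, *,
                        min_group: int = 5) -> RiskGroupSplit:
    """Split subjects into low/high risk at the score threshold whose
    one-parameter Cox model (high/low indicator, Breslow ties) attains
    the lowest AIC = 2 - 2*maximized partial log-likelihood.

    Candidate thresholds are midpoints between consecutive distinct
    scores, restricted so both groups keep at least ``min_group``
    subjects. The chosen partition depends on score ranks only.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.isnan(scores).any():
        raise ValueError("scores contain missing values")
    if events.sum() < 2:
        raise ValueError("need >= 2 events to stratify")
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("no split possible: all scores identical")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    rows = []
    for thr in candidates:
        high = scores > thr
        if high.sum() < min_group or (~high).sum() < min_group:
            continue
        fit = cox_newton(times, events, high.astype(float), predictor="high_risk")
        aic = 2.0 - 2.0 * fit.loglik
        rows.append((float(thr), aic, fit))
    if not rows:
        raise ValueError("no split possible: every candidate threshold "
                         f"leaves a group below {min_group} subjects")
    profile = pd.DataFrame({"threshold": [r[0] for r in rows],
                            "aic": [r[1] for r in rows]})
    best_i = int(np.argmin(profile["aic"].to_numpy()))
    thr, aic, fit = rows[best_i]
    high = scores > thr
    labels = np.where(high, "high", "low")
    return RiskGroupSplit(
        threshold=thr, labels=labels, aic=aic, profile=profile,
        km_low=km_estimate(times[~high], events[~high]),
        km_high=km_estimate(times[high], events[high]),
        hazard_ratio=fit.hazard_ratio, wald_p=fit.wald_p)


# ---------------------------------------------------------------------------
# Plot helpers (optional artifacts)
# ---------------------------------------------------------------------------

def plot_km(curves: dict[str, KMCurve], path, title="Cumulative onset risk"):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        t = np.concatenate([[0.0], np.repeat(curve.times, 2)])
        r = np.concatenate([[0.0, 0.0],
                            np.repeat(curve.cumulative_risk, 2)[:-1]]) \
            if curve.times.size else np.array([0.0])
        if curve.times.size:
            ax.plot(t, r[:t.size], label=f"{label} (n={curve.n_subjects})")
        else:
            ax.plot([0, 1], [0, 0], label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("cumulative risk")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_auc(curve: TimeAUCCurve, path, title="Discrimination over time"):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.months, curve.auc, "k--", label="AUC")
    ax.fill_between(curve.months, curve.ci_low, curve.ci_high, alpha=0.3)
    sig = curve.significant
    ax.plot(curve.months[sig], curve.auc[sig], "r-", lw=2.5,
            label="CI excludes 0.5")
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.set_ylim(0, 1)
    ax.set_xlabel("months since baseline")
    ax.set_ylabel("cumulative/dynamic AUC")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
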