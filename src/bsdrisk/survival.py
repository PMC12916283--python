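"""Kaplan-Meier estimation and univariate Cox regression.

The screening stage of the analysis fits one Cox proportional-hazards
model per baseline predictor (complete cases only) and reports hazard
ratios with Wald confidence intervals and two-tailed p-values; the
Kaplan-Meier product-limit estimator summarises cumulative onset risk
while accounting for loss to follow-up. Tied event times use the
Breslow approximation throughout, consistent with the penalized fits.

Kaplan-Meier estimation delegates to lifelines; the univariate Cox
Newton-Raphson solver is implemented here because the screening
contract needs explicit non-estimable and divergent-fit flags (constant
predictors, complete separation) rather than exceptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "KMCurve",
    "CoxFit",
    "km_estimate",
    "cumulative_risk_at",
    "cox_newton",
    "cox_fit_univariate",
    "breslow_loglik",
    "breslow_gradient",
]

_ETA_CLIP = 100.0  # keeps exp(eta) finite in float64

#: |standardized beta| beyond which a univariate fit is flagged divergent
SEPARATION_BOUND = 10.0


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the event times.

    ``times`` holds the distinct event times (ascending); ``survival``
    the right-continuous S(t) just after each; ``at_risk`` the risk-set
    size just before each event time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_subjects: int
    n_events: int

    @property
    def cumulative_risk(self) -> np.ndarray:
        return 1.0 - self.survival

    def survival_at(self, t: float) -> float:
        """S(t) with the right-continuous step convention; S(0) = 1."""
        if t < 0:
            raise ValueError("t must be non-negative")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Censored subjects leave the risk set after their censoring time;
    ties of events and censorings at the same time are resolved
    events-first (the censored subject is still at risk for the tied
    event).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    ev_rows = table[table["observed"] > 0]
    ev_times = ev_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(ev_times).to_numpy(dtype=float)
    at_risk = ev_rows["at_risk"].to_numpy(dtype=int)
    return KMCurve(times=ev_times, survival=surv, at_risk=at_risk,
                   n_subjects=int(times.size), n_events=int(events.sum()))


def cumulative_risk_at(curve: KMCurve, t: float) -> float:
    """Cumulative event risk 1 - S(t); t beyond the last event time
    returns the final value (step-function convention)."""
    return 1.0 - curve.survival_at(t)


# ---------------------------------------------------------------------------
# Breslow partial likelihood machinery (shared with the penalized fits)
# ---------------------------------------------------------------------------

def _sorted_groups(times: np.ndarray):
    order = np.argsort(times, kind="stable")
    t = times[order]
    is_new = np.empty(t.size, dtype=bool)
    is_new[0] = True
    is_new[1:] = t[1:] != t[:-1]
    starts = np.flatnonzero(is_new)
    group_id = np.cumsum(is_new) - 1
    return order, starts, group_id


def breslow_loglik(times, events, eta) -> float:
    """Breslow-tie Cox partial log-likelihood at linear predictor eta."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    eta = np.asarray(eta, dtype=float)
    order, starts, _ = _sorted_groups(times)
    e = events[order]
    h = np.clip(eta[order], -_ETA_CLIP, _ETA_CLIP)
    theta = np.exp(h)
    rev = np.cumsum(theta[::-1])[::-1]
    s0 = rev[starts]
    d = np.add.reduceat(e, starts)
    return float(np.sum(h * e) - np.sum(d * np.log(s0)))


def breslow_gradient(times, events, eta):
    """Per-subject gradient and curvature of the Breslow partial
    log-likelihood with respect to eta (diagonal Hessian approximation),
    plus the log-likelihood. Used by the penalized Cox solver's
    quadratic approximation and by KKT certificates."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    eta = np.asarray(eta, dtype=float)
    n = times.size
    order, starts, group_id = _sorted_groups(times)
    e = events[order]
    h = np.clip(eta[order], -_ETA_CLIP, _ETA_CLIP)
    theta = np.exp(h)
    rev = np.cumsum(theta[::-1])[::-1]
    s0 = rev[starts]
    d = np.add.reduceat(e, starts)
    inc1 = np.cumsum(d / s0)[group_id]
    inc2 = np.cumsum(d / s0 ** 2)[group_id]
    grad_s = e - theta * inc1
    w_s = theta * inc1 - theta ** 2 * inc2
    ll = float(np.sum(h * e) - np.sum(d * np.log(s0)))
    grad = np.empty(n)
    w = np.empty(n)
    grad[order] = grad_s
    w[order] = w_s
    return grad, w, ll


def _cox_score_info(times, events, x, beta):
    """(loglik, score U, information I) for a single-covariate Cox model."""
    order, starts, group_id = _sorted_groups(times)
    e = np.asarray(events, dtype=float)[order]
    xs = np.asarray(x, dtype=float)[order]
    h = np.clip(beta * xs, -_ETA_CLIP, _ETA_CLIP)
    theta = np.exp(h)
    s0 = np.cumsum(theta[::-1])[::-1][starts]
    s1 = np.cumsum((theta * xs)[::-1])[::-1][starts]
    s2 = np.cumsum((theta * xs ** 2)[::-1])[::-1][starts]
    d = np.add.reduceat(e, starts)
    m1 = s1 / s0
    ll = float(np.sum(h * e) - np.sum(d * np.log(s0)))
    u = float(np.sum(e * xs) - np.sum(d * m1))
    info = float(np.sum(d * (s2 / s0 - m1 ** 2)))
    return ll, u, info


# ---------------------------------------------------------------------------
# Univariate Cox
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Univariate Cox fit: log-hazard slope, hazard ratio with Wald CI
    and two-tailed p-value, plus flags for degenerate fits."""

    predictor: str
    beta: float
    hazard_ratio: float
    se: float
    wald_p: float
    ci_95: tuple[float, float]
    n: int
    n_events: int
    loglik: float = np.nan
    loglik_null: float = np.nan
    n_iter: int = 0
    non_estimable: bool = False
    divergent: bool = False


class CoxConvergenceError(RuntimeError):
    pass


def cox_newton(times, events, x, *, predictor: str = "x", alpha: float = 0.05,
               max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Newton-Raphson maximization of the Breslow partial likelihood for
    a single covariate, with step-halving.

    Convergence is declared when the log-likelihood improvement drops
    below ``tol``. A constant covariate yields a flagged non-estimable
    result (HR 1, infinite CI); complete separation (|standardized beta|
    beyond :data:`SEPARATION_BOUND`) yields a flagged divergent fit.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    n = times.size
    n_events = int(events.sum())
    sd = float(x.std())
    z_crit = stats.norm.ppf(1 - alpha / 2)
    if sd == 0.0 or n_events == 0:
        ll0 = breslow_loglik(times, events, np.zeros(n))
        return CoxFit(predictor=predictor, beta=0.0, hazard_ratio=1.0,
                      se=np.inf, wald_p=1.0, ci_95=(0.0, np.inf),
                      n=n, n_events=n_events, loglik=ll0, loglik_null=ll0,
                      non_estimable=True)
    mu = float(x.mean())
    xs = (x - mu) / sd
    beta = 0.0
    ll, u, info = _cox_score_info(times, events, xs, beta)
    ll_null = ll
    divergent = False
    it = 0
    for it in range(1, max_iter + 1):
        if info <= 0:
            raise CoxConvergenceError(
                f"{predictor}: non-positive information at iteration {it}")
        step = u / info
        new_beta = beta + step
        ll_new, u_new, info_new = _cox_score_info(times, events, xs, new_beta)
        halvings = 0
        while ll_new < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            ll_new, u_new, info_new = _cox_score_info(times, events, xs, new_beta)
            halvings += 1
        improvement = ll_new - ll
        beta, ll, u, info = new_beta, ll_new, u_new, info_new
        if abs(beta) > SEPARATION_BOUND:
            divergent = True
            break
        if abs(improvement) < tol:
            break
    else:
        raise CoxConvergenceError(
            f"{predictor}: no convergence after {max_iter} iterations "
            f"(last improvement {improvement:.3e}, beta={beta:.3f})")
    se_s = 1.0 / np.sqrt(info) if info > 0 else np.inf
    beta_raw = beta / sd
    se_raw = se_s / sd
    z = beta / se_s if np.isfinite(se_s) and se_s > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    lo = float(np.exp(np.clip(beta_raw - z_crit * se_raw, -_ETA_CLIP, _ETA_CLIP)))
    hi = float(np.exp(np.clip(beta_raw + z_crit * se_raw, -_ETA_CLIP, _ETA_CLIP)))
    hr = float(np.exp(np.clip(beta_raw, -_ETA_CLIP, _ETA_CLIP)))
    return CoxFit(predictor=predictor, beta=float(beta_raw), hazard_ratio=hr,
                  se=float(se_raw), wald_p=p, ci_95=(lo, hi), n=n,
                  n_events=n_events, loglik=ll, loglik_null=ll_null,
                  n_iter=it, divergent=divergent)


def cox_fit_univariate(cohort, predictor: str, *, alpha: float = 0.05) -> CoxFit:
    """Univariate screening fit for one predictor column of a cohort.

    Subjects with a missing value for the predictor are dropped
    (complete-case analysis; only the multivariable pipeline imputes).
    """
    design = cohort.design_frame()
    if predictor not in design.columns:
        raise KeyError(f"unknown predictor {predictor!r}")
    col = design[predictor].to_numpy(dtype=float)
    keep = ~np.isnan(col)
    n_keep = int(keep.sum())
    if n_keep < 2:
        raise ValueError(f"{predictor}: fewer than 2 complete cases")
    x = col[keep]
    if np.unique(x).size < 2:
        warnings.warn(f"{predictor}: constant among complete cases; "
                      "non-estimable", stacklevel=2)
    return cox_newton(cohort.times[keep], cohort.events[keep], x,
                      predictor=predictor, alpha=alpha)
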