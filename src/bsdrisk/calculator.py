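"""The published four-item bipolar-spectrum disorder risk calculator.

The calculator is a linear score over four BPSS-FP terms —

    0.833 * [prevalence of inflated self-esteem/grandiosity (M3)]
  + 0.079 * [prevalence of racing thoughts (M6)]
  + 0.030 * [severity of overtalkativeness (M5)]
  + 0.035 * [severity of increased energy (M8)]

— with subjects above the cutoff 0.172 classified high-risk (strict
inequality; the boundary itself is low-risk). For descriptive use, the
score maps to a probability of onset within a 20-month horizon through
a logistic regression of observed 20-month status on log(score + eps),
eps = 1e-16 guarding against zero scores; the logistic intercept and
slope are not part of the published model and are refit on whatever
cohort is supplied.

The cross-validated model additionally carries a fifth, negligible term
(mood lability, G1, beta = 0.001); the published formula omits it and
the calculator matches the published formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .lasso import LassoFit, compute_relevance

__all__ = [
    "CalculatorModel",
    "CalculatorProfile",
    "PUBLISHED_COEFFICIENTS",
    "score_profile",
    "classify_risk",
    "fit_horizon_mapping",
    "probability_at_horizon",
    "relevance_table",
]

PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "prevalence_M3": 0.833,   # inflated self-esteem/grandiosity, present
    "prevalence_M6": 0.079,   # racing thoughts, present
    "severity_M5": 0.030,     # overtalkativeness, 0-6
    "severity_M8": 0.035,     # increased energy, 0-6
}

PUBLISHED_CUTOFF = 0.172


@dataclass(frozen=True)
class CalculatorModel:
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(PUBLISHED_COEFFICIENTS))
    cutoff: float = PUBLISHED_CUTOFF
    epsilon: float = 1e-16
    horizon_months: float = 20.0
    logistic_intercept: float | None = None
    logistic_slope: float | None = None

    def __post_init__(self):
        if any(v < 0 for v in self.coefficients.values()):
            raise ValueError("published coefficients are non-negative")
        if self.cutoff <= 0 or self.epsilon <= 0:
            raise ValueError("cutoff and epsilon must be positive")


@dataclass(frozen=True)
class CalculatorProfile:
    """The four calculator inputs for one subject; no missing entries
    are accepted at scoring time."""

    prevalence_M3: int
    prevalence_M6: int
    severity_M5: int
    severity_M8: int

    def __post_init__(self):
        for name in ("prevalence_M3", "prevalence_M6"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {v!r}")
        for name in ("severity_M5", "severity_M8"):
            v = getattr(self, name)
            if v not in range(0, 7):
                raise ValueError(f"{name} must be an integer 0-6, got {v!r}")


def score_profile(profile: CalculatorProfile,
                  model: CalculatorModel | None = None) -> float:
    """Linear risk score: dot product of the profile with the model
    coefficients, evaluated in decimal arithmetic at the published
    precision (so e.g. a full-scale profile scores exactly 1.302)."""
    model = model or CalculatorModel()
    values = {
        "prevalence_M3": profile.prevalence_M3,
        "prevalence_M6": profile.prevalence_M6,
        "severity_M5": profile.severity_M5,
        "severity_M8": profile.severity_M8,
    }
    total = Decimal(0)
    for name, coef in model.coefficients.items():
        total += Decimal(str(coef)) * Decimal(values[name])
    return float(total)


def classify_risk(score: float, model: CalculatorModel | None = None) -> str:
    """'high' iff the score strictly exceeds the cutoff, else 'low'."""
    model = model or CalculatorModel()
    if score < 0:
        raise ValueError("score must be non-negative")
    return "high" if score > model.cutoff else "low"


def fit_horizon_mapping(scores, times, events,
                        model: CalculatorModel | None = None) -> CalculatorModel:
    """Fit the logistic score -> horizon-probability mapping.

    The dependent variable is observed onset status at the horizon;
    subjects censored before the horizon without an event have unknown
    status and are excluded from fitting. The independent variable is
    log(score + eps). Returns a copy of the model carrying the fitted
    intercept and slope.
    """
    model = model or CalculatorModel()
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    h = model.horizon_months
    onset = (events == 1) & (times <= h)
    known = onset | (times >= h)
    if onset.sum() < 3:
        raise ValueError(
            f"need >= 3 events by {h} months to fit the mapping "
            f"(got {int(onset.sum())})")
    x = np.log(np.maximum(scores[known], 0.0) + model.epsilon)
    y = onset[known].astype(float)
    if np.unique(x).size < 2:
        raise ValueError("scores are constant among subjects with known "
                         "horizon status; mapping not identifiable")
    design = sm.add_constant(x)
    res = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    return replace(model, logistic_intercept=float(res.params[0]),
                   logistic_slope=float(res.params[1]))


def probability_at_horizon(score: float, model: CalculatorModel) -> float:
    """expit(a + b*log(score + eps)): estimated probability of onset
    within the model horizon; monotone non-decreasing in the score when
    the fitted slope is non-negative, and finite at score 0 thanks to
    eps."""
    if model.logistic_intercept is None or model.logistic_slope is None:
        raise ValueError("horizon mapping not fitted; call fit_horizon_mapping")
    if score < 0:
        raise ValueError("score must be non-negative")
    z = model.logistic_intercept + model.logistic_slope * np.log(
        score + model.epsilon)
    return float(1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))))


def relevance_table(fit: LassoFit) -> pd.DataFrame:
    """Selected predictors with standardized beta and relevance,
    sorted descending by relevance (the published model-table shape)."""
    relevance = compute_relevance(fit)
    rows = [(name, fit.coefficients[name], rel)
            for name, rel in relevance.items()]
    table = pd.DataFrame(rows, columns=["predictor", "beta", "relevance"])
    return table.sort_values("relevance", ascending=False,
                             ignore_index=True)
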