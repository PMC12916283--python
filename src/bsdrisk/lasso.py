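"""L1-penalized gaussian, binomial and Cox regression with a
regularization path.

These solvers back both the imputation models (gaussian/binomial) and
the prognostic Cox model. All families minimise

    (negative log-likelihood) / n  +  lambda * sum_j |beta_j|

on predictors standardized to mean 0 and population SD 1, by cyclic
coordinate descent; binomial and Cox wrap the weighted-least-squares
kernel in an outer quadratic (IRLS) approximation, Cox using the
Breslow partial likelihood with a diagonal Hessian. Coefficients are
reported on both the standardized and the original scale.

Lambda selection is inner k-fold cross-validation on deviance with the
"min" rule, seeded fold assignment, and a log-spaced grid descending
from lambda_max (the smallest penalty that zeroes every coefficient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cd import cd_wls
from .survival import breslow_gradient, breslow_loglik

__all__ = [
    "StandardizedDesign",
    "LassoFit",
    "LassoPath",
    "LambdaRule",
    "fit_lasso",
    "lambda_max",
    "select_lambda",
    "compute_relevance",
    "kkt_violation",
]

FAMILIES = ("gaussian", "binomial", "cox")

_P_CLIP = 1e-6
_W_FLOOR = 1e-9


class LassoConvergenceError(RuntimeError):
    pass


class LassoDivergedError(LassoConvergenceError):
    """Coefficients ran away (e.g. separation at a tiny penalty)."""


#: standardized-scale coefficient bound beyond which a fit is declared
#: divergent rather than iterated further
_BETA_BOUND = 1e3


# ---------------------------------------------------------------------------
# Standardized design
# ---------------------------------------------------------------------------

@dataclass
class StandardizedDesign:
    """Predictor matrix centered to mean 0 and scaled to population SD 1,
    with the means/SDs stored for back-transformation. Zero-variance
    columns are removed with a warning."""

    X: np.ndarray
    names: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str] = field(default_factory=list)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StandardizedDesign":
        if frame.isna().any().any():
            bad = frame.columns[frame.isna().any()][0]
            raise ValueError(f"design contains missing cells (e.g. {bad!r}); "
                             "impute before standardizing")
        return cls.from_array(frame.to_numpy(dtype=float), list(frame.columns))

    @classmethod
    def from_array(cls, X: np.ndarray, names: list[str]) -> "StandardizedDesign":
        X = np.asarray(X, dtype=float)
        means = X.mean(axis=0)
        sds = X.std(axis=0)  # population SD (divisor n)
        keep = sds > 0
        dropped = [n for n, k in zip(names, keep) if not k]
        if dropped:
            warnings.warn(f"dropping zero-variance columns: {dropped}",
                          stacklevel=2)
        Xs = (X[:, keep] - means[keep]) / sds[keep]
        return cls(X=np.ascontiguousarray(Xs),
                   names=[n for n, k in zip(names, keep) if k],
                   means=means[keep], sds=sds[keep], dropped=dropped)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def back_transform(self, beta_std: np.ndarray, intercept_std: float = 0.0):
        """Map standardized-scale coefficients to the original scale."""
        beta_raw = beta_std / self.sds
        intercept_raw = intercept_std - float(np.sum(beta_raw * self.means))
        return beta_raw, intercept_raw


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

@dataclass
class LassoFit:
    """A single penalized fit at one lambda.

    ``coefficients`` live on the standardized scale (the scale on which
    the penalty and the relevance metric are defined); ``coefficients_raw``
    on the original predictor scale. For gaussian/binomial,
    ``intercept_raw`` completes the raw-scale linear predictor; Cox has
    no intercept (absorbed by the baseline hazard).
    """

    family: str
    lam: float
    coefficients: dict[str, float]
    coefficients_raw: dict[str, float]
    intercept: float
    intercept_raw: float
    names: list[str]
    means: np.ndarray
    sds: np.ndarray
    n_iter: int = 0

    @property
    def active_set(self) -> list[str]:
        return [k for k, v in self.coefficients.items() if v != 0.0]

    def beta_std(self) -> np.ndarray:
        return np.array([self.coefficients[k] for k in self.names])

    def predict_linear(self, frame: pd.DataFrame) -> np.ndarray:
        """Raw-scale linear predictor for new subjects.

        gaussian/binomial include the intercept; for Cox this is the
        log-relative-hazard score sum_j beta_raw_j * x_j (uncentered —
        any additive constant is irrelevant to ranking and to the
        partial likelihood).
        """
        missing = [n for n in self.names if n not in frame.columns]
        if missing:
            raise KeyError(f"prediction frame lacks columns {missing}")
        X = frame[self.names].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("prediction frame contains missing cells")
        beta_raw = np.array([self.coefficients_raw[k] for k in self.names])
        eta = X @ beta_raw
        if self.family != "cox":
            eta = eta + self.intercept_raw
        return eta

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "lambda": self.lam,
            "coefficients": self.coefficients,
            "coefficients_raw": self.coefficients_raw,
            "intercept": self.intercept,
            "intercept_raw": self.intercept_raw,
        }


@dataclass
class LassoPath:
    """Descending lambda grid with CV deviances and the selected fit."""

    family: str
    lambdas: np.ndarray
    cv_deviance: np.ndarray
    selected_lambda: float
    selected_fit: LassoFit
    rule: str = "cv_min"
    n_folds: int = 0
    coef_path: np.ndarray | None = None  # (n_lambda, p), standardized scale


@dataclass(frozen=True)
class LambdaRule:
    """Cross-validation settings for lambda selection."""

    n_folds: int = 10
    n_lambda: int = 100
    decades: float = 4.0


# ---------------------------------------------------------------------------
# Core solvers (standardized scale)
# ---------------------------------------------------------------------------

def _check_family(family: str):
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")


def _gaussian_objective(X, y, beta, b0, lam):
    r = y - b0 - X @ beta
    return float(r @ r / (2 * X.shape[0]) + lam * np.abs(beta).sum())


def _solve_gaussian(X, y, lam, beta, max_iter, tol):
    w = np.ones(X.shape[0])
    y = y.astype(float)
    b0 = float(y.mean())
    total = 0
    obj = _gaussian_objective(X, y, beta, b0, lam)
    # coefficient-change convergence, with an objective-stagnation stop
    # for rank-deficient (p > n) designs whose minimizer set is flat
    while total < max(max_iter, 20_000):
        b0, sweeps, dmax = cd_wls(X, w, y, beta, b0, lam, True, 200, tol)
        total += sweeps
        new_obj = _gaussian_objective(X, y, beta, b0, lam)
        if dmax < tol:
            if tol <= 1e-6:
                # polish so the KKT certificate holds tightly
                b0, sweeps, _ = cd_wls(X, w, y, beta, b0, lam, True, 500,
                                       1e-13)
                total += sweeps
            return beta, b0, total
        if obj - new_obj < 1e-12 * (1.0 + abs(new_obj)):
            return beta, b0, total
        obj = new_obj
    raise LassoConvergenceError(
        f"gaussian lasso: no convergence at lambda={lam:.4g} "
        f"after {total} sweeps")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def _irls_l1(X, lam, beta, b0, use_intercept, tol, max_iter,
             linearize, objective, label):
    """Proximal-Newton outer loop shared by the binomial and cox
    families: at each iteration the smooth loss is replaced by its
    weighted quadratic approximation and solved by coordinate descent;
    if the full step raises the penalized objective (IRLS is not
    monotone), the update backtracks along the step direction, which is
    a guaranteed descent direction."""
    n = X.shape[0]
    inner_tol = max(tol * 1e-3, 1e-12)
    obj_tol = max(tol * 1e-4, 1e-13)
    obj = objective(beta, b0)
    total = 0
    n_outer = 200
    for outer in range(n_outer):
        w, z = linearize(beta, b0)
        cand = beta.copy()
        cand_b0, sweeps, _ = cd_wls(X, w, z, cand, b0, lam, use_intercept,
                                    min(max_iter, 1000), inner_tol)
        total += sweeps
        cand_obj = objective(cand, cand_b0)
        full_step = cand_obj <= obj + 1e-12 * (1.0 + abs(obj))
        if not full_step:
            d, d0 = cand - beta, cand_b0 - b0
            t = 0.5
            for _ in range(25):
                trial = beta + t * d
                trial_b0 = b0 + t * d0
                trial_obj = objective(trial, trial_b0)
                if trial_obj <= obj - 1e-15:
                    cand, cand_b0, cand_obj = trial, trial_b0, trial_obj
                    break
                t /= 2.0
            else:
                return beta, b0, total  # numerical plateau
        scale = max(1.0, float(np.max(np.abs(cand), initial=0.0)))
        if scale > _BETA_BOUND:
            raise LassoDivergedError(
                f"{label} lasso diverged at lambda={lam:.4g} "
                f"(|beta| > {_BETA_BOUND:g}; separation)")
        change = max(float(np.max(np.abs(cand - beta), initial=0.0)),
                     abs(cand_b0 - b0) if use_intercept else 0.0)
        converged = (change < tol * scale
                     or abs(obj - cand_obj) < obj_tol * (1.0 + abs(cand_obj)))
        beta[:] = cand
        b0, obj = cand_b0, cand_obj
        if converged:
            if not full_step:
                # a backtracked (interpolated) step may carry non-exact
                # zeros; one full CD solve restores sparsity if it does
                # not worsen the objective
                w, z = linearize(beta, b0)
                cand = beta.copy()
                cand_b0, sweeps, _ = cd_wls(X, w, z, cand, b0, lam,
                                            use_intercept,
                                            min(max_iter, 1000), inner_tol)
                total += sweeps
                if objective(cand, cand_b0) <= obj + 1e-10 * (1 + abs(obj)):
                    beta[:] = cand
                    b0 = cand_b0
            return beta, b0, total
    raise LassoConvergenceError(
        f"{label} lasso: no outer convergence at lambda={lam:.4g} "
        f"after {n_outer} iterations (last change {change:.2e})")


def _solve_binomial(X, y, lam, beta, max_iter, tol):
    n = X.shape[0]
    pbar = float(np.clip(y.mean(), _P_CLIP, 1 - _P_CLIP))

    def objective(b, b0):
        eta = b0 + X @ b
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return -ll / n + lam * float(np.abs(b).sum())

    def linearize(b, b0):
        eta = b0 + X @ b
        p = _expit(eta)
        w = p * (1 - p)
        # saturation guard: treat near-0/1 probabilities as exact with a
        # floor weight, so their working residual vanishes instead of
        # exploding under (quasi-)separation
        low = p < 1e-5
        high = p > 1 - 1e-5
        p = np.where(low, 0.0, np.where(high, 1.0, p))
        w = np.where(low | high, 1e-5, w)
        return w, eta + (y - p) / w

    b0_init = float(np.log(pbar / (1 - pbar)))
    return _irls_l1(X, lam, beta, b0_init, True, tol, max_iter,
                    linearize, objective, "binomial")


def _solve_cox(X, times, events, lam, beta, max_iter, tol):
    n = X.shape[0]

    def objective(b, _b0):
        ll = breslow_loglik(times, events, X @ b)
        return -ll / n + lam * float(np.abs(b).sum())

    def linearize(b, _b0):
        eta = X @ b
        grad, w, _ = breslow_gradient(times, events, eta)
        w = np.maximum(w, _W_FLOOR)
        return w, eta + grad / w

    beta, b0, total = _irls_l1(X, lam, beta, 0.0, False, tol, max_iter,
                               linearize, objective, "cox")
    return beta, 0.0, total


def _solve(X, outcome, lam, family, beta, max_iter=5000, tol=1e-7):
    if family == "gaussian":
        return _solve_gaussian(X, np.asarray(outcome, dtype=float), lam, beta,
                               max_iter, tol)
    if family == "binomial":
        return _solve_binomial(X, np.asarray(outcome, dtype=float), lam, beta,
                               max_iter, tol)
    times, events = outcome
    return _solve_cox(X, np.asarray(times, float), np.asarray(events, float),
                      lam, beta, max_iter, tol)


def _smooth_gradient(X, outcome, family, beta, b0):
    """Gradient of the (1/n-scaled) smooth loss wrt standardized beta."""
    n = X.shape[0]
    if family == "gaussian":
        r = np.asarray(outcome, float) - b0 - X @ beta
        return -(X.T @ r) / n
    if family == "binomial":
        p = _expit(b0 + X @ beta)
        return -(X.T @ (np.asarray(outcome, float) - p)) / n
    times, events = outcome
    grad, _, _ = breslow_gradient(times, events, X @ beta)
    return -(X.T @ grad) / n


def kkt_violation(design: StandardizedDesign, outcome, family: str,
                  fit: LassoFit) -> float:
    """Maximum violation of the subgradient optimality conditions:
    |g_j| <= lambda for inactive coordinates and g_j = -sign(beta_j)*lambda
    for active ones. Zero (to numerical tolerance) certifies the solution."""
    beta = fit.beta_std()
    g = _smooth_gradient(design.X, outcome, family, beta, fit.intercept)
    viol = np.where(beta == 0.0,
                    np.maximum(np.abs(g) - fit.lam, 0.0),
                    np.abs(g + np.sign(beta) * fit.lam))
    return float(viol.max(initial=0.0))


def lambda_max(design: StandardizedDesign, outcome, family: str) -> float:
    """Smallest penalty at which every coefficient is exactly zero."""
    _check_family(family)
    g = _smooth_gradient(design.X, outcome, family,
                         np.zeros(design.p), _null_intercept(outcome, family))
    return float(np.abs(g).max(initial=0.0))


def _null_intercept(outcome, family):
    if family == "gaussian":
        return float(np.mean(outcome))
    if family == "binomial":
        pbar = float(np.clip(np.mean(outcome), _P_CLIP, 1 - _P_CLIP))
        return float(np.log(pbar / (1 - pbar)))
    return 0.0


def fit_lasso(design: StandardizedDesign, outcome, lam: float,
              family: str, *, beta0: np.ndarray | None = None,
              max_iter: int = 5000, tol: float = 1e-7) -> LassoFit:
    """Fit one L1-penalized model at a fixed lambda.

    ``outcome`` is a numeric vector for gaussian, a 0/1 vector for
    binomial, and a ``(times, events)`` pair for cox (requiring at
    least one event). ``beta0`` warm-starts the standardized-scale
    coefficients.
    """
    _check_family(family)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if family == "cox":
        times, events = outcome
        if np.sum(events) < 1:
            raise ValueError("cox family requires at least one event")
    beta = (np.zeros(design.p) if beta0 is None
            else np.asarray(beta0, dtype=float).copy())
    beta, b0, sweeps = _solve(design.X, outcome, lam, family, beta,
                              max_iter=max_iter, tol=tol)
    beta_raw, b0_raw = design.back_transform(beta, b0)
    return LassoFit(
        family=family, lam=float(lam),
        coefficients={k: float(v) for k, v in zip(design.names, beta)},
        coefficients_raw={k: float(v) for k, v in zip(design.names, beta_raw)},
        intercept=float(b0), intercept_raw=float(b0_raw),
        names=list(design.names), means=design.means.copy(),
        sds=design.sds.copy(), n_iter=sweeps)


# ---------------------------------------------------------------------------
# Lambda selection
# ---------------------------------------------------------------------------

def _lambda_grid(lmax: float, n_lambda: int, decades: float) -> np.ndarray:
    if lmax <= 0:
        lmax = 1e-3
    return lmax * np.logspace(0, -decades, n_lambda)


#: convergence tolerance for exploratory CV-path fits (the final refit
#: at the selected lambda uses the strict default)
_PATH_TOL = 1e-4


def _path_betas(X, outcome, family, lambdas):
    """Warm-started coefficient path (standardized scale) down the grid.

    The path is frozen at the last stable fit (remaining grid points
    repeat it, so their CV deviance mirrors it and they are never
    preferred) in two situations: divergence or persistent IRLS
    oscillation at a small lambda (separation), and — for cox —
    saturation, when the active set exceeds the event count and the
    partial likelihood has no degrees of freedom left to spend.
    """
    p = X.shape[1]
    n = X.shape[0]
    dfmax = int(np.sum(outcome[1])) if family == "cox" else n - 1
    betas = np.zeros((len(lambdas), p))
    b0s = np.zeros(len(lambdas))
    beta = np.zeros(p)
    for k, lam in enumerate(lambdas):
        try:
            beta, b0, _ = _solve(X, outcome, lam, family, beta, tol=_PATH_TOL)
        except LassoConvergenceError:
            if k == 0:
                raise
            betas[k:] = betas[k - 1]
            b0s[k:] = b0s[k - 1]
            return betas, b0s
        betas[k] = beta
        b0s[k] = b0
        if int(np.count_nonzero(beta)) > dfmax and k + 1 < len(lambdas):
            betas[k + 1:] = betas[k]
            b0s[k + 1:] = b0s[k]
            return betas, b0s
    return betas, b0s


def _subset_outcome(outcome, family, idx):
    if family == "cox":
        times, events = outcome
        return (np.asarray(times, float)[idx], np.asarray(events, float)[idx])
    return np.asarray(outcome, float)[idx]


def _fold_deviance(X_all, outcome, family, train_idx, test_idx, lambdas):
    """Per-lambda CV deviance contribution of one fold.

    gaussian: held-out squared error; binomial: held-out -2 log-lik;
    cox: Verweij-Van Houwelingen partial-likelihood deviance
    -2*(ll_all(beta_k) - ll_train(beta_k)), which stays defined even
    when the held-out fold alone carries too few events.
    """
    Xtr_raw = X_all[train_idx]
    means = Xtr_raw.mean(axis=0)
    sds = Xtr_raw.std(axis=0)
    sds_safe = np.where(sds > 0, sds, 1.0)
    Xtr = (Xtr_raw - means) / sds_safe
    Xtr[:, sds == 0] = 0.0
    out_tr = _subset_outcome(outcome, family, train_idx)
    betas, b0s = _path_betas(np.ascontiguousarray(Xtr), out_tr, family, lambdas)

    dev = np.empty(len(lambdas))
    if family == "cox":
        times, events = outcome
        Xs_all = (X_all - means) / sds_safe
        Xs_all[:, sds == 0] = 0.0
        for k in range(len(lambdas)):
            eta_all = Xs_all @ betas[k]
            ll_all = breslow_loglik(times, events, eta_all)
            ll_tr = breslow_loglik(times[train_idx], events[train_idx],
                                   eta_all[train_idx])
            dev[k] = -2.0 * (ll_all - ll_tr)
        return dev

    Xte = (X_all[test_idx] - means) / sds_safe
    Xte[:, sds == 0] = 0.0
    y_te = _subset_outcome(outcome, family, test_idx)
    for k in range(len(lambdas)):
        eta = b0s[k] + Xte @ betas[k]
        if family == "gaussian":
            dev[k] = float(np.sum((y_te - eta) ** 2))
        else:
            p_te = np.clip(_expit(eta), _P_CLIP, 1 - _P_CLIP)
            dev[k] = float(-2.0 * np.sum(y_te * np.log(p_te)
                                         + (1 - y_te) * np.log(1 - p_te)))
    return dev


def select_lambda(design: StandardizedDesign, outcome, family: str,
                  n_folds: int = 10, seed: int = 0, *,
                  n_lambda: int = 100, decades: float = 4.0) -> LassoPath:
    """Choose lambda by seeded inner k-fold CV on deviance ("min" rule).

    The grid holds ``n_lambda`` log-spaced values descending ``decades``
    orders of magnitude from lambda_max. For cox, if there are fewer
    events than folds the fold count is reduced with a warning.
    """
    _check_family(family)
    n = design.n
    if family == "cox":
        n_events = int(np.sum(outcome[1]))
        if n_events < 3:
            raise ValueError("cox lambda selection needs >= 3 events")
        if n_events < n_folds:
            warnings.warn(f"reducing folds from {n_folds} to {n_events} "
                          "(fewer events than folds)", stacklevel=2)
            n_folds = n_events
    if n_folds < 3:
        raise ValueError("n_folds must be >= 3")
    n_folds = min(n_folds, n)

    lmax = lambda_max(design, outcome, family)
    lambdas = _lambda_grid(lmax, n_lambda, decades)

    rng = np.random.default_rng(seed)
    fold_id = rng.permutation(np.arange(n) % n_folds)
    dev = np.zeros(len(lambdas))
    for f in range(n_folds):
        test_idx = np.flatnonzero(fold_id == f)
        train_idx = np.flatnonzero(fold_id != f)
        dev += _fold_deviance(design.X, outcome, family, train_idx, test_idx,
                              lambdas)
    dev /= n
    best = int(np.argmin(dev))
    # the CV minimum can fall in the separated tail of the path (folds
    # freeze at different depths); back off to the largest lambda at
    # which the full-data fit is stable
    fit = None
    while best >= 0:
        try:
            fit = fit_lasso(design, outcome, float(lambdas[best]), family)
            break
        except LassoConvergenceError:
            best -= 1
    if fit is None:
        raise LassoConvergenceError(
            f"{family}: no lambda on the grid admits a stable fit")
    return LassoPath(family=family, lambdas=lambdas, cv_deviance=dev,
                     selected_lambda=float(lambdas[best]), selected_fit=fit,
                     rule="cv_min", n_folds=n_folds)


# ---------------------------------------------------------------------------
# Relevance
# ---------------------------------------------------------------------------

def compute_relevance(fit: LassoFit) -> dict[str, float]:
    """Relevance of each selected predictor: |standardized coefficient|
    divided by the sum of absolute standardized coefficients. Values are
    non-negative and sum to one over the active set."""
    active = {k: abs(v) for k, v in fit.coefficients.items() if v != 0.0}
    if not active:
        raise ValueError("no predictors selected")
    total = sum(active.values())
    return {k: v / total for k, v in active.items()}
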