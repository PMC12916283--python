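"""Nested multiple imputation and out-of-sample risk estimation.

The central guarantee of the analysis: no subject's risk score is ever
produced by any model — imputation or Cox — whose training rows
included that subject. Two strategies enforce it:

* leave-one-out cross-validation: for each subject, lasso imputation
  models and m multiply-imputed Cox lasso fits are trained on the other
  n-1 subjects; the held-out subject is imputed with the training-fitted
  models and scored per imputation; the m linear predictors are averaged
  into one out-of-sample score.
* bootstrap out-of-bag validation: each of B replications trains the
  same pipeline on a with-replacement resample and scores the subjects
  left out of that resample; per-subject scores average over the
  replications in which the subject was out-of-bag, and per-replication
  scores are retained for confidence-interval construction.

Imputation fits a gaussian lasso per incomplete continuous/ordinal
predictor and a binomial lasso per incomplete binary predictor, each
regressing on all other predictors (never the outcome), on training
rows only; completions are stochastic draws (prediction + residual
noise, or Bernoulli at the predicted probability) so that imputation
uncertainty propagates.

Randomness is organised as a master seed spawning named substreams per
fold / replication / imputation, so any fold can be re-executed
independently and bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .lasso import (LambdaRule, LassoFit, StandardizedDesign,
                    select_lambda)

__all__ = [
    "ValidationConfig",
    "ImputationModelSet",
    "OutOfSampleRisk",
    "fit_imputation_models",
    "impute_multiply",
    "fit_scoring_pipeline",
    "apply_scoring_pipeline",
    "bootstrap_bag",
    "loocv_risk",
    "bootstrap_oob_risk",
    "compare_strategies",
    "design_kinds",
]


@dataclass(frozen=True)
class ValidationConfig:
    """Settings shared by both validation strategies."""

    m_imputations: int = 10
    n_bootstrap: int = 1000
    seed: int = 0
    cox_rule: LambdaRule = LambdaRule(n_folds=10, n_lambda=100, decades=4.0)
    impute_rule: LambdaRule = LambdaRule(n_folds=3, n_lambda=10, decades=1.0)

    def __post_init__(self):
        if self.m_imputations < 1:
            raise ValueError("m_imputations must be >= 1")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


def desk_validation_config(seed: int = 0) -> ValidationConfig:
    """Reduced-cost profile for smoke runs: B=100, m=5, lighter lambda
    search."""
    return ValidationConfig(
        m_imputations=5, n_bootstrap=100, seed=seed,
        cox_rule=LambdaRule(n_folds=4, n_lambda=25, decades=2.5),
        impute_rule=LambdaRule(n_folds=3, n_lambda=8, decades=1.0))


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationModelSet:
    """One lasso per incomplete predictor, fitted on training rows only.

    ``fill`` holds the training means used to complete covariates before
    prediction; ``models`` maps column -> (family, LassoFit or marginal
    parameters, residual SD)."""

    columns: list[str]
    fill: pd.Series
    models: dict[str, dict]


def design_kinds(cohort: CohortTable) -> dict[str, str]:
    """Imputation family per design column: 'binary' or 'continuous'
    (ordinal severities impute as continuous)."""
    kinds: dict[str, str] = {}
    frame = cohort.design_frame()
    for name in frame.columns:
        base = cohort.manifest.get(name)
        if base == "binary":
            kinds[name] = "binary"
        elif base in ("continuous", "ordinal"):
            kinds[name] = "continuous"
        else:  # one-hot indicator of a categorical column
            kinds[name] = "binary"
    return kinds


def fit_imputation_models(train: pd.DataFrame, kinds: dict[str, str],
                          columns: list[str], rule: LambdaRule,
                          seed) -> ImputationModelSet:
    """Fit the per-column imputation lassos on training rows.

    ``columns`` names the predictors to model (those incomplete anywhere
    in the cohort). Covariates are pre-filled with training means for
    the single-pass fit. Columns with fewer than 10 observed training
    rows — or binary columns whose minority class has fewer than 8 —
    fall back to a marginal draw model; a column with no observed
    training values is an error; >50% missing draws a warning.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence) else seed
    col_seeds = ss.spawn(len(columns))
    fill = train.mean()
    if fill.isna().any():
        bad = fill.index[fill.isna()][0]
        raise ValueError(f"predictor {bad!r} entirely missing in training data")
    filled = train.fillna(fill)
    models: dict[str, dict] = {}
    for col, cseed in zip(columns, col_seeds):
        observed = train[col].notna()
        frac_missing = 1.0 - observed.mean()
        if frac_missing > 0.5:
            warnings.warn(f"predictor {col!r}: {frac_missing:.0%} missing in "
                          "training data", stacklevel=2)
        y = train.loc[observed, col].to_numpy(dtype=float)
        family = "binomial" if kinds[col] == "binary" else "gaussian"
        too_sparse = (family == "binomial"
                      and min(y.sum(), y.size - y.sum()) < 8)
        if observed.sum() < 10 or np.unique(y).size < 2 or too_sparse:
            # marginal fallback: a regression carries no usable
            # information here (near-constant or minority class < 8)
            models[col] = {"kind": "marginal", "family": family,
                           "mean": float(y.mean()),
                           "sd": float(y.std()) if y.size else 0.0}
            continue
        covars = filled.loc[observed, filled.columns != col]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-variance columns in folds
            design = StandardizedDesign.from_frame(covars)
            seed_int = int(cseed.generate_state(1)[0] % (2 ** 31))
            path = select_lambda(design, y, family,
                                 n_folds=rule.n_folds, seed=seed_int,
                                 n_lambda=rule.n_lambda, decades=rule.decades)
        fit = path.selected_fit
        resid_sd = None
        if family == "gaussian":
            pred = fit.predict_linear(covars)
            resid_sd = float(np.sqrt(np.mean((y - pred) ** 2)))
        # precompiled raw-scale prediction (column indices + betas), so
        # completion runs on plain arrays
        all_cols = {name: k for k, name in enumerate(train.columns)}
        models[col] = {"kind": "lasso", "family": family, "fit": fit,
                       "resid_sd": resid_sd,
                       "cov_idx": np.array([all_cols[nm] for nm in fit.names],
                                           dtype=int),
                       "beta_raw": np.array([fit.coefficients_raw[nm]
                                             for nm in fit.names]),
                       "b0_raw": fit.intercept_raw}
    return ImputationModelSet(columns=list(columns), fill=fill, models=models)


def _complete_once(frame: pd.DataFrame, models: ImputationModelSet,
                   rng: np.random.Generator) -> pd.DataFrame:
    """One stochastic completion; observed cells untouched."""
    values = frame.to_numpy(dtype=float)
    fill_vec = models.fill.reindex(frame.columns).to_numpy(dtype=float)
    nan_mask = np.isnan(values)
    base = np.where(nan_mask, fill_vec, values)
    out = values.copy()
    col_pos = {name: k for k, name in enumerate(frame.columns)}
    for col in models.columns:
        j = col_pos[col]
        miss = nan_mask[:, j]
        if not miss.any():
            continue
        spec = models.models[col]
        k = int(miss.sum())
        if spec["kind"] == "marginal":
            if spec["family"] == "binomial":
                draws = rng.binomial(1, np.clip(spec["mean"], 0, 1),
                                     k).astype(float)
            else:
                draws = spec["mean"] + spec["sd"] * rng.standard_normal(k)
        else:
            eta = base[np.ix_(miss, spec["cov_idx"])] @ spec["beta_raw"] \
                + spec["b0_raw"]
            if spec["family"] == "binomial":
                p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
                draws = rng.binomial(1, p).astype(float)
            else:
                draws = eta + spec["resid_sd"] * rng.standard_normal(k)
        out[miss, j] = draws
    return pd.DataFrame(out, columns=frame.columns, index=frame.index)


def impute_multiply(train: pd.DataFrame, apply_to: pd.DataFrame,
                    models: ImputationModelSet | None, m: int, seed, *,
                    kinds: dict[str, str] | None = None,
                    rule: LambdaRule = LambdaRule(3, 15, 2.0),
                    ) -> list[pd.DataFrame]:
    """Produce ``m`` independently drawn completions of ``apply_to``.

    If ``models`` is None they are fitted on ``train`` first (which may
    equal ``apply_to``); otherwise they must have been fitted on
    ``train``. With no missing cells all m completions equal the input.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence) else seed
    if models is None:
        if kinds is None:
            raise ValueError("kinds required when models are fitted in-call")
        cols = [c for c in apply_to.columns
                if train[c].isna().any() or apply_to[c].isna().any()]
        s_fit, s_draw = ss.spawn(2)
        models = fit_imputation_models(train, kinds, cols, rule, s_fit)
    else:
        s_draw = ss
    draw_seeds = s_draw.spawn(m)
    return [_complete_once(apply_to, models, np.random.default_rng(s))
            for s in draw_seeds]


# ---------------------------------------------------------------------------
# Out-of-sample risk
# ---------------------------------------------------------------------------

@dataclass
class OutOfSampleRisk:
    """Per-subject risk scores never produced by a model that saw that
    subject. ``replications`` (bootstrap only) keeps per-replication
    out-of-bag index/score pairs for CI construction downstream."""

    subject_ids: np.ndarray
    scores: np.ndarray
    n_contributions: np.ndarray
    strategy: str
    replications: list[tuple[np.ndarray, np.ndarray]] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids,
                             "score": self.scores,
                             "n_contributions": self.n_contributions})


def bootstrap_bag(seed, n: int) -> tuple[np.ndarray, np.ndarray]:
    """One with-replacement resample of ``n`` subjects and its
    out-of-bag complement (expected fraction (1-1/n)^n ~ 0.368)."""
    rng = np.random.default_rng(seed)
    bag = rng.integers(0, n, n)
    oob = np.setdiff1d(np.arange(n), bag)
    return bag, oob


@dataclass
class FoldModel:
    """The training product of one fold/replication: imputation models
    plus one Cox lasso per imputed training dataset."""

    imputation: ImputationModelSet
    cox_fits: list[LassoFit]
    n_train_events: int


def fit_scoring_pipeline(train: pd.DataFrame, times: np.ndarray,
                         events: np.ndarray, kinds: dict[str, str],
                         columns_to_model: list[str],
                         config: ValidationConfig, seed) -> FoldModel:
    """Train the full imputation + m-times-imputed Cox lasso ensemble on
    one training sample. ``seed`` is a SeedSequence (or int) governing
    imputation-model fitting, the m stochastic completions, and the m
    inner lambda-selection fold assignments."""
    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence) else seed
    s_imp, s_draw, s_cv = ss.spawn(3)
    models = fit_imputation_models(train, kinds, columns_to_model,
                                   config.impute_rule, s_imp)
    completions = impute_multiply(train, train, models,
                                  config.m_imputations, s_draw)
    # one fold assignment shared across imputed datasets, so that with
    # no missingness every imputation yields the identical fit
    seed_int = int(s_cv.generate_state(1)[0] % (2 ** 31))
    fits = []
    for completed in completions:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = StandardizedDesign.from_frame(completed)
            path = select_lambda(design, (times, events), "cox",
                                 n_folds=config.cox_rule.n_folds,
                                 seed=seed_int,
                                 n_lambda=config.cox_rule.n_lambda,
                                 decades=config.cox_rule.decades)
        fits.append(path.selected_fit)
    return FoldModel(imputation=models, cox_fits=fits,
                     n_train_events=int(np.sum(events)))


def apply_scoring_pipeline(model: FoldModel, frame: pd.DataFrame,
                           seed) -> np.ndarray:
    """Score held-out subjects: impute them m times with the
    training-fitted models, predict the Cox linear predictor with the
    matching per-imputation fit, and average across imputations."""
    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence) else seed
    # train argument is unused when models are pre-fitted
    completions = impute_multiply(frame, frame, model.imputation,
                                  len(model.cox_fits), ss)
    scores = np.zeros(len(frame))
    for completed, fit in zip(completions, model.cox_fits):
        scores += fit.predict_linear(completed)
    return scores / len(model.cox_fits)


def loocv_risk(cohort: CohortTable, config: ValidationConfig) -> OutOfSampleRisk:
    """Leave-one-out cross-validated risk profile: exactly one
    out-of-sample score per subject."""
    n = cohort.n
    events = cohort.events
    if n < 10:
        raise ValueError("leave-one-out validation needs n >= 10")
    if events.sum() < 3:
        raise ValueError("leave-one-out validation needs >= 3 events")
    frame = cohort.design_frame()
    kinds = design_kinds(cohort)
    cols = [c for c in frame.columns if frame[c].isna().any()]
    times = cohort.times

    master = np.random.SeedSequence(config.seed)
    fold_seeds = master.spawn(n)
    scores = np.full(n, np.nan)
    contributions = np.zeros(n, dtype=int)
    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        if events[train_idx].sum() == 0:
            warnings.warn(f"training fold without events for subject {i}; "
                          "score left missing", stacklevel=2)
            continue
        s_fit, s_apply = fold_seeds[i].spawn(2)
        fold = fit_scoring_pipeline(
            frame.iloc[train_idx].reset_index(drop=True),
            times[train_idx], events[train_idx], kinds, cols, config, s_fit)
        scores[i] = apply_scoring_pipeline(fold, frame.iloc[[i]], s_apply)[0]
        contributions[i] = 1
    return OutOfSampleRisk(subject_ids=cohort.subject_ids.copy(),
                           scores=scores, n_contributions=contributions,
                           strategy="loocv")


def bootstrap_oob_risk(cohort: CohortTable,
                       config: ValidationConfig) -> OutOfSampleRisk:
    """Bootstrap out-of-bag risk profile over ``config.n_bootstrap``
    seeded replications; extra replications are run if any subject was
    never out-of-bag."""
    n = cohort.n
    events = cohort.events
    if n < 10:
        raise ValueError("bootstrap validation needs n >= 10")
    if events.sum() < 3:
        raise ValueError("bootstrap validation needs >= 3 events")
    frame = cohort.design_frame()
    kinds = design_kinds(cohort)
    cols = [c for c in frame.columns if frame[c].isna().any()]
    times = cohort.times

    master = np.random.SeedSequence(config.seed)
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    replications: list[tuple[np.ndarray, np.ndarray]] = []
    b = 0
    budget = config.n_bootstrap
    # after the budget, keep replicating until every subject has been
    # scored out-of-bag at least once (with a hard safety cap)
    while b < budget or (b < 4 * budget and (counts == 0).any()):
        rep_seed = master.spawn(1)[0]
        s_bag, s_fit, s_apply = rep_seed.spawn(3)
        bag, oob = bootstrap_bag(s_bag, n)
        b += 1
        if oob.size == 0:
            continue
        if events[bag].sum() < 3:
            # too few in-bag events to select lambda; replication
            # recorded but contributes no scores
            replications.append((oob, np.full(oob.size, np.nan)))
            continue
        fold = fit_scoring_pipeline(
            frame.iloc[bag].reset_index(drop=True),
            times[bag], events[bag], kinds, cols, config, s_fit)
        rep_scores = apply_scoring_pipeline(fold, frame.iloc[oob], s_apply)
        replications.append((oob, rep_scores))
        sums[oob] += rep_scores
        counts[oob] += 1
    if (counts == 0).any():
        warnings.warn("some subjects were never scored out-of-bag within "
                      "the replication cap", stacklevel=2)
    scores = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return OutOfSampleRisk(subject_ids=cohort.subject_ids.copy(),
                           scores=scores, n_contributions=counts,
                           strategy="bootstrap_oob", replications=replications)


# ---------------------------------------------------------------------------
# Strategy comparison harness
# ---------------------------------------------------------------------------

def compare_strategies(generator_config, replications: int, seed: int,
                       validation_config: ValidationConfig | None = None,
                       *, n_truth: int = 10_000) -> dict:
    """Simulate cohorts with known truth, run both validation
    strategies, and report the distribution of their discrimination
    estimates against the large-sample true AUC.

    The "true" AUC is the cumulative/dynamic AUC of the generating
    linear predictor on an independent simulated test cohort of
    ``n_truth`` subjects, evaluated at the median observed event time of
    each replicate cohort.
    """
    from dataclasses import replace as dc_replace

    from .evaluate import cumulative_auc_at
    from .synthetic import generate_cohort

    if validation_config is None:
        validation_config = desk_validation_config()
    rows = []
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(replications)
    big_cfg = dc_replace(generator_config, n_subjects=n_truth,
                         target_events=max(
                             2, int(round(n_truth * generator_config.target_events
                                          / generator_config.n_subjects))),
                         missing_fraction=0.0,
                         seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31))
    big_cohort, big_truth = generate_cohort(big_cfg)
    for r, rseed in enumerate(rep_seeds):
        ints = rseed.generate_state(3) % (2 ** 31)
        cfg = dc_replace(generator_config, seed=int(ints[0]))
        cohort, truth = generate_cohort(cfg)
        month = float(np.median(cohort.times[cohort.events == 1]))
        vc = dc_replace(validation_config, seed=int(ints[1]))
        loocv = loocv_risk(cohort, vc)
        vc_b = dc_replace(validation_config, seed=int(ints[2]))
        boot = bootstrap_oob_risk(cohort, vc_b)
        auc_true = cumulative_auc_at(
            big_truth.frame["linear_predictor"].to_numpy(),
            big_cohort.times, big_cohort.events, month)
        rows.append({
            "replicate": r,
            "month": month,
            "auc_true": auc_true,
            "auc_loocv": cumulative_auc_at(loocv.scores, cohort.times,
                                           cohort.events, month),
            "auc_bootstrap": cumulative_auc_at(boot.scores, cohort.times,
                                               cohort.events, month),
        })
    frame = pd.DataFrame(rows)
    return {
        "per_replicate": frame,
        "summary": {
            strat: {"mean": float(frame[f"auc_{strat}"].mean()),
                    "sd": float(frame[f"auc_{strat}"].std(ddof=1))
                    if len(frame) > 1 else 0.0}
            for strat in ("loocv", "bootstrap")
        },
        "true_auc_mean": float(frame["auc_true"].mean()),
    }
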