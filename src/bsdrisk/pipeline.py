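"""End-to-end orchestration: screen -> validate -> evaluate -> calculator.

One seeded run reproduces, bit-identically, every numeric artifact:
the univariate screening table, per-subject out-of-sample risk scores
under both validation strategies, the final model table with
relevances, monthly AUC curves with confidence bands, the minimum-AIC
risk stratification with stratified Kaplan-Meier curves, and the fitted
calculator mapping. A provenance block (config, seed, version) is
written alongside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calculator import CalculatorModel, fit_horizon_mapping, relevance_table
from .cohort import CohortTable, default_manifest, read_cohort, read_manifest, \
    write_cohort, write_manifest
from .evaluate import aic_threshold_split, auc_curve_with_ci, plot_auc, plot_km
from .survival import cox_fit_univariate, km_estimate
from .synthetic import GeneratorConfig, generate_cohort
from .validate import (OutOfSampleRisk, ValidationConfig, bootstrap_oob_risk,
                       desk_validation_config, design_kinds,
                       fit_scoring_pipeline, loocv_risk)

log = logging.getLogger("bsdrisk")

__all__ = ["RunConfig", "RunReport", "run_full_analysis"]


@dataclass
class RunConfig:
    outdir: str | Path = "results/run"
    cohort_path: str | Path | None = None       # None -> synthetic cohort
    manifest_path: str | Path | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    alpha: float = 0.05
    horizon_months: float = 60.0
    seed: int = 0
    desk: bool = False               # reduced-cost profile (B=100, m=5)
    strategies: tuple[str, ...] = ("loocv", "bootstrap_oob")
    make_plots: bool = False

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class RunReport:
    outdir: Path
    artifacts: dict[str, Path]
    summary: dict


def run_full_analysis(config: RunConfig) -> RunReport:
    """Execute every stage in order, writing all artifacts to
    ``config.outdir``; idempotent under identical config + seed. Any
    stage failure writes a FAILED marker naming the stage and re-raises,
    leaving earlier artifacts in place."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    summary: dict = {}
    vconf = desk_validation_config(config.seed) if config.desk \
        else config.validation
    stage = "setup"
    try:
        # ---- cohort ------------------------------------------------------
        stage = "cohort"
        log.info("stage=cohort")
        if config.cohort_path is not None:
            manifest = (read_manifest(config.manifest_path)
                        if config.manifest_path else default_manifest())
            cohort = read_cohort(config.cohort_path, manifest,
                                 horizon_months=config.horizon_months)
            truth = None
        else:
            gen = dataclasses.replace(config.generator,
                                      seed=_stage_seed_base(config.seed, 1))
            cohort, truth = generate_cohort(gen)
            artifacts["truth"] = outdir / "truth.csv"
            truth.frame.to_csv(artifacts["truth"], index=False)
        artifacts["cohort"] = outdir / "cohort.csv"
        write_cohort(cohort, artifacts["cohort"])
        artifacts["manifest"] = outdir / "manifest.txt"
        write_manifest(cohort.manifest, artifacts["manifest"])
        summary["n_subjects"] = cohort.n
        summary["n_events"] = int(cohort.events.sum())

        # ---- screen ------------------------------------------------------
        stage = "screen"
        log.info("stage=screen")
        screening = screen_univariate(cohort, alpha=config.alpha)
        artifacts["screening"] = outdir / "screening.csv"
        screening.to_csv(artifacts["screening"], index=False)

        km_all = km_estimate(cohort.times, cohort.events)
        artifacts["km_overall"] = outdir / "km_overall.csv"
        pd.DataFrame({"time_months": km_all.times,
                      "survival": km_all.survival,
                      "cumulative_risk": km_all.cumulative_risk,
                      "at_risk": km_all.at_risk}).to_csv(
            artifacts["km_overall"], index=False)

        # ---- validate ----------------------------------------------------
        stage = "validate"
        risks: dict[str, OutOfSampleRisk] = {}
        if "loocv" in config.strategies:
            log.info("stage=validate strategy=loocv")
            vc = dataclasses.replace(vconf, seed=_stage_seed_base(config.seed, 2))
            risks["loocv"] = loocv_risk(cohort, vc)
            artifacts["risk_loocv"] = outdir / "risk_loocv.csv"
            risks["loocv"].to_frame().to_csv(artifacts["risk_loocv"], index=False)
        if "bootstrap_oob" in config.strategies:
            log.info("stage=validate strategy=bootstrap_oob")
            vc = dataclasses.replace(vconf, seed=_stage_seed_base(config.seed, 3))
            risks["bootstrap_oob"] = bootstrap_oob_risk(cohort, vc)
            artifacts["risk_bootstrap"] = outdir / "risk_bootstrap.csv"
            risks["bootstrap_oob"].to_frame().to_csv(
                artifacts["risk_bootstrap"], index=False)

        # final full-cohort model (for the model table / calculator)
        stage = "final_model"
        log.info("stage=final_model")
        final_fit, model_table = fit_final_model(
            cohort, vconf, seed=_stage_seed_base(config.seed, 4))
        artifacts["model_table"] = outdir / "model_table.csv"
        model_table.to_csv(artifacts["model_table"], index=False)
        artifacts["model_final"] = outdir / "model_final.json"
        artifacts["model_final"].write_text(
            json.dumps(final_fit.to_dict(), indent=2, sort_keys=True))
        summary["n_selected"] = len(final_fit.active_set)

        # ---- evaluate ----------------------------------------------------
        stage = "evaluate"
        log.info("stage=evaluate")
        for name, risk in risks.items():
            curve = auc_curve_with_ci(
                risk, cohort.times, cohort.events,
                seed=_stage_seed_base(config.seed, 5), alpha=config.alpha)
            key = f"auc_{'loocv' if name == 'loocv' else 'bootstrap'}"
            artifacts[key] = outdir / f"{key}.csv"
            curve.to_frame().to_csv(artifacts[key], index=False)
            if config.make_plots:
                plot_auc(curve, outdir / f"{key}.png")

        split = None
        base = risks.get("loocv") or next(iter(risks.values()), None)
        if base is not None and np.unique(
                base.scores[~np.isnan(base.scores)]).size >= 2:
            try:
                split = aic_threshold_split(base.scores, cohort.times,
                                            cohort.events)
            except ValueError as exc:
                log.warning("risk stratification skipped: %s", exc)
        if split is not None:
            artifacts["risk_split"] = outdir / "risk_split.json"
            artifacts["risk_split"].write_text(json.dumps({
                "threshold": split.threshold,
                "aic": split.aic,
                "n_high": int((split.labels == "high").sum()),
                "n_low": int((split.labels == "low").sum()),
                "hazard_ratio": split.hazard_ratio,
                "wald_p": split.wald_p,
            }, indent=2, sort_keys=True))
            km_frame = pd.concat([
                pd.DataFrame({"group": "low", "time_months": split.km_low.times,
                              "cumulative_risk": split.km_low.cumulative_risk}),
                pd.DataFrame({"group": "high", "time_months": split.km_high.times,
                              "cumulative_risk": split.km_high.cumulative_risk}),
            ])
            artifacts["km_by_group"] = outdir / "km_by_group.csv"
            km_frame.to_csv(artifacts["km_by_group"], index=False)
            if config.make_plots:
                plot_km({"low risk": split.km_low, "high risk": split.km_high},
                        outdir / "km_by_group.png")
            summary["risk_threshold"] = split.threshold

        # ---- calculator --------------------------------------------------
        stage = "calculator"
        log.info("stage=calculator")
        calc = CalculatorModel()
        calc_payload = {"coefficients": calc.coefficients,
                        "cutoff": calc.cutoff, "epsilon": calc.epsilon,
                        "horizon_months": calc.horizon_months}
        if base is not None:
            onset20 = ((cohort.events == 1)
                       & (cohort.times <= calc.horizon_months)).sum()
            if onset20 >= 3:
                try:
                    fitted = fit_horizon_mapping(
                        np.maximum(base.scores, 0.0), cohort.times,
                        cohort.events, calc)
                except ValueError as exc:
                    log.warning("horizon mapping skipped: %s", exc)
                else:
                    calc_payload["logistic_intercept"] = \
                        fitted.logistic_intercept
                    calc_payload["logistic_slope"] = fitted.logistic_slope
        artifacts["calculator"] = outdir / "calculator.json"
        artifacts["calculator"].write_text(
            json.dumps(calc_payload, indent=2, sort_keys=True))

        # ---- provenance --------------------------------------------------
        stage = "provenance"
        prov = {
            "version": __version__,
            "seed": config.seed,
            "desk": config.desk,
            "alpha": config.alpha,
            "strategies": list(config.strategies),
            "generator": _as_jsonable(config.generator),
            "validation": _as_jsonable(vconf),
            "summary": summary,
        }
        artifacts["provenance"] = outdir / "provenance.json"
        artifacts["provenance"].write_text(
            json.dumps(prov, indent=2, sort_keys=True))
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\n{exc!r}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    return RunReport(outdir=outdir, artifacts=artifacts, summary=summary)


def _stage_seed_base(seed: int, k: int) -> int:
    """Named deterministic substream per stage, kept below 2**31."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0]
               % (2 ** 31))


def screen_univariate(cohort: CohortTable, alpha: float = 0.05) -> pd.DataFrame:
    """Table-shaped univariate Cox screen: one row per design column
    with HR, 95% CI, two-tailed Wald p, and degenerate-fit flags."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in cohort.design_frame().columns:
            try:
                fit = cox_fit_univariate(cohort, name, alpha=alpha)
            except ValueError:
                continue
            rows.append({
                "predictor": name, "n": fit.n, "n_events": fit.n_events,
                "hazard_ratio": fit.hazard_ratio,
                "ci_low": fit.ci_95[0], "ci_high": fit.ci_95[1],
                "p_value": fit.wald_p,
                "non_estimable": int(fit.non_estimable),
                "divergent": int(fit.divergent),
            })
    return pd.DataFrame(rows)


def fit_final_model(cohort: CohortTable, vconf: ValidationConfig, seed: int):
    """Full-cohort prognostic model: m multiply-imputed Cox lasso fits
    whose standardized coefficients are averaged, with the relevance
    table computed on the average."""
    frame = cohort.design_frame()
    kinds = design_kinds(cohort)
    cols = [c for c in frame.columns if frame[c].isna().any()]
    fold = fit_scoring_pipeline(frame, cohort.times, cohort.events, kinds,
                                cols, vconf, seed)
    names = fold.cox_fits[0].names
    avg_std = np.mean([[f.coefficients[n] for n in names]
                       for f in fold.cox_fits], axis=0)
    template = fold.cox_fits[0]
    avg_fit = dataclasses.replace(
        template,
        coefficients={n: float(v) for n, v in zip(names, avg_std)},
        coefficients_raw={n: float(v / s) for n, v, s in
                          zip(names, avg_std, template.sds)},
    )
    if avg_fit.active_set:
        table = relevance_table(avg_fit)
    else:
        table = pd.DataFrame(columns=["predictor", "beta", "relevance"])
    return avg_fit, table


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _as_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj
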