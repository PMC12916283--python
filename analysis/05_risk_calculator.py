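"""The published four-item risk calculator on worked examples.

Scores example symptom profiles with the published coefficients,
classifies them against the 0.172 cutoff, and — where the cohort
carries enough 20-month onsets — fits the descriptive logistic mapping
from log(score + eps) to the probability of onset within 20 months.

Reads:  results/cohort/cohort.csv, results/risk_loocv.csv
Writes: results/calculator.json, results/calculator_examples.csv
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from bsdrisk.calculator import (CalculatorModel, CalculatorProfile,
                                classify_risk, fit_horizon_mapping,
                                probability_at_horizon, score_profile)
from bsdrisk.cohort import read_cohort, read_manifest

EXAMPLES = [
    ("no mania-like symptoms", CalculatorProfile(0, 0, 0, 0)),
    ("grandiosity only", CalculatorProfile(1, 0, 0, 0)),
    ("racing thoughts + mild talkativeness", CalculatorProfile(0, 1, 2, 0)),
    ("full-scale profile", CalculatorProfile(1, 1, 6, 6)),
]


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--cohort", type=Path,
                        default=Path("results/cohort/cohort.csv"))
    parser.add_argument("--manifest", type=Path,
                        default=Path("results/cohort/manifest.txt"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    model = CalculatorModel()
    fitted = None
    risk_path = args.outdir / "risk_loocv.csv"
    if args.cohort.exists() and risk_path.exists():
        cohort = read_cohort(args.cohort, read_manifest(args.manifest))
        scores = pd.read_csv(risk_path)["score"].to_numpy(dtype=float)
        onsets20 = int(((cohort.events == 1)
                        & (cohort.times <= model.horizon_months)).sum())
        if onsets20 >= 3:
            try:
                fitted = fit_horizon_mapping(np.maximum(scores, 0.0),
                                             cohort.times, cohort.events,
                                             model)
            except ValueError as exc:
                print(f"20-month mapping not fitted: {exc}")
            else:
                print(f"fitted 20-month mapping on {onsets20} onsets: "
                      f"intercept {fitted.logistic_intercept:+.2f}, "
                      f"slope {fitted.logistic_slope:+.3f}")

    rows = []
    for label, profile in EXAMPLES:
        s = score_profile(profile, model)
        row = {"profile": label, "score": s, "risk_group": classify_risk(s)}
        if fitted is not None:
            row["probability_20m"] = probability_at_horizon(s, fitted)
        rows.append(row)
        extra = (f", P(onset by 20 m) = {row['probability_20m']:.2f}"
                 if fitted is not None else "")
        print(f"  {label:<38s} score {s:.3f} -> {row['risk_group']}{extra}")
    pd.DataFrame(rows).to_csv(args.outdir / "calculator_examples.csv",
                              index=False)

    payload = {"coefficients": model.coefficients, "cutoff": model.cutoff,
               "epsilon": model.epsilon,
               "horizon_months": model.horizon_months}
    if fitted is not None:
        payload["logistic_intercept"] = fitted.logistic_intercept
        payload["logistic_slope"] = fitted.logistic_slope
    (args.outdir / "calculator.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True))
    print(f"wrote calculator artifacts to {args.outdir}")


if __name__ == "__main__":
    main()
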