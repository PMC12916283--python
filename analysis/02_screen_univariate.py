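"""Univariate Cox screening of every baseline predictor.

Fits one proportional-hazards model per predictor (complete cases,
Breslow ties) and writes the hazard-ratio table the multivariable
stages start from; prints the predictors crossing alpha = 0.05.

Reads:  results/cohort/cohort.csv (+ manifest)
Writes: results/screening.csv
"""

import argparse
from pathlib import Path

from bsdrisk.cohort import read_cohort, read_manifest
from bsdrisk.pipeline import screen_univariate


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--cohort", type=Path,
                        default=Path("results/cohort/cohort.csv"))
    parser.add_argument("--manifest", type=Path,
                        default=Path("results/cohort/manifest.txt"))
    parser.add_argument("--out", type=Path, default=Path("results/screening.csv"))
    args = parser.parse_args()

    cohort = read_cohort(args.cohort, read_manifest(args.manifest))
    table = screen_univariate(cohort)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)

    hits = table[(table["p_value"] < 0.05) & (table["non_estimable"] == 0)]
    print(f"screened {len(table)} predictors; "
          f"{len(hits)} associated at alpha=0.05:")
    for _, row in hits.sort_values("p_value").head(12).iterrows():
        print(f"  {row['predictor']:<28s} HR={row['hazard_ratio']:6.2f} "
              f"({row['ci_low']:.2f}-{row['ci_high']:.2f}) "
              f"p={row['p_value']:.4f}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
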