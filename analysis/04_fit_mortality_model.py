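"""Fit the random-intercept logistic mortality models.

Main analysis: 30-day death on the competitor-count competition level
plus patient and hospital covariates, hospital as random intercept.
Sensitivity analysis: the same model with the HHI-based level. Writes
odds-ratio tables and prints both model summaries.
"""

import argparse
from pathlib import Path

import pandas as pd

from hospcomp.glmm import ModelSpec, build_design, fit_random_intercept_logistic


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--competition", type=Path, default=Path("results/competition.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = pd.read_csv(args.cohort)
    comp = pd.read_csv(args.competition).set_index("hospital_id")
    cohort = cohort.merge(
        comp[["category_ncomp", "category_hhi"]], left_on="hospital_id", right_index=True
    )
    spec = ModelSpec()
    args.out.mkdir(parents=True, exist_ok=True)
    for label, col in (("ncomp", "category_ncomp"), ("hhi", "category_hhi")):
        sub = cohort.dropna(subset=[col]).copy()
        sub["competition_category"] = sub[col]
        X, y, groups, names = build_design(sub, spec)
        fit = fit_random_intercept_logistic(X, y, groups, names)
        fit.or_table.to_csv(args.out / f"or_table_{label}.csv", index=False)
        (args.out / f"model_{label}.txt").write_text(fit.summary())
        method = "number of competitors (radius)" if label == "ncomp" else "HHI (patient flow)"
        print(f"\n=== competition measured by {method} ===")
        print(fit.summary())
    print(f"\nwrote OR tables to {args.out}/")


if __name__ == "__main__":
    main()
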