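"""Assemble the descriptive tables of the analysis.

Patient baseline characteristics (counts and percentages of every
covariate level) and hospital/market characteristics (hospitals and
patients per competition level, caseload band, status and rurality
band, with NA rows for undelimited markets).
"""

import argparse
from pathlib import Path

import pandas as pd

from hospcomp.cohort import derive_hospital_covariates
from hospcomp.report import hospital_table, patient_table
from hospcomp.synthetic import load_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--competition", type=Path, default=Path("results/competition.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    geo, _ = load_dataset(args.data)
    cohort = pd.read_csv(args.cohort)
    comp = pd.read_csv(args.competition).set_index("hospital_id")
    cohort = cohort.merge(
        comp[["n_competitors", "hhi", "category_ncomp", "category_hhi"]],
        left_on="hospital_id",
        right_index=True,
    )
    hosp = derive_hospital_covariates(cohort, geo)

    t1 = patient_table(cohort)
    t2 = hospital_table(cohort, comp, hosp)
    t1.to_csv(args.out / "table_patients.csv", index=False)
    t2.to_csv(args.out / "table_hospitals.csv", index=False)
    print(t1.to_string(index=False))
    print()
    print(t2.to_string(index=False))
    print(f"\nwrote tables to {args.out}/")


if __name__ == "__main__":
    main()
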