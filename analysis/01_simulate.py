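"""Generate the synthetic claims dataset used by the whole analysis.

Writes municipalities.csv / hospitals.csv / stays.csv under
results/data/ and prints the generative ground truth (competition mix,
true odds ratios, hospital-intercept SD) so later stages can be judged
against it.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hospcomp.report import ground_truth_categories
from hospcomp.synthetic import (
    SimulationConfig,
    generate_admissions,
    generate_geography,
    simulate_outcomes,
    write_dataset,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    geo = generate_geography(cfg)
    stays = generate_admissions(geo, cfg)
    truth = ground_truth_categories(stays, geo)
    stays = simulate_outcomes(stays, truth, cfg)
    write_dataset(geo, stays, args.out)
    pd.Series(truth, name="category").rename_axis("hospital_id").to_csv(
        args.out / "true_competition_categories.csv"
    )

    mix = pd.Series(truth).value_counts()
    print(f"simulated {len(stays)} stays, {cfg.n_hospitals} hospitals, "
          f"{cfg.n_municipalities} municipalities (seed {args.seed})")
    print(f"true competition mix: {mix.to_dict()}")
    print(f"true hospital-intercept SD: {cfg.random_intercept_sd}")
    print(f"true OR highly vs non: {np.exp(cfg.true_beta['competition_category[highly]']):.2f}")
    print(f"crude 30-day mortality: {100 * stays['death_date'].notna().mean():.2f}%")
    print(f"wrote dataset to {args.out}/")


if __name__ == "__main__":
    main()
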