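"""Cohort construction: inclusion filters, outcome, covariates.

The study population is every surgical stay for colorectal cancer
(ICD-10 C18–C20) at a mainland hospital by a mainland resident, over a
five-year window, excluding hospitals with fewer than five such
patients in total and records with missing required fields. Each filter
step is logged so the patient flowchart can be reproduced and checked
for arithmetic consistency.

The primary outcome is death within 30 days of surgery (inclusive).
Hospital covariates: annual caseload banded ≤50 / 51–100 / >100, status
(teaching vs not), and the rurality of the hospital's recruitment area
— the admission-weighted mean density of its patients' municipalities,
banded at patient-level quartiles so each band holds ≈25% of patients.
Patient covariates: age band, Charlson band, deprivation (FDep)
tertile, plus the recorded flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import charlson as _charlson
from .synthetic import age_band, Geography

__all__ = [
    "CohortConfig",
    "FilterLog",
    "REQUIRED_FIELDS",
    "apply_inclusion_filters",
    "derive_outcome",
    "derive_patient_covariates",
    "derive_hospital_covariates",
    "prepare_analysis_table",
]

REQUIRED_FIELDS = (
    "patient_id",
    "hospital_id",
    "municipality_id",
    "surgery_date",
    "age",
    "sex",
    "cancer_code",
    "procedure",
)

CASELOAD_LEVELS = ("<=50", "51-100", ">100")
DENSITY_LEVELS = ("very_rural", "rural", "urban", "very_urban")
FDEP_LEVELS = ("lower", "middle", "upper")


@dataclass(frozen=True)
class CohortConfig:
    included_cancer_codes: frozenset[str] = frozenset({"C18", "C19", "C20"})
    min_patients_per_hospital: int = 5
    mortality_window_days: int = 30
    study_years: int = 5
    caseload_breaks: tuple[float, ...] = (50.0, 100.0)

    def __post_init__(self) -> None:
        if self.mortality_window_days <= 0:
            raise ValueError("mortality_window_days must be positive")
        if list(self.caseload_breaks) != sorted(set(self.caseload_breaks)):
            raise ValueError("caseload_breaks must be strictly increasing")


@dataclass
class FilterLog:
    """Ordered record of filter steps, mirroring a patient flowchart."""

    steps: list[dict] = field(default_factory=list)

    def record(self, name: str, n_before: int, n_after: int) -> None:
        if self.steps and self.steps[-1]["n_after"] != n_before:
            raise ValueError("filter chain broken: n_before != previous n_after")
        self.steps.append(
            {"filter": name, "n_before": n_before, "n_removed": n_before - n_after, "n_after": n_after}
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.steps, indent=2))

    def to_text(self) -> str:
        if not self.steps:
            return "(no filters applied)"
        lines = [f"Assessed stays: {self.steps[0]['n_before']}"]
        for s in self.steps:
            lines.append(f"  - {s['filter']}: removed {s['n_removed']} -> {s['n_after']}")
        lines.append(f"Included: {self.steps[-1]['n_after']}")
        return "\n".join(lines)


def _missing_mask(stays: pd.DataFrame) -> pd.Series:
    miss = pd.Series(False, index=stays.index)
    for col in REQUIRED_FIELDS:
        if col not in stays.columns:
            raise KeyError(f"required column {col!r} absent")
        col_missing = stays[col].isna()
        if stays[col].dtype == object:
            col_missing |= stays[col].astype(str).str.len() == 0
        miss |= col_missing
    return miss


def apply_inclusion_filters(
    stays: pd.DataFrame, geo: Geography, config: CohortConfig | None = None
) -> tuple[pd.DataFrame, FilterLog]:
    """Apply the inclusion/exclusion cascade and log the flowchart.

    Order: cancer diagnosis, mainland residence, mainland hospital,
    minimum hospital volume (computed on the already-filtered stays),
    then missing-data removal. Rows whose municipality is unknown are
    kept through the geographic steps and fall out at the missing-data
    step. An empty input yields an empty cohort with a log, not an
    error.
    """
    config = config or CohortConfig()
    log = FilterLog()
    cur = stays.copy()
    missing = _missing_mask(cur)

    n0 = len(cur)
    keep = cur["cancer_code"].isin(config.included_cancer_codes) | missing
    cur = cur.loc[keep]
    missing = missing.loc[keep]
    log.record("cancer_diagnosis_C18_C20", n0, len(cur))

    region = geo.municipalities.set_index("municipality_id")["region"]
    res_region = cur["municipality_id"].map(region)
    keep = (res_region == "mainland") | missing
    n0 = len(cur)
    cur = cur.loc[keep]
    missing = missing.loc[keep]
    log.record("mainland_residence", n0, len(cur))

    hreg = geo.hospitals.set_index("hospital_id")["region"]
    hosp_region = cur["hospital_id"].map(hreg)
    keep = (hosp_region == "mainland") | missing
    n0 = len(cur)
    cur = cur.loc[keep]
    missing = missing.loc[keep]
    log.record("mainland_hospital", n0, len(cur))

    counts = cur["hospital_id"].value_counts()
    big = counts[counts >= config.min_patients_per_hospital].index
    keep = cur["hospital_id"].isin(big) | missing
    n0 = len(cur)
    cur = cur.loc[keep]
    missing = missing.loc[keep]
    log.record(f"hospital_volume_ge_{config.min_patients_per_hospital}", n0, len(cur))

    n0 = len(cur)
    cur = cur.loc[~missing]
    log.record("missing_data", n0, len(cur))

    return cur.reset_index(drop=True), log


def derive_outcome(stays: pd.DataFrame, config: CohortConfig | None = None) -> np.ndarray:
    """30-day mortality indicator (inclusive window).

    1 iff a death date exists and falls within ``mortality_window_days``
    of surgery; a death before surgery is a data error.
    """
    config = config or CohortConfig()
    surgery = pd.to_datetime(stays["surgery_date"])
    death = pd.to_datetime(stays["death_date"]) if "death_date" in stays else pd.Series(pd.NaT, index=stays.index)
    delta = (death - surgery).dt.days
    if (delta < 0).any():
        bad = stays.loc[delta < 0, "patient_id"].tolist()[:5]
        raise ValueError(f"death before surgery for patient(s) {bad}")
    return ((delta >= 0) & (delta <= config.mortality_window_days)).astype(int).to_numpy()


def derive_patient_covariates(
    stays: pd.DataFrame, geo: Geography, config: CohortConfig | None = None
) -> pd.DataFrame:
    """Add age band, Charlson score/band, FDep tertile and the outcome."""
    config = config or CohortConfig()
    out = stays.copy()
    cmap = _charlson.load_charlson_map()
    scores = np.asarray(_charlson.batch_scores(out["icd10_codes"], cmap))
    out["charlson_score"] = scores
    out["charlson_band"] = [_charlson.categorize_charlson(int(s)) for s in scores]
    out["age_band"] = age_band(out["age"])
    fdep = out["municipality_id"].map(geo.municipalities.set_index("municipality_id")["fdep"])
    out["fdep"] = fdep
    t1, t2 = np.quantile(fdep.to_numpy(dtype=float), [1 / 3, 2 / 3])
    out["fdep_category"] = np.select(
        [fdep <= t1, fdep <= t2], [FDEP_LEVELS[0], FDEP_LEVELS[1]], default=FDEP_LEVELS[2]
    )
    out["death30"] = derive_outcome(out, config)
    return out


def derive_hospital_covariates(
    cohort: pd.DataFrame, geo: Geography, config: CohortConfig | None = None
) -> pd.DataFrame:
    """Per-hospital caseload band, status and recruitment-area density.

    The density score of a hospital is the admission-weighted mean of
    its patients' municipal densities; the four rurality bands are cut
    at quartiles computed over *patients*, so each holds ≈25% of the
    cohort (hospital counts per band may differ).
    """
    config = config or CohortConfig()
    if cohort.empty:
        raise ValueError("cohort is empty")
    counts = cohort["hospital_id"].value_counts()
    caseload = counts / config.study_years
    b1, b2 = config.caseload_breaks
    caseload_cat = pd.Series(
        np.select([caseload <= b1, caseload <= b2], CASELOAD_LEVELS[:2], default=CASELOAD_LEVELS[2]),
        index=caseload.index,
    )
    dens = cohort["municipality_id"].map(
        geo.municipalities.set_index("municipality_id")["density"]
    )
    score = dens.groupby(cohort["hospital_id"]).mean()
    per_patient = cohort["hospital_id"].map(score).to_numpy(dtype=float)
    q1, q2, q3 = np.quantile(per_patient, [0.25, 0.5, 0.75])
    density_cat = pd.Series(
        np.select(
            [score <= q1, score <= q2, score <= q3],
            DENSITY_LEVELS[:3],
            default=DENSITY_LEVELS[3],
        ),
        index=score.index,
    )
    status = geo.hospitals.set_index("hospital_id")["status"].reindex(score.index)
    return pd.DataFrame(
        {
            "caseload": caseload.reindex(score.index),
            "caseload_category": caseload_cat.reindex(score.index),
            "status": status,
            "density_score": score,
            "density_category": density_cat,
        }
    ).rename_axis("hospital_id")


def prepare_analysis_table(
    stays: pd.DataFrame, geo: Geography, config: CohortConfig | None = None
) -> tuple[pd.DataFrame, FilterLog, pd.DataFrame]:
    """Filters + patient and hospital covariates, ready for modelling.

    Returns ``(analysis_table, filter_log, hospital_table)``; the
    analysis table still lacks the competition category, which depends
    on the market stage.
    """
    config = config or CohortConfig()
    cohort, log = apply_inclusion_filters(stays, geo, config)
    if cohort.empty:
        return cohort, log, pd.DataFrame()
    cohort = derive_patient_covariates(cohort, geo, config)
    hosp = derive_hospital_covariates(cohort, geo, config)
    cohort = cohort.merge(
        hosp[["caseload_category", "status", "density_category"]],
        left_on="hospital_id",
        right_index=True,
        how="left",
    )
    return cohort, log, hosp
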