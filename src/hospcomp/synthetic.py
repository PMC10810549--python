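"""Synthetic hospital-claims data with known ground truth.

Emulates a national surgical-claims extract for colorectal-cancer
resections so the whole analysis pipeline — cohort filters, Charlson
scoring, market delimitation, competition indices, mixed-model fit —
can be exercised and validated without any confidential data.

The generative process, stage by stage (each stage draws from its own
substream of one global seed):

1. *Geography* — municipalities scattered over a mainland-France-sized
   lat/lon box (plus a small overseas box to exercise the residence
   filter). Population density decays exponentially with distance to a
   set of urban centres, giving spatially clustered densities;
   hospitals are placed preferentially in dense municipalities and a
   small fraction are teaching hospitals with an attractiveness bonus.
2. *Admissions* — each patient draws a residence municipality with
   probability proportional to population, then a hospital under a
   gravity model: P(hospital) ∝ exp(attractiveness − decay · distance).
   Patient covariates are drawn to match the descriptive margins of a
   large colorectal-cancer cohort (mean age ≈ 70, ≈ 44% female,
   Charlson bands ≈ 75/13/12, emergency ≈ 10%), with an age–comorbidity
   positive association and independence otherwise.
3. *Outcomes* — 30-day death is Bernoulli with
   logit p = baseline + Σ β·x + u_hospital, u ~ N(0, σ²); the death day
   is uniform on 0..30 after surgery.

Ground truth (β, σ, flows) is recorded in the config, so parameter
recovery by the downstream model is directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import charlson as _charlson
from .market import haversine_km

__all__ = [
    "SimulationConfig",
    "Geography",
    "default_true_beta",
    "generate_geography",
    "generate_admissions",
    "simulate_outcomes",
    "write_dataset",
    "load_dataset",
]

STUDY_START = pd.Timestamp("2015-01-01")

AGE_BANDS = ("<=60", "61-70", "71-80", "81-90", ">90")
PROCEDURES = (
    "right_colectomy",
    "left_colectomy",
    "rectosigmoid_resection",
    "rectal_resection",
    "multiple_resection",
    "other",
)
PROCEDURE_PROBS = (0.337, 0.231, 0.226, 0.071, 0.087, 0.048)
CANCER_CODES = ("C18", "C19", "C20")
CANCER_PROBS = (0.70, 0.12, 0.18)

# mainland and overseas bounding boxes (lat_min, lat_max, lon_min, lon_max)
_MAINLAND_BOX = (42.5, 51.0, -4.5, 8.0)
_OVERSEAS_BOX = (14.5, 16.5, -61.8, -60.8)

# stage tags for seed substreams
_STAGE = {"geography": 0, "admissions": 1, "outcomes": 2}


def default_true_beta() -> dict[str, float]:
    """Ground-truth log-odds coefficients for the outcome model.

    Values are logs of the adjusted odds ratios of a published national
    colorectal-cancer analysis, so simulated data carry realistic effect
    sizes (e.g. highly-competitive market OR 0.69, emergency OR 2.93).
    Keys follow the ``covariate[level]`` naming of the fitted design.
    """
    ors = {
        "competition_category[slightly]": 1.02,
        "competition_category[moderately]": 0.88,
        "competition_category[highly]": 0.69,
        "age_band[61-70]": 1.37,
        "age_band[71-80]": 1.86,
        "age_band[81-90]": 3.63,
        "age_band[>90]": 6.42,
        "sex[male]": 1.36,
        "charlson_band[3-4]": 1.30,
        "charlson_band[>4]": 2.43,
        "malnutrition": 1.42,
        "emergency": 2.93,
        "neoadjuvant": 1.23,
        "procedure[left_colectomy]": 0.86,
        "procedure[rectosigmoid_resection]": 0.84,
        "procedure[rectal_resection]": 0.67,
        "procedure[multiple_resection]": 1.08,
        "procedure[other]": 1.55,
    }
    return {k: float(np.log(v)) for k, v in ors.items()}


@dataclass(frozen=True)
class SimulationConfig:
    n_municipalities: int = 5000
    n_hospitals: int = 726
    n_patients: int = 30_000
    study_years: int = 5
    gravity_decay: float = 0.08  # km^-1; flow half-distance ~ 9 km
    hospital_attractiveness_sd: float = 0.5
    true_beta: dict[str, float] = field(default_factory=default_true_beta)
    random_intercept_sd: float = 0.3
    baseline_logit: float = -4.555  # calibrated: marginal mortality ~3.6% under defaults
    overseas_fraction: float = 0.02
    include_index_cancer: bool = True
    n_urban_centers: int = 25
    teaching_fraction: float = 0.084
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_municipalities", "n_hospitals", "n_patients", "study_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        if self.gravity_decay < 0:
            raise ValueError("gravity_decay must be >= 0")
        if self.hospital_attractiveness_sd < 0:
            raise ValueError("hospital_attractiveness_sd must be >= 0")


@dataclass(frozen=True)
class Geography:
    """Synthetic gazetteer: municipalities and hospitals."""

    municipalities: pd.DataFrame  # municipality_id, lat, lon, population, density, fdep, region
    hospitals: pd.DataFrame  # hospital_id, lat, lon, status, attractiveness, municipality_id, region


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STAGE[stage]]))


def _uniform_box(rng, n, box):
    lat = rng.uniform(box[0], box[1], n)
    lon = rng.uniform(box[2], box[3], n)
    return lat, lon


def generate_geography(config: SimulationConfig) -> Geography:
    """Municipality gazetteer plus hospital registry, fully synthetic.

    Density: log-density = 3 + 4.5·exp(−d_centre/20 km) + N(0, 0.7²)
    with d_centre the distance to the nearest urban centre — rural
    plateaus near e³ ≈ 20 and city cores near e⁷·⁵ ≈ 1800 inhab/km²,
    with well separated quartiles. Hospitals are drawn without
    replacement with probability ∝ density, so hospital presence tracks
    urbanisation.
    """
    rng = _rng(config, "geography")
    n = config.n_municipalities
    n_over = int(round(config.overseas_fraction * n))
    n_main = n - n_over

    lat_m, lon_m = _uniform_box(rng, n_main, _MAINLAND_BOX)
    lat_o, lon_o = _uniform_box(rng, n_over, _OVERSEAS_BOX)
    lat = np.concatenate([lat_m, lat_o])
    lon = np.concatenate([lon_m, lon_o])
    region = np.array(["mainland"] * n_main + ["overseas"] * n_over)

    c_lat, c_lon = _uniform_box(rng, config.n_urban_centers, _MAINLAND_BOX)
    if n_over:
        c_lat = np.append(c_lat, _OVERSEAS_BOX[0] + 1.0)
        c_lon = np.append(c_lon, _OVERSEAS_BOX[2] + 0.5)
    d_center = haversine_km(
        lat[:, None], lon[:, None], c_lat[None, :], c_lon[None, :]
    ).min(axis=1)
    log_density = 3.0 + 4.5 * np.exp(-d_center / 20.0) + rng.normal(0.0, 0.7, n)
    density = np.exp(log_density)
    area_km2 = np.exp(rng.normal(2.6, 0.9, n))  # commune areas, median ~13 km2
    population = np.maximum(50, (density * area_km2).round()).astype(int)
    fdep = rng.normal(0.0, 1.0, n)

    municipalities = pd.DataFrame(
        {
            "municipality_id": [f"M{i:05d}" for i in range(n)],
            "lat": lat,
            "lon": lon,
            "population": population,
            "density": density,
            "fdep": fdep,
            "region": region,
        }
    )

    p = density / density.sum()
    # with replacement: dense municipalities (cities) can host several hospitals
    host_idx = rng.choice(n, size=config.n_hospitals, replace=True, p=p)
    host = municipalities.iloc[host_idx].reset_index(drop=True)
    teaching = rng.random(config.n_hospitals) < config.teaching_fraction
    attractiveness = rng.normal(0.0, config.hospital_attractiveness_sd, config.n_hospitals)
    attractiveness = attractiveness + 0.5 * teaching  # teaching hospitals recruit wider
    hospitals = pd.DataFrame(
        {
            "hospital_id": [f"H{i:04d}" for i in range(config.n_hospitals)],
            "lat": host["lat"] + rng.normal(0.0, 0.005, config.n_hospitals),
            "lon": host["lon"] + rng.normal(0.0, 0.005, config.n_hospitals),
            "status": np.where(teaching, "teaching", "non_teaching"),
            "attractiveness": attractiveness,
            "municipality_id": host["municipality_id"],
            "region": host["region"],
        }
    )
    return Geography(municipalities=municipalities, hospitals=hospitals)


# ---------------------------------------------------------------------------
# admissions

# Charlson condition pools used to hit the 75/13/12 band mix. One
# representative ICD-10 code (a prefix of the Quan table) is emitted per
# condition; the scoring module recovers the intended band exactly.
_W1_POOL = (
    ("myocardial_infarction", "I21"),
    ("congestive_heart_failure", "I50"),
    ("peripheral_vascular_disease", "I70"),
    ("cerebrovascular_disease", "I63"),
    ("dementia", "F03"),
    ("chronic_pulmonary_disease", "J44"),
    ("rheumatic_disease", "M05"),
    ("peptic_ulcer_disease", "K25"),
    ("mild_liver_disease", "K74"),
    ("diabetes_without_complications", "E119"),
)
_W2_POOL = (
    ("diabetes_with_complications", "E112"),
    ("hemiplegia_paraplegia", "G81"),
    ("renal_disease", "N18"),
)
_METASTATIC_CODE = "C78"

# Charlson band probabilities by age group; the age gradient averages to
# the target 75/13/12 mix under the Normal(70.4, 12.2) age distribution.
_BAND_PROBS_BY_AGE = (
    (65.0, (0.850, 0.090, 0.060)),
    (75.0, (0.760, 0.130, 0.110)),
    (np.inf, (0.648, 0.167, 0.185)),
)


def _draw_comorbidity_codes(rng, band: int) -> list[str]:
    """Extra ICD-10 codes so that the total Charlson score (with the
    index cancer contributing weight 2) falls in the requested band."""
    if band == 0:  # score 2 (malignancy only)
        return []
    if band == 1:  # score 3-4
        u = rng.random()
        if u < 0.5:
            picks = rng.choice(len(_W1_POOL), size=1, replace=False)
            return [_W1_POOL[i][1] for i in picks]
        if u < 0.8:
            picks = rng.choice(len(_W1_POOL), size=2, replace=False)
            return [_W1_POOL[i][1] for i in picks]
        return [_W2_POOL[rng.integers(len(_W2_POOL))][1]]
    # band 2: score > 4; mostly metastatic disease (2 -> 6 via hierarchy)
    if rng.random() < 0.75:
        codes = [_METASTATIC_CODE]
        if rng.random() < 0.5:
            codes.append(_W1_POOL[rng.integers(len(_W1_POOL))][1])
        return codes
    picks = rng.choice(len(_W1_POOL), size=2, replace=False)
    w2 = _W2_POOL[rng.integers(len(_W2_POOL))][1]
    return [_W1_POOL[i][1] for i in picks] + [w2]  # 2 + 1 + 1 + 2 >= 5


def generate_admissions(geo: Geography, config: SimulationConfig) -> pd.DataFrame:
    """One row per surgical stay; death columns left empty.

    Residence ∝ municipal population; hospital choice by the gravity
    model P ∝ exp(attractiveness − gravity_decay · distance).
    """
    if geo.hospitals.empty:
        raise ValueError("geography has no hospitals")
    if geo.municipalities.empty:
        raise ValueError("geography has no municipalities")
    rng = _rng(config, "admissions")
    n = config.n_patients
    munis = geo.municipalities.reset_index(drop=True)
    hosps = geo.hospitals.reset_index(drop=True)

    pop = munis["population"].to_numpy(dtype=float)
    res_idx = rng.choice(len(munis), size=n, p=pop / pop.sum())

    D = haversine_km(
        munis["lat"].to_numpy()[:, None],
        munis["lon"].to_numpy()[:, None],
        hosps["lat"].to_numpy()[None, :],
        hosps["lon"].to_numpy()[None, :],
    )
    logits = hosps["attractiveness"].to_numpy()[None, :] - config.gravity_decay * D
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)

    hosp_idx = np.empty(n, dtype=int)
    for m in np.unique(res_idx):
        mask = res_idx == m
        hosp_idx[mask] = rng.choice(len(hosps), size=int(mask.sum()), p=probs[m])

    age = np.clip(rng.normal(70.4, 12.2, n), 18.0, 105.0)
    sex = np.where(rng.random(n) < 0.444, "female", "male")
    obesity = rng.random(n) < 0.124
    malnutrition = rng.random(n) < 0.217
    emergency = rng.random(n) < 0.103
    neoadjuvant = rng.random(n) < 0.123
    proc_p = np.asarray(PROCEDURE_PROBS) / np.sum(PROCEDURE_PROBS)
    procedure = rng.choice(PROCEDURES, size=n, p=proc_p)
    cancer = rng.choice(CANCER_CODES, size=n, p=CANCER_PROBS)
    surgery_offset = rng.integers(0, config.study_years * 365, n)
    surgery_date = STUDY_START + pd.to_timedelta(surgery_offset, unit="D")

    # age-graded Charlson band, then concrete comorbidity codes
    band = np.empty(n, dtype=int)
    u = rng.random(n)
    prev = -np.inf
    for hi, p3 in _BAND_PROBS_BY_AGE:
        mask = (age > prev) & (age <= hi)
        band[mask] = np.searchsorted(np.cumsum(p3), u[mask], side="right")
        prev = hi
    band = np.clip(band, 0, 2)

    codes: list[list[str]] = []
    for i in range(n):
        extra = _draw_comorbidity_codes(rng, int(band[i]))
        if config.include_index_cancer:
            extra = [cancer[i] + "0"] + extra
        codes.append(extra)

    stays = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "hospital_id": hosps["hospital_id"].to_numpy()[hosp_idx],
            "municipality_id": munis["municipality_id"].to_numpy()[res_idx],
            "surgery_date": surgery_date,
            "age": age,
            "sex": sex,
            "icd10_codes": codes,
            "cancer_code": cancer,
            "procedure": procedure,
            "emergency": emergency.astype(int),
            "obesity": obesity.astype(int),
            "malnutrition": malnutrition.astype(int),
            "neoadjuvant": neoadjuvant.astype(int),
            "death_date": pd.NaT,
        }
    )
    return stays


# ---------------------------------------------------------------------------
# outcomes


def age_band(age) -> np.ndarray:
    """Band ages as <=60 / 61-70 / 71-80 / 81-90 / >90."""
    age = np.asarray(age, dtype=float)
    idx = np.digitize(age, [60.0, 70.0, 80.0, 90.0], right=True)
    return np.asarray(AGE_BANDS)[idx]


def outcome_features(
    stays: pd.DataFrame, competition_category_by_hospital: dict[str, str]
) -> pd.DataFrame:
    """Binary feature columns named ``covariate[level]`` for the outcome model."""
    cmap = _charlson.load_charlson_map()
    scores = np.asarray(_charlson.batch_scores(stays["icd10_codes"], cmap))
    bands = np.array([_charlson.categorize_charlson(int(s)) for s in scores])
    cat = stays["hospital_id"].map(competition_category_by_hospital)
    if cat.isna().any():
        missing = sorted(stays.loc[cat.isna(), "hospital_id"].unique())
        raise ValueError(f"no competition category for hospitals: {missing[:5]}")
    feats = {}
    for lv in ("slightly", "moderately", "highly"):
        feats[f"competition_category[{lv}]"] = (cat == lv).to_numpy(dtype=float)
    ab = age_band(stays["age"])
    for lv in AGE_BANDS[1:]:
        feats[f"age_band[{lv}]"] = (ab == lv).astype(float)
    feats["sex[male]"] = (stays["sex"] == "male").to_numpy(dtype=float)
    for lv in ("3-4", ">4"):
        feats[f"charlson_band[{lv}]"] = (bands == lv).astype(float)
    for name in ("malnutrition", "emergency", "neoadjuvant"):
        feats[name] = stays[name].to_numpy(dtype=float)
    for lv in PROCEDURES[1:]:
        feats[f"procedure[{lv}]"] = (stays["procedure"] == lv).to_numpy(dtype=float)
    return pd.DataFrame(feats, index=stays.index)


def _validate_true_beta(true_beta: dict[str, float], feats: pd.DataFrame) -> None:
    """A covariate either has no coefficients at all (null effect) or a
    coefficient for every one of its levels present in the data."""
    known = set(feats.columns)
    unknown = set(true_beta) - known
    if unknown:
        raise ValueError(f"unknown coefficient name(s): {sorted(unknown)}")
    covariate = lambda name: name.split("[")[0]
    keyed = {covariate(k) for k in true_beta}
    for col in feats.columns:
        if covariate(col) in keyed and col not in true_beta and feats[col].any():
            raise ValueError(f"missing coefficient for present covariate level {col!r}")


def simulate_outcomes(
    stays: pd.DataFrame,
    competition_category_by_hospital: dict[str, str],
    config: SimulationConfig,
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fill ``death_date`` from the random-intercept logistic truth.

    One intercept per hospital is drawn from N(0, σ²); each stay dies
    with probability expit(baseline + Σ β·x + u) and, if so, on a day
    uniform on 0..30 after surgery. ``features`` may carry the output
    of :func:`outcome_features` to avoid recomputing it across
    replicate draws; it must correspond to ``stays``.
    """
    rng = _rng(config, "outcomes")
    feats = (
        features
        if features is not None
        else outcome_features(stays, competition_category_by_hospital)
    )
    _validate_true_beta(config.true_beta, feats)
    eta = np.full(len(stays), config.baseline_logit, dtype=float)
    for name, b in config.true_beta.items():
        eta += b * feats[name].to_numpy()

    hospital_ids = np.sort(stays["hospital_id"].unique())
    u = dict(zip(hospital_ids, rng.normal(0.0, config.random_intercept_sd, len(hospital_ids))))
    eta += stays["hospital_id"].map(u).to_numpy()

    p = expit(eta)
    dies = rng.random(len(stays)) < p
    day = rng.integers(0, 31, len(stays))  # uniform on 0..30 inclusive
    out = stays.copy()
    death = pd.Series(pd.NaT, index=stays.index, dtype="datetime64[ns]")
    death[dies] = pd.to_datetime(out.loc[dies, "surgery_date"]) + pd.to_timedelta(
        day[dies], unit="D"
    )
    out["death_date"] = death
    return out


# ---------------------------------------------------------------------------
# CSV interface


def write_dataset(geo: Geography, stays: pd.DataFrame, outdir: str | Path) -> None:
    """Write municipalities.csv / hospitals.csv / stays.csv (ISO dates,
    ICD-10 codes ';'-joined)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geo.municipalities.to_csv(outdir / "municipalities.csv", index=False)
    geo.hospitals.to_csv(outdir / "hospitals.csv", index=False)
    flat = stays.copy()
    flat["icd10_codes"] = [";".join(c) for c in flat["icd10_codes"]]
    flat["surgery_date"] = pd.to_datetime(flat["surgery_date"]).dt.strftime("%Y-%m-%d")
    dd = pd.to_datetime(flat["death_date"])
    flat["death_date"] = dd.dt.strftime("%Y-%m-%d").where(dd.notna(), "")
    flat.to_csv(outdir / "stays.csv", index=False)


def load_dataset(indir: str | Path) -> tuple[Geography, pd.DataFrame]:
    """Inverse of :func:`write_dataset`."""
    indir = Path(indir)
    municipalities = pd.read_csv(indir / "municipalities.csv")
    hospitals = pd.read_csv(indir / "hospitals.csv")
    stays = pd.read_csv(indir / "stays.csv", keep_default_na=False, na_values=[])
    stays["icd10_codes"] = [c.split(";") if c else [] for c in stays["icd10_codes"]]
    stays["surgery_date"] = pd.to_datetime(stays["surgery_date"])
    stays["death_date"] = pd.to_datetime(stays["death_date"].replace("", pd.NaT))
    for col in ("emergency", "obesity", "malnutrition", "neoadjuvant"):
        stays[col] = stays[col].astype(int)
    stays["age"] = stays["age"].astype(float)
    return Geography(municipalities=municipalities, hospitals=hospitals), stays
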