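"""End-to-end pipeline: data -> cohort -> markets -> competition -> model.

`run_pipeline` sequences the analysis on either a simulated dataset or
CSV inputs, writes every intermediate table plus descriptive outputs
(a patient-characteristics table, a hospital/market-characteristics
table, odds-ratio tables for both competition measures) and a manifest
with the seed and a config hash so runs are reproducible.

The main analysis measures competition as the number of competitors in
the 30-km radius market; the sensitivity analysis uses the HHI on the
patient-flow market. Hospitals whose market cannot be delimited carry
an NA competition level and are excluded from the corresponding model
fit, never silently imputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import competition as _comp
from . import market as _market
from .cohort import CohortConfig, prepare_analysis_table
from .glmm import ModelSpec, build_design, fit_random_intercept_logistic
from .market import MarketConfig
from .synthetic import (
    Geography,
    SimulationConfig,
    generate_admissions,
    generate_geography,
    load_dataset,
    simulate_outcomes,
)

__all__ = ["PipelineConfig", "run_pipeline", "competition_table", "ground_truth_categories"]

logger = logging.getLogger("hospcomp")


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    market: MarketConfig = field(default_factory=MarketConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    outdir: str = "results/pipeline"
    fit_models: bool = True

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("provide exactly one of simulation config or input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.get("simulation")
        return cls(
            simulation=SimulationConfig(**sim) if sim is not None else None,
            input_dir=raw.get("input_dir"),
            cohort=CohortConfig(**raw.get("cohort", {})),
            market=MarketConfig(**raw.get("market", {})),
            outdir=raw.get("outdir", "results/pipeline"),
            fit_models=raw.get("fit_models", True),
        )

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""

        def enc(o):
            if dataclasses.is_dataclass(o):
                return {
                    f.name: enc(getattr(o, f.name))
                    for f in dataclasses.fields(o)
                    if f.name != "outdir"
                }
            if isinstance(o, (frozenset, set)):
                return sorted(o)
            if isinstance(o, (tuple, list)):
                return [enc(x) for x in o]
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            return o

        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def competition_table(
    cohort: pd.DataFrame, geo: Geography, config: MarketConfig | None = None
) -> pd.DataFrame:
    """Both competition indices and their quartile levels, per hospital.

    Undefined markets yield NaN indices and NA categories (the hospital
    stays in the table so descriptive outputs can report the NA row).
    """
    config = config or MarketConfig()
    hospital_ids = np.sort(cohort["hospital_id"].unique())
    n_comp: dict[str, float] = {}
    hhi_val: dict[str, float] = {}
    for hid in hospital_ids:
        rmkt = _market.radius_market(hid, geo.municipalities, geo.hospitals, config)
        comp = _market.competitors_in_radius(
            hid, geo.municipalities, geo.hospitals, cohort, config, focal_market=rmkt
        )
        n_comp[hid] = np.nan if comp is None else float(len(comp))
        fmkt = _market.patient_flow_market(hid, cohort, config)
        if fmkt.defined:
            hhi_val[hid] = _comp.hhi(_comp.market_shares(fmkt, cohort))
        else:
            hhi_val[hid] = np.nan
    out = pd.DataFrame(
        {
            "n_competitors": pd.Series(n_comp),
            "hhi": pd.Series(hhi_val),
        }
    ).rename_axis("hospital_id")
    out["category_ncomp"] = _comp.categorize_by_quartiles(
        out["n_competitors"], "higher_is_more_competitive"
    )
    out["category_hhi"] = _comp.categorize_by_quartiles(out["hhi"], "lower_is_more_competitive")
    return out


def ground_truth_categories(
    stays: pd.DataFrame, geo: Geography, config: MarketConfig | None = None
) -> dict[str, str]:
    """Competition level per hospital used as simulation ground truth.

    Computed on the full admission flows with the main (radius) method;
    hospitals with an undefined market are treated as non-competitive
    for outcome generation.
    """
    table = competition_table(stays, geo, config)
    cat = table["category_ncomp"].fillna("non")
    return dict(cat)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle under ``outdir``.

    Returns a dict with the in-memory products (cohort, competition
    table, fits, manifest). Raises on the first failing stage, naming
    it, after writing a partial manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.simulation.seed if config.simulation else None,
        "stages": {},
    }
    products: dict = {"manifest": manifest}
    t0 = time.perf_counter()

    def stage(name, fn):
        try:
            t = time.perf_counter()
            res = fn()
            manifest["stages"][name] = round(time.perf_counter() - t, 3)
            logger.info("stage %s done in %.2fs", name, manifest["stages"][name])
            return res
        except Exception as exc:
            manifest["stages"][name] = f"FAILED: {exc}"
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    def _data():
        if config.simulation is not None:
            geo = generate_geography(config.simulation)
            stays = generate_admissions(geo, config.simulation)
            truth = ground_truth_categories(stays, geo, config.market)
            stays = simulate_outcomes(stays, truth, config.simulation)
            manifest["mode"] = "simulation"
            manifest["true_categories_n"] = pd.Series(truth).value_counts().to_dict()
        else:
            geo, stays = load_dataset(config.input_dir)
            manifest["mode"] = "csv"
        return geo, stays

    geo, stays = stage("data", _data)
    geo.municipalities.to_csv(outdir / "municipalities.csv", index=False)
    geo.hospitals.to_csv(outdir / "hospitals.csv", index=False)

    analysis, flog, hosp = stage(
        "cohort", lambda: prepare_analysis_table(stays, geo, config.cohort)
    )
    flog.to_json(outdir / "filter_log.json")
    (outdir / "flowchart.txt").write_text(flog.to_text())
    manifest["cohort_size"] = int(len(analysis))

    comp = stage("competition", lambda: competition_table(analysis, geo, config.market))
    comp.to_csv(outdir / "competition.csv")
    analysis = analysis.merge(
        comp[["n_competitors", "hhi", "category_ncomp", "category_hhi"]],
        left_on="hospital_id",
        right_index=True,
        how="left",
    )
    flat = analysis.copy()
    flat["icd10_codes"] = [";".join(c) for c in flat["icd10_codes"]]
    flat.to_csv(outdir / "cohort.csv", index=False)

    def _tables():
        t1 = patient_table(analysis)
        t2 = hospital_table(analysis, comp, hosp)
        t1.to_csv(outdir / "table_patients.csv", index=False)
        t2.to_csv(outdir / "table_hospitals.csv", index=False)
        return t1, t2

    table1, table2 = stage("tables", _tables)

    fits = {}
    if config.fit_models:
        for label, cat_col in (("ncomp", "category_ncomp"), ("hhi", "category_hhi")):

            def _do_fit(cat_col=cat_col):
                sub = analysis.dropna(subset=[cat_col]).copy()
                sub["competition_category"] = sub[cat_col]
                X, y, groups, names = build_design(sub, config.model)
                return fit_random_intercept_logistic(X, y, groups, names)

            fit = stage(f"fit_{label}", _do_fit)
            fits[label] = fit
            fit.or_table.to_csv(outdir / f"or_table_{label}.csv", index=False)
            (outdir / f"model_{label}.txt").write_text(fit.summary())

    manifest["runtime_s"] = round(time.perf_counter() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    products.update(
        {
            "geo": geo,
            "stays": stays,
            "analysis": analysis,
            "filter_log": flog,
            "hospitals": hosp,
            "competition": comp,
            "fits": fits,
            "table_patients": table1,
            "table_hospitals": table2,
        }
    )
    return products


# ---------------------------------------------------------------------------
# descriptive tables


def _pct(x) -> float:
    return round(100.0 * float(np.mean(x)), 1)


def patient_table(analysis: pd.DataFrame) -> pd.DataFrame:
    """Cohort descriptives in the layout of a baseline table."""
    n = len(analysis)
    rows = [("N", "", n, "")]
    rows.append(("Gender", "female", int((analysis["sex"] == "female").sum()), _pct(analysis["sex"] == "female")))
    rows.append(("Age, mean (SD)", "", round(float(analysis["age"].mean()), 1), round(float(analysis["age"].std()), 1)))
    for band in ("0-2", "3-4", ">4"):
        m = analysis["charlson_band"] == band
        rows.append(("Charlson index", band, int(m.sum()), _pct(m)))
    for flag in ("obesity", "malnutrition", "emergency", "neoadjuvant"):
        rows.append((flag, "yes", int(analysis[flag].sum()), _pct(analysis[flag])))
    for proc in analysis["procedure"].value_counts().index:
        m = analysis["procedure"] == proc
        rows.append(("Surgical procedure", proc, int(m.sum()), _pct(m)))
    for cat in ("lower", "middle", "upper"):
        m = analysis["fdep_category"] == cat
        rows.append(("FDep", cat, int(m.sum()), _pct(m)))
    rows.append(("30-day mortality", "", int(analysis["death30"].sum()), _pct(analysis["death30"])))
    return pd.DataFrame(rows, columns=["covariate", "level", "n", "pct_or_sd"])


def hospital_table(
    analysis: pd.DataFrame, comp: pd.DataFrame, hosp: pd.DataFrame
) -> pd.DataFrame:
    """Hospital / market characteristics: hospitals and patients per level."""
    per_stay = analysis
    rows = []

    def block(name, hospital_series, stay_series, levels):
        for lv in levels:
            hm = hospital_series == lv
            sm = stay_series == lv
            rows.append((name, lv, int(hm.sum()), int(sm.sum())))
        n_na = int(hospital_series.isna().sum())
        if n_na:
            rows.append((name, "NA", n_na, int(stay_series.isna().sum())))

    block(
        "status",
        hosp["status"],
        per_stay["status"],
        ("teaching", "non_teaching"),
    )
    block("caseload_per_year", hosp["caseload_category"], per_stay["caseload_category"], ("<=50", "51-100", ">100"))
    block(
        "n_competitors",
        comp["category_ncomp"],
        per_stay["category_ncomp"],
        _comp.COMPETITION_LEVELS,
    )
    block("hhi", comp["category_hhi"], per_stay["category_hhi"], _comp.COMPETITION_LEVELS)
    block(
        "density_of_hospital_area",
        hosp["density_category"],
        per_stay["density_category"],
        ("very_rural", "rural", "urban", "very_urban"),
    )
    return pd.DataFrame(rows, columns=["covariate", "level", "n_hospitals", "n_patients"])
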