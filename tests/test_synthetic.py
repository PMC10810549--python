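"""Generator contracts: determinism, spatial structure, flows, calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import chisquare, spearmanr

from hospcomp.market import haversine_km
from hospcomp.synthetic import (
    SimulationConfig,
    generate_admissions,
    generate_geography,
    simulate_outcomes,
)


def test_zero_municipalities_is_configuration_error():
    with pytest.raises(ValueError):
        SimulationConfig(n_municipalities=0)


def test_negative_sigma_is_configuration_error():
    with pytest.raises(ValueError):
        SimulationConfig(random_intercept_sd=-0.1)


def test_same_seed_reproduces_geography_and_admissions():
    cfg = SimulationConfig(n_municipalities=300, n_hospitals=30, n_patients=500, seed=42)
    g1, g2 = generate_geography(cfg), generate_geography(cfg)
    pd.testing.assert_frame_equal(g1.municipalities, g2.municipalities)
    pd.testing.assert_frame_equal(g1.hospitals, g2.hospitals)
    s1 = generate_admissions(g1, cfg)
    s2 = generate_admissions(g2, cfg)
    pd.testing.assert_frame_equal(s1, s2)
    cats = {h: "non" for h in g1.hospitals["hospital_id"]}
    pd.testing.assert_frame_equal(
        simulate_outcomes(s1, cats, cfg), simulate_outcomes(s2, cats, cfg)
    )


def test_hospitals_cluster_where_density_is_high():
    # hospitals placed density-weighted in a spatially correlated density
    # field: municipal density and nearby-hospital count must co-vary
    cfg = SimulationConfig(n_hospitals=200, n_municipalities=2000, seed=1)
    geo = generate_geography(cfg)
    m, h = geo.municipalities, geo.hospitals
    d = haversine_km(
        m["lat"].to_numpy()[:, None],
        m["lon"].to_numpy()[:, None],
        h["lat"].to_numpy()[None, :],
        h["lon"].to_numpy()[None, :],
    )
    n_within_30 = (d <= 30.0).sum(axis=1)
    rho = spearmanr(m["density"], n_within_30).statistic
    assert rho > 0


def test_extreme_distance_decay_sends_everyone_to_nearest_hospital():
    cfg = SimulationConfig(
        n_municipalities=150,
        n_hospitals=8,
        n_patients=1500,
        gravity_decay=1000.0,
        hospital_attractiveness_sd=0.0,
        teaching_fraction=0.0,
        overseas_fraction=0.0,
        seed=5,
    )
    geo = generate_geography(cfg)
    stays = generate_admissions(geo, cfg)
    m = geo.municipalities.set_index("municipality_id")
    h = geo.hospitals
    d = haversine_km(
        m["lat"].to_numpy()[:, None],
        m["lon"].to_numpy()[:, None],
        h["lat"].to_numpy()[None, :],
        h["lon"].to_numpy()[None, :],
    )
    nearest = pd.Series(h["hospital_id"].to_numpy()[d.argmin(axis=1)], index=m.index)
    assert (stays["hospital_id"].to_numpy() == nearest[stays["municipality_id"]].to_numpy()).all()


def test_no_decay_equal_attractiveness_gives_uniform_hospital_choice():
    cfg = SimulationConfig(
        n_municipalities=100,
        n_hospitals=10,
        n_patients=10_000,
        gravity_decay=0.0,
        hospital_attractiveness_sd=0.0,
        teaching_fraction=0.0,
        overseas_fraction=0.0,
        seed=9,
    )
    geo = generate_geography(cfg)
    stays = generate_admissions(geo, cfg)
    counts = stays["hospital_id"].value_counts().reindex(geo.hospitals["hospital_id"], fill_value=0)
    res = chisquare(counts.to_numpy())
    assert res.pvalue > 0.01


def test_flow_mass_conservation(small_dataset):
    _, stays, _ = small_dataset
    assert stays.groupby("hospital_id").size().sum() == len(stays)


def test_admission_counts_decay_with_distance():
    # one residence cluster, hospitals strung out at growing distances:
    # with equal attractiveness the flow must fall off monotonically
    cfg = SimulationConfig(
        n_municipalities=1,
        n_hospitals=5,
        n_patients=20_000,
        gravity_decay=0.05,
        hospital_attractiveness_sd=0.0,
        teaching_fraction=0.0,
        overseas_fraction=0.0,
        seed=3,
    )
    geo = generate_geography(cfg)
    # rebuild hospital coordinates on a line at 5/10/20/40/80 km
    km_per_deg = 360.0 / (2 * np.pi * 6371.0)
    base = geo.municipalities.iloc[0]
    geo.hospitals["lat"] = base["lat"] + np.array([5, 10, 20, 40, 80]) * km_per_deg
    geo.hospitals["lon"] = base["lon"]
    stays = generate_admissions(geo, cfg)
    counts = stays["hospital_id"].value_counts().reindex(geo.hospitals["hospital_id"], fill_value=0)
    assert (np.diff(counts.to_numpy()) < 0).all()


def test_mean_age_matches_cohort_profile(small_config):
    cfg = dataclasses.replace(small_config, n_patients=30_000)
    geo = generate_geography(cfg)
    stays = generate_admissions(geo, cfg)
    assert stays["age"].mean() == pytest.approx(70.0, abs=1.0)
    assert (stays["sex"] == "female").mean() == pytest.approx(0.444, abs=0.02)


def test_charlson_band_mix_matches_cohort_profile(small_dataset):
    _, stays, _ = small_dataset
    from hospcomp.charlson import batch_scores, categorize_charlson, load_charlson_map

    cmap = load_charlson_map()
    bands = pd.Series(
        [categorize_charlson(s) for s in batch_scores(stays["icd10_codes"], cmap)]
    ).value_counts(normalize=True)
    assert bands["0-2"] == pytest.approx(0.75, abs=0.03)
    assert bands["3-4"] == pytest.approx(0.13, abs=0.03)
    assert bands[">4"] == pytest.approx(0.12, abs=0.03)


def test_null_model_death_rate_matches_baseline():
    # all betas zero, sigma zero: empirical mortality must sit at the
    # inverse-logit of the baseline (3.6%) up to binomial error
    cfg = SimulationConfig(
        n_municipalities=500,
        n_hospitals=50,
        n_patients=200_000,
        true_beta={},
        random_intercept_sd=0.0,
        baseline_logit=float(logit(0.036)),
        seed=17,
    )
    geo = generate_geography(cfg)
    stays = generate_admissions(geo, cfg)
    cats = {h: "non" for h in geo.hospitals["hospital_id"]}
    out = simulate_outcomes(stays, cats, cfg)
    rate = out["death_date"].notna().mean()
    assert rate * 100 == pytest.approx(3.6, abs=0.3)


def test_impossible_death_probability_gives_zero_deaths():
    cfg = SimulationConfig(
        n_municipalities=50,
        n_hospitals=5,
        n_patients=2000,
        true_beta={},
        random_intercept_sd=0.0,
        baseline_logit=-1e9,
        seed=2,
    )
    geo = generate_geography(cfg)
    stays = generate_admissions(geo, cfg)
    cats = {h: "non" for h in geo.hospitals["hospital_id"]}
    out = simulate_outcomes(stays, cats, cfg)
    assert out["death_date"].isna().all()


def test_competition_effect_reproduced_in_two_by_two_margins():
    # half the hospitals highly competitive with log(0.69) effect and no
    # other terms: the crude OR from the simulated margins recovers 0.69
    true_or = 0.69
    cfg = SimulationConfig(
        n_municipalities=1000,
        n_hospitals=100,
        n_patients=300_000,
        true_beta={"competition_category[highly]": float(np.log(true_or))},
        random_intercept_sd=0.0,
        baseline_logit=float(logit(0.044)),
        seed=23,
    )
    geo = generate_geography(cfg)
    stays = generate_admissions(geo, cfg)
    hosp_ids = geo.hospitals["hospital_id"].tolist()
    cats = {h: ("highly" if i % 2 == 0 else "non") for i, h in enumerate(hosp_ids)}
    out = simulate_outcomes(stays, cats, cfg)
    cat = out["hospital_id"].map(cats)
    dead = out["death_date"].notna()
    d_h, s_h = dead[cat == "highly"].sum(), (~dead[cat == "highly"]).sum()
    d_n, s_n = dead[cat == "non"].sum(), (~dead[cat == "non"]).sum()
    or_hat = (d_h / s_h) / (d_n / s_n)
    assert 0.6 <= or_hat <= 0.8


def test_death_dates_never_precede_surgery(small_dataset):
    _, stays, _ = small_dataset
    died = stays["death_date"].notna()
    delta = (stays.loc[died, "death_date"] - stays.loc[died, "surgery_date"]).dt.days
    assert (delta >= 0).all() and (delta <= 30).all()


def test_missing_coefficient_for_present_level_is_config_error():
    cfg = SimulationConfig(
        n_municipalities=50,
        n_hospitals=5,
        n_patients=200,
        true_beta={"competition_category[highly]": 0.1},
        seed=4,
    )
    geo = generate_geography(cfg)
    stays = generate_admissions(geo, cfg)
    cats = {h: "slightly" for h in geo.hospitals["hospital_id"]}  # level not keyed
    with pytest.raises(ValueError, match="missing coefficient"):
        simulate_outcomes(stays, cats, cfg)


def test_unknown_coefficient_name_is_config_error():
    with pytest.raises(ValueError, match="unknown coefficient"):
        cfg = SimulationConfig(
            n_municipalities=50,
            n_hospitals=5,
            n_patients=100,
            true_beta={"not_a_feature": 1.0},
            seed=4,
        )
        geo = generate_geography(cfg)
        stays = generate_admissions(geo, cfg)
        simulate_outcomes(stays, {h: "non" for h in geo.hospitals["hospital_id"]}, cfg)
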