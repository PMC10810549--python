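import numpy as np
import pandas as pd
import pytest

from hospcomp.report import ground_truth_categories
from hospcomp.synthetic import (
    SimulationConfig,
    generate_admissions,
    generate_geography,
    simulate_outcomes,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study conditions shared across tests."""
    return SimulationConfig(
        n_municipalities=800, n_hospitals=120, n_patients=6000, seed=1234
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(geo, stays with outcomes, truth categories) for the small config."""
    geo = generate_geography(small_config)
    stays = generate_admissions(geo, small_config)
    truth = ground_truth_categories(stays, geo)
    stays = simulate_outcomes(stays, truth, small_config)
    return geo, stays, truth


def toy_geography(munis, hospitals):
    """Build a Geography from (id, lat, lon) tuples; densities constant."""
    from hospcomp.synthetic import Geography

    mdf = pd.DataFrame(munis, columns=["municipality_id", "lat", "lon"])
    mdf["population"] = 1000
    mdf["density"] = 100.0
    mdf["fdep"] = 0.0
    mdf["region"] = "mainland"
    hdf = pd.DataFrame(hospitals, columns=["hospital_id", "lat", "lon"])
    hdf["status"] = "non_teaching"
    hdf["attractiveness"] = 0.0
    hdf["municipality_id"] = mdf["municipality_id"].iloc[0]
    hdf["region"] = "mainland"
    return Geography(municipalities=mdf, hospitals=hdf)


def toy_stays(rows):
    """Stays from (patient, hospital, municipality) triples, filled defaults."""
    df = pd.DataFrame(rows, columns=["patient_id", "hospital_id", "municipality_id"])
    n = len(df)
    df["surgery_date"] = pd.Timestamp("2016-06-01")
    df["age"] = 70.0
    df["sex"] = "female"
    df["icd10_codes"] = [[] for _ in range(n)]
    df["cancer_code"] = "C18"
    df["procedure"] = "right_colectomy"
    df["emergency"] = 0
    df["obesity"] = 0
    df["malnutrition"] = 0
    df["neoadjuvant"] = 0
    df["death_date"] = pd.NaT
    return df
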