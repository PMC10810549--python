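"""Market delimitation: distances, radius markets, competitors, patient flow."""

import numpy as np
import pandas as pd
import pytest

from conftest import toy_geography, toy_stays
from hospcomp.market import (
    EARTH_RADIUS_KM,
    MarketConfig,
    competitors_in_radius,
    haversine_km,
    patient_flow_market,
    radius_market,
)

KM_PER_DEG_LAT = 360.0 / (2.0 * np.pi * EARTH_RADIUS_KM)  # degrees per km


def lat_offset(km: float) -> float:
    """Degrees of latitude subtending `km` along a meridian."""
    return km * KM_PER_DEG_LAT


# ---------------------------------------------------------------------------
# haversine


def test_haversine_zero_and_symmetry():
    assert haversine_km(45.0, 3.0, 45.0, 3.0) == 0.0
    a = haversine_km(48.0, 2.0, 44.0, 5.0)
    b = haversine_km(44.0, 5.0, 48.0, 2.0)
    assert a == pytest.approx(b, abs=1e-12)


def test_haversine_one_degree_equator():
    # one degree of arc on a 6371-km sphere: 2*pi*R/360
    assert haversine_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(111.19, abs=0.01)


def test_haversine_matches_spherical_law_of_cosines():
    # independent oracle on the Paris-Lyon pair
    lat1, lon1, lat2, lon2 = 48.8566, 2.3522, 45.7640, 4.8357
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    oracle = EARTH_RADIUS_KM * np.arccos(
        np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    )
    assert haversine_km(lat1, lon1, lat2, lon2) == pytest.approx(oracle, abs=1e-6)
    assert haversine_km(lat1, lon1, lat2, lon2) == pytest.approx(392.0, abs=1.0)


@pytest.mark.parametrize("bad", [(91.0, 0.0), (-95.0, 10.0)])
def test_haversine_rejects_bad_latitude(bad):
    with pytest.raises(ValueError):
        haversine_km(bad[0], bad[1], 0.0, 0.0)


def test_haversine_rejects_bad_longitude():
    with pytest.raises(ValueError):
        haversine_km(0.0, 181.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# radius market


def _line_geo(distances_km, hospital=("H1", 46.0, 2.0)):
    munis = [
        (f"M{i}", hospital[1] + lat_offset(d), hospital[2])
        for i, d in enumerate(distances_km)
    ]
    return toy_geography(munis, [hospital])


def test_radius_market_toy_grid():
    geo = _line_geo([10, 20, 29, 31, 50])
    mkt = radius_market("H1", geo.municipalities, geo.hospitals)
    assert mkt.municipality_ids == {"M0", "M1", "M2"}


def test_radius_market_boundary_inclusive():
    geo = _line_geo([30.0])
    mkt = radius_market("H1", geo.municipalities, geo.hospitals)
    assert mkt.municipality_ids == {"M0"}


def test_radius_market_empty_is_undefined():
    geo = _line_geo([40, 80])
    mkt = radius_market("H1", geo.municipalities, geo.hospitals)
    assert not mkt.defined


def test_radius_market_monotone_in_radius(small_dataset):
    geo, _, _ = small_dataset
    hid = geo.hospitals["hospital_id"].iloc[0]
    prev = frozenset()
    for r in (10.0, 20.0, 30.0, 60.0):
        mkt = radius_market(hid, geo.municipalities, geo.hospitals, MarketConfig(radius_km=r))
        assert prev <= mkt.municipality_ids
        prev = mkt.municipality_ids


# ---------------------------------------------------------------------------
# competitors


def _competitor_setup():
    """Focal F plus three in-disk hospitals with area shares 0.5%/1%/20%,
    one out-of-disk hospital, one focal-market municipality M0 and one
    far municipality MF supplying the rest of each hospital's volume."""
    lat0, lon0 = 46.0, 2.0
    munis = [("M0", lat0 + lat_offset(5), lon0), ("MF", lat0 + lat_offset(500), lon0)]
    hospitals = [
        ("F", lat0, lon0),
        ("A", lat0 + lat_offset(10), lon0),  # 1/200 = 0.5% -> out
        ("B", lat0 + lat_offset(12), lon0),  # 1/100 = 1%  -> in (inclusive)
        ("C", lat0 + lat_offset(15), lon0),  # 2/10 = 20%  -> in
        ("X", lat0 + lat_offset(200), lon0),  # outside the disk
    ]
    geo = toy_geography(munis, hospitals)
    rows = [("pF", "F", "M0")]
    rows += [("pA0", "A", "M0")] + [(f"pA{i}", "A", "MF") for i in range(1, 200)]
    rows += [("pB0", "B", "M0")] + [(f"pB{i}", "B", "MF") for i in range(1, 100)]
    rows += [("pC0", "C", "M0"), ("pC1", "C", "M0")] + [
        (f"pC{i}", "C", "MF") for i in range(2, 10)
    ]
    rows += [(f"pX{i}", "X", "M0") for i in range(50)]  # recruits heavily but too far
    return geo, toy_stays(rows)


def test_competitor_share_rule_and_location_rule():
    geo, stays = _competitor_setup()
    comp = competitors_in_radius("F", geo.municipalities, geo.hospitals, stays)
    assert comp == {"B", "C"}


def test_competitors_undefined_when_no_recruitment_area():
    geo = _line_geo([45, 60])
    stays = toy_stays([("p0", "H1", "M0")])
    assert competitors_in_radius("H1", geo.municipalities, geo.hospitals, stays) is None


def test_competitors_shrink_with_higher_share_threshold():
    geo, stays = _competitor_setup()
    strict = MarketConfig(competitor_min_share=0.05)
    comp = competitors_in_radius("F", geo.municipalities, geo.hospitals, stays, strict)
    assert comp == {"C"}


# ---------------------------------------------------------------------------
# patient-flow market


def _flow_stays(counts: dict[str, int], hospital="H1"):
    rows = []
    for muni, n in counts.items():
        rows += [(f"p{muni}{i}", hospital, muni) for i in range(n)]
    return toy_stays(rows)


def test_flow_market_single_municipality():
    stays = _flow_stays({"M0": 10})
    mkt = patient_flow_market("H1", stays)
    assert mkt.defined and mkt.municipality_ids == {"M0"}


def test_flow_market_share_rule_extends_cumulative_prefix():
    # ranked shares 0.35/0.25/0.15/0.10/0.08/0.04/0.03: the prefix rule
    # stops after two, the 3% share rule pulls in all seven
    counts = {"M0": 35, "M1": 25, "M2": 15, "M3": 10, "M4": 8, "M5": 4, "M6": 3}
    mkt = patient_flow_market("H1", _flow_stays(counts))
    assert mkt.municipality_ids == set(counts)


def test_flow_market_cumulative_rule_with_long_tail():
    # one 39% municipality plus thirty ~2% ones: share rule keeps only the
    # head; the 40% cumulative rule adds exactly one more, tie-broken by id
    counts = {"M00": 39}
    counts.update({f"M{i:02d}": 2 for i in range(1, 31)})
    mkt = patient_flow_market("H1", _flow_stays(counts))
    assert mkt.municipality_ids == {"M00", "M01"}


def test_flow_market_drops_singleton_municipalities():
    counts = {"M0": 6, "M1": 1, "M2": 1}
    mkt = patient_flow_market("H1", _flow_stays(counts))
    assert mkt.municipality_ids == {"M0"}
    assert mkt.admissions_by_municipality == {"M0": 6}


def test_flow_market_all_singletons_is_undefined():
    counts = {f"M{i}": 1 for i in range(5)}
    mkt = patient_flow_market("H1", _flow_stays(counts))
    assert not mkt.defined


def test_flow_market_reaches_cumulative_share(small_dataset):
    _, stays, _ = small_dataset
    cfg = MarketConfig()
    counts_all = stays.groupby("hospital_id").size()
    for hid in counts_all[counts_all >= 30].index[:20]:
        mkt = patient_flow_market(hid, stays, cfg)
        if not mkt.defined:
            continue
        kept = stays[stays["hospital_id"] == hid].groupby("municipality_id").size()
        kept = kept[kept >= cfg.min_patients_per_municipality]
        share = sum(mkt.admissions_by_municipality.values()) / kept.sum()
        assert share >= cfg.flow_cum_share
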