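"""Hospital market delimitation.

Two delimitation methods are provided, mirroring the two standard
approaches in the hospital-competition literature:

* fixed radius — the market of a hospital is every municipality whose
  centroid lies within ``radius_km`` (default 30 km) of the hospital;
  competitors are the other hospitals located inside that disk that
  recruit at least ``competitor_min_share`` (default 1%) of their own
  admissions from it;
* patient flow — the market is the set of municipalities sending at
  least ``flow_min_share`` (default 3%) of the hospital's admissions,
  united with the smallest top-ranked group of municipalities jointly
  providing ``flow_cum_share`` (default 40%) of cumulative admissions,
  after discarding municipalities contributing fewer than
  ``min_patients_per_municipality`` (default 2) patients.

All thresholds are inclusive (``>=``). Distances are great-circle
kilometres on a 6371-km sphere. A hospital whose market cannot be
delimited (no municipality in the disk; every municipality a singleton)
yields an *undefined* market, which downstream stages report as NA and
exclude from modelling rather than erroring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarketConfig",
    "Market",
    "haversine_km",
    "radius_market",
    "competitors_in_radius",
    "patient_flow_market",
    "admissions_by_municipality",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class MarketConfig:
    radius_km: float = 30.0
    competitor_min_share: float = 0.01
    flow_min_share: float = 0.03
    flow_cum_share: float = 0.40
    min_patients_per_municipality: int = 2

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")
        for name in ("competitor_min_share", "flow_min_share", "flow_cum_share"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class Market:
    """A delimited hospital market.

    ``defined`` is False when the method could not delimit a market
    (e.g. empty 30-km disk, or only single-patient municipalities);
    such hospitals carry an undefined competition level downstream.
    """

    hospital_id: str
    method: str  # "radius" | "patient_flow"
    municipality_ids: frozenset[str]
    admissions_by_municipality: dict[str, int] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return len(self.municipality_ids) > 0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km; accepts scalars or numpy arrays."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude out of [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180.0):
            raise ValueError("longitude out of [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _hospital_row(hospitals: pd.DataFrame, hospital_id: str) -> pd.Series:
    rows = hospitals.loc[hospitals["hospital_id"] == hospital_id]
    if rows.empty:
        raise KeyError(f"unknown hospital {hospital_id!r}")
    row = rows.iloc[0]
    if pd.isna(row["lat"]) or pd.isna(row["lon"]):
        raise ValueError(f"hospital {hospital_id!r} has no coordinates")
    return row


def radius_market(
    hospital_id: str,
    municipalities: pd.DataFrame,
    hospitals: pd.DataFrame,
    config: MarketConfig | None = None,
) -> Market:
    """Municipalities whose centroid lies within ``radius_km`` (inclusive)."""
    config = config or MarketConfig()
    h = _hospital_row(hospitals, hospital_id)
    d = haversine_km(h["lat"], h["lon"], municipalities["lat"].to_numpy(), municipalities["lon"].to_numpy())
    inside = municipalities.loc[d <= config.radius_km, "municipality_id"]
    return Market(hospital_id=hospital_id, method="radius", municipality_ids=frozenset(inside))


def admissions_by_municipality(stays: pd.DataFrame, hospital_id: str) -> pd.Series:
    """Count a hospital's admissions per municipality of residence."""
    sub = stays.loc[stays["hospital_id"] == hospital_id]
    return sub.groupby("municipality_id").size().sort_values(ascending=False)


def competitors_in_radius(
    focal_hospital_id: str,
    municipalities: pd.DataFrame,
    hospitals: pd.DataFrame,
    stays: pd.DataFrame,
    config: MarketConfig | None = None,
    focal_market: Market | None = None,
) -> set[str] | None:
    """Competitor set of a hospital under the fixed-radius method.

    A hospital ``h != focal`` is a competitor when (i) it is located
    inside the focal disk and (ii) its admissions originating from the
    focal market's municipalities make up at least
    ``competitor_min_share`` of its own total admissions.

    Returns ``None`` (undefined competition) when the focal market is
    empty — the hospital recruits nowhere within the radius.
    """
    config = config or MarketConfig()
    if focal_market is None:
        focal_market = radius_market(focal_hospital_id, municipalities, hospitals, config)
    if not focal_market.defined:
        return None
    focal = _hospital_row(hospitals, focal_hospital_id)
    others = hospitals.loc[hospitals["hospital_id"] != focal_hospital_id]
    d = haversine_km(focal["lat"], focal["lon"], others["lat"].to_numpy(), others["lon"].to_numpy())
    in_disk = others.loc[d <= config.radius_km, "hospital_id"]

    competitors: set[str] = set()
    market_munis = focal_market.municipality_ids
    totals = stays.groupby("hospital_id").size()
    in_market = stays.loc[stays["municipality_id"].isin(market_munis)].groupby("hospital_id").size()
    for hid in in_disk:
        total = int(totals.get(hid, 0))
        if total == 0:
            continue
        share = int(in_market.get(hid, 0)) / total
        if share >= config.competitor_min_share:
            competitors.add(hid)
    return competitors


def patient_flow_market(
    hospital_id: str,
    stays: pd.DataFrame,
    config: MarketConfig | None = None,
) -> Market:
    """Delimit a market from the hospital's own patient flows.

    Municipalities providing fewer than ``min_patients_per_municipality``
    patients are dropped first (occasional recruitment); shares are then
    computed on the remaining admissions. The market is the union of the
    share rule (share >= ``flow_min_share``) and the cumulative rule
    (shortest descending-share prefix reaching ``flow_cum_share``).
    Ties in the ranking are broken by municipality id.
    """
    config = config or MarketConfig()
    counts = admissions_by_municipality(stays, hospital_id)
    if counts.empty:
        raise ValueError(f"hospital {hospital_id!r} has no admissions")
    counts = counts[counts >= config.min_patients_per_municipality]
    if counts.empty:
        # all municipalities were singletons: market undefined
        return Market(hospital_id=hospital_id, method="patient_flow", municipality_ids=frozenset())
    # deterministic ranking: descending count, then municipality id
    ranked = counts.reset_index(name="n").sort_values(
        ["n", "municipality_id"], ascending=[False, True]
    )
    shares = ranked["n"].to_numpy() / ranked["n"].sum()
    by_share = shares >= config.flow_min_share
    cum = np.cumsum(shares)
    k = int(np.searchsorted(cum, config.flow_cum_share)) + 1  # smallest prefix with cum >= threshold
    selected = by_share.copy()
    selected[:k] = True
    munis = frozenset(ranked.loc[selected, "municipality_id"])
    admissions = dict(
        zip(ranked.loc[selected, "municipality_id"], ranked.loc[selected, "n"].astype(int))
    )
    return Market(
        hospital_id=hospital_id,
        method="patient_flow",
        municipality_ids=munis,
        admissions_by_municipality=admissions,
    )
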