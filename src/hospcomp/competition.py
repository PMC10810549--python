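"""Competition indices over delimited hospital markets.

Two indices are computed, one per delimitation method:

* number of competitors in the 30-km radius market (main analysis);
* Herfindahl–Hirschman index (HHI) on the patient-flow market
  (sensitivity analysis): the sum of squared market shares of every
  hospital recruiting in the market's municipalities. HHI is 1 for a
  monopoly and 1/n for n equal competitors; the lower the HHI, the
  higher the competition.

Hospitals are then banded into four competition levels at the quartiles
of the index distribution over hospitals: non / slightly / moderately /
highly competitive. For competitor counts a higher value means more
competition; for HHI a lower value does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .market import Market

__all__ = [
    "CompetitionMeasure",
    "COMPETITION_LEVELS",
    "market_shares",
    "hhi",
    "categorize_by_quartiles",
]

#: Ordered from least to most competitive.
COMPETITION_LEVELS = ("non", "slightly", "moderately", "highly")


@dataclass(frozen=True)
class CompetitionMeasure:
    hospital_id: str
    n_competitors: int | None = None
    hhi: float | None = None
    category_ncomp: str | None = None
    category_hhi: str | None = None


def market_shares(market: Market, stays: pd.DataFrame) -> pd.Series:
    """Market share of every hospital recruiting in a market.

    Shares are each hospital's admissions originating from the market's
    municipalities divided by all admissions from those municipalities;
    they sum to one. Raises when the market is undefined or attracts no
    admissions at all.
    """
    if not market.defined:
        raise ValueError(f"market of {market.hospital_id!r} is undefined")
    sub = stays.loc[stays["municipality_id"].isin(market.municipality_ids)]
    if sub.empty:
        raise ValueError(f"no admissions originate from the market of {market.hospital_id!r}")
    counts = sub.groupby("hospital_id").size().sort_index()
    return counts / counts.sum()


def hhi(shares) -> float:
    """Herfindahl–Hirschman index: sum of squared market shares."""
    s = np.asarray(shares, dtype=float)
    if abs(s.sum() - 1.0) > 1e-9:
        raise ValueError(f"shares must sum to 1, got {s.sum()!r}")
    if np.any(s < 0):
        raise ValueError("shares must be non-negative")
    return float(np.sum(s**2))


def categorize_by_quartiles(
    values: pd.Series,
    direction: str = "higher_is_more_competitive",
) -> pd.Series:
    """Band hospitals into four competition levels at index quartiles.

    ``values`` is indexed by hospital id; NaN entries (undefined
    markets) stay NaN and are reported as NA downstream. Cut points are
    the 25/50/75 percentiles over hospitals with a defined value; ties
    at a cut point fall to the lower-competition side. With heavily tied
    discrete values (competitor counts) the four groups are legitimately
    unequal; with a continuous index (HHI) they are near-quarters.
    """
    if direction not in ("higher_is_more_competitive", "lower_is_more_competitive"):
        raise ValueError(f"unknown direction {direction!r}")
    defined = values.dropna()
    if len(defined) < 4:
        raise ValueError("need at least 4 hospitals with a defined index")
    v = defined.to_numpy(dtype=float)
    if direction == "lower_is_more_competitive":
        v = -v
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    out = pd.Series(pd.NA, index=values.index, dtype="object")
    if q1 == q3:
        warnings.warn("degenerate index distribution: all hospitals in one band", stacklevel=2)
        out[defined.index] = COMPETITION_LEVELS[0]
        return out
    cat = np.select(
        [v <= q1, v <= q2, v <= q3],
        [COMPETITION_LEVELS[0], COMPETITION_LEVELS[1], COMPETITION_LEVELS[2]],
        default=COMPETITION_LEVELS[3],
    )
    out[defined.index] = cat
    return out
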