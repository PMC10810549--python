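"""Charlson comorbidity index from ICD-10 diagnosis lists.

Implements the Quan et al. (2005) ICD-10 coding algorithm for the 17
Charlson condition groups with the original Charlson weights (1/2/3/6).
A condition is present when any diagnosis code, normalised to uppercase
with dots stripped, starts with one of the condition's code prefixes.
Hierarchy rules retain only the severe member of a pair when both are
coded (complicated diabetes over uncomplicated, metastatic cancer over
localised malignancy, moderate/severe over mild liver disease).

The mapping ships as an editable CSV resource
(``data/quan_charlson_icd10.csv``); :func:`load_charlson_map` reads it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "CharlsonMap",
    "load_charlson_map",
    "normalize_code",
    "map_codes_to_conditions",
    "charlson_score",
    "categorize_charlson",
    "CHARLSON_BANDS",
]

#: Score bands used for descriptive tables and as model covariate levels.
CHARLSON_BANDS = ("0-2", "3-4", ">4")


@dataclass(frozen=True)
class CharlsonMap:
    """Condition -> (prefixes, weight) table plus severity hierarchy.

    Attributes
    ----------
    conditions : dict
        condition name -> tuple of ICD-10 prefixes (uppercase, undotted).
    weights : dict
        condition name -> integer weight (>= 1).
    hierarchy : dict
        mild condition -> severe condition that supersedes it.
    """

    conditions: dict[str, tuple[str, ...]]
    weights: dict[str, int]
    hierarchy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mild, severe in self.hierarchy.items():
            if mild not in self.conditions or severe not in self.conditions:
                raise ValueError(
                    f"hierarchy pair ({mild!r}, {severe!r}) references an undefined condition"
                )
        for name, w in self.weights.items():
            if w < 1:
                raise ValueError(f"weight for {name!r} must be >= 1, got {w}")
        for name, prefixes in self.conditions.items():
            for p in prefixes:
                if p != p.upper() or "." in p:
                    raise ValueError(f"prefix {p!r} of {name!r} must be uppercase and undotted")


def load_charlson_map() -> CharlsonMap:
    """Load the packaged Quan-2005 ICD-10 mapping with original weights."""
    conditions: dict[str, tuple[str, ...]] = {}
    weights: dict[str, int] = {}
    hierarchy: dict[str, str] = {}
    ref = resources.files("hospcomp").joinpath("data/quan_charlson_icd10.csv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            name = row["condition"]
            conditions[name] = tuple(row["icd10_prefixes"].split(";"))
            weights[name] = int(row["weight"])
            if row["superseded_by"]:
                hierarchy[name] = row["superseded_by"]
    return CharlsonMap(conditions=conditions, weights=weights, hierarchy=hierarchy)


def normalize_code(code: str) -> str:
    """Normalise an ICD-10 code: strip dots and whitespace, uppercase."""
    return code.replace(".", "").strip().upper()


def map_codes_to_conditions(codes: list[str] | tuple[str, ...], cmap: CharlsonMap) -> set[str]:
    """Return the set of Charlson conditions coded in ``codes``.

    Unmatched codes are ignored. When both members of a hierarchy pair
    are present only the severe one is retained.
    """
    norm = [normalize_code(c) for c in codes]
    present: set[str] = set()
    for name, prefixes in cmap.conditions.items():
        if any(c.startswith(p) for c in norm for p in prefixes):
            present.add(name)
    for mild, severe in cmap.hierarchy.items():
        if mild in present and severe in present:
            present.discard(mild)
    return present


def charlson_score(conditions: set[str], cmap: CharlsonMap) -> int:
    """Sum of weights of the retained conditions."""
    unknown = conditions - cmap.conditions.keys()
    if unknown:
        raise KeyError(f"unknown Charlson condition(s): {sorted(unknown)}")
    return sum(cmap.weights[c] for c in conditions)


def score_codes(codes: list[str] | tuple[str, ...], cmap: CharlsonMap) -> int:
    """Convenience: codes -> conditions (with hierarchy) -> score."""
    return charlson_score(map_codes_to_conditions(codes, cmap), cmap)


def batch_scores(code_lists, cmap: CharlsonMap) -> list[int]:
    """Charlson scores for many code lists at once.

    Matches each distinct code against the prefix table once, then
    scores rows from the cached code -> conditions lookup; equivalent to
    calling :func:`score_codes` per row.
    """
    lookup: dict[str, frozenset[str]] = {}
    for codes in code_lists:
        for raw in codes:
            c = normalize_code(raw)
            if c not in lookup:
                lookup[c] = frozenset(
                    name
                    for name, prefixes in cmap.conditions.items()
                    if any(c.startswith(p) for p in prefixes)
                )
    scores = []
    for codes in code_lists:
        present: set[str] = set()
        for raw in codes:
            present |= lookup[normalize_code(raw)]
        for mild, severe in cmap.hierarchy.items():
            if mild in present and severe in present:
                present.discard(mild)
        scores.append(sum(cmap.weights[c] for c in present))
    return scores


def categorize_charlson(score: int) -> str:
    """Band a Charlson score as 0-2 / 3-4 / >4."""
    if score < 0:
        raise ValueError(f"Charlson score cannot be negative, got {score}")
    if score <= 2:
        return CHARLSON_BANDS[0]
    if score <= 4:
        return CHARLSON_BANDS[1]
    return CHARLSON_BANDS[2]
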