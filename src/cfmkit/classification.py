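"""Plausibility screening and the nine-way nutritional-status taxonomy.

A child with complete (HAZ, WAZ, WHZ) is assigned exactly one of nine
mutually exclusive categories: ``normal``, the four standalone forms of
malnutrition (SFM: stunting, wasting, underweight, overweight/obese), and
the four coexisting forms (CFM):

* CUW  -- underweight with wasting        (WAZ <= -2 and WHZ <= -2)
* CUS  -- underweight with stunting       (WAZ <= -2 and HAZ <= -2)
* CUWS -- underweight with wasting and stunting (all three <= -2)
* CSO  -- stunting with overweight/obesity (HAZ <= -2 and WAZ >= +2 and/or WHZ >= +2)

Deficit predicates use z <= -2.0 inclusive; the excess predicate uses
z >= +2.0 inclusive, so normal is the open band (-2, +2) on every index.

Combinations outside the underweight- and stunting-anchored taxonomy
(e.g. stunted + wasted but not underweight) still receive exactly one
category, by a fixed deficit-first precedence, and carry a conflict flag
so they can be tabulated separately.

Plausibility bounds (applied before classification): |HAZ| <= 6,
|WHZ| <= 5, and -6 <= WAZ <= +5, inclusive at the bound; values strictly
beyond are biologically implausible and the record is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .regions import map_country_region  # noqa: F401  (re-exported surface)

__all__ = [
    "CATEGORIES",
    "CFM_CATEGORIES",
    "SFM_CATEGORIES",
    "CONFLICT_FLAGS",
    "PlausibilityResult",
    "NutritionStatus",
    "IncompleteAnthropometryError",
    "plausibility_filter",
    "classify",
    "classify_frame",
    "derive_group_counts",
    "map_country_region",
]

CFM_CATEGORIES = ("CUW", "CUS", "CUWS", "CSO")
SFM_CATEGORIES = ("stunting", "wasting", "underweight", "overweight_obese")
CATEGORIES = ("normal",) + SFM_CATEGORIES + CFM_CATEGORIES

CONFLICT_FLAGS = (
    "none",
    "stunted_wasted_not_underweight",
    "underweight_with_overfeeding_pattern",
    "multiple_standalone",
)

DEFICIT_CUT = -2.0
EXCESS_CUT = 2.0

#: (index, lower, upper) inclusive plausibility bounds.
PLAUSIBILITY_BOUNDS = {
    "haz": (-6.0, 6.0),
    "whz": (-5.0, 5.0),
    "waz": (-6.0, 5.0),
}


class IncompleteAnthropometryError(ValueError):
    """A record with a missing index cannot enter the nine-way taxonomy."""


@dataclass
class PlausibilityResult:
    retained: bool
    violated_bounds: List[Tuple[str, float, Tuple[float, float]]] = field(default_factory=list)


@dataclass
class NutritionStatus:
    category: str
    malnourished: bool
    cfm: bool
    sfm: bool
    conflict_flag: str = "none"


def plausibility_filter(haz: float, waz: float, whz: float) -> PlausibilityResult:
    """Screen one z-score triple against the WHO outlier bounds.

    Missing (NaN/None) components impose no constraint.  Bounds are
    inclusive: exclusion requires a value strictly beyond the bound.
    """
    violations = []
    for name, value in (("haz", haz), ("waz", waz), ("whz", whz)):
        if value is None or not np.isfinite(value):
            continue
        lo, hi = PLAUSIBILITY_BOUNDS[name]
        if value < lo or value > hi:
            violations.append((name, float(value), (lo, hi)))
    return PlausibilityResult(retained=not violations, violated_bounds=violations)


def classify(haz: float, waz: float, whz: float) -> NutritionStatus:
    """Assign one child's z-score triple to its nutritional-status category.

    Requires all three indices present (raises
    :class:`IncompleteAnthropometryError` otherwise); callers handle
    missingness as a record disposition, mirroring the complete-anthropometry
    eligibility rule.  Resolution priority: CUWS, CUS, CUW, CSO, then the
    conflict-flagged and standalone cells, then normal.
    """
    vals = (haz, waz, whz)
    if any(v is None or not np.isfinite(v) for v in vals):
        raise IncompleteAnthropometryError(f"incomplete anthropometry: {vals}")

    stunted = haz <= DEFICIT_CUT
    wasted = whz <= DEFICIT_CUT
    under = waz <= DEFICIT_CUT
    over = (whz >= EXCESS_CUT) or (waz >= EXCESS_CUT)

    flag = "none"
    if under and stunted and wasted:
        cat = "CUWS"
    elif under and stunted:
        cat = "CUS"
        if over:  # WHZ >= +2 alongside WAZ <= -2: contradictory pattern
            flag = "underweight_with_overfeeding_pattern"
    elif under and wasted:
        cat = "CUW"
    elif stunted and over:
        cat = "CSO"
        if wasted:  # over via WAZ >= +2 while WHZ <= -2
            flag = "multiple_standalone"
    elif stunted and wasted:
        cat = "stunting"
        flag = "stunted_wasted_not_underweight"
    elif under and over:
        cat = "underweight"
        flag = "underweight_with_overfeeding_pattern"
    elif wasted and over:
        cat = "wasting"
        flag = "multiple_standalone"
    elif stunted:
        cat = "stunting"
    elif wasted:
        cat = "wasting"
    elif under:
        cat = "underweight"
    elif over:
        cat = "overweight_obese"
    else:
        cat = "normal"

    return NutritionStatus(
        category=cat,
        malnourished=cat != "normal",
        cfm=cat in CFM_CATEGORIES,
        sfm=cat != "normal" and cat not in CFM_CATEGORIES,
        conflict_flag=flag,
    )


def _classify_arrays(haz: np.ndarray, waz: np.ndarray, whz: np.ndarray):
    """Vectorised category + flag assignment; NaN-complete rows only."""
    stunted = haz <= DEFICIT_CUT
    wasted = whz <= DEFICIT_CUT
    under = waz <= DEFICIT_CUT
    over = (whz >= EXCESS_CUT) | (waz >= EXCESS_CUT)

    conds = [
        under & stunted & wasted,
        under & stunted,
        under & wasted,
        stunted & over,
        stunted & wasted,
        under & over,
        wasted & over,
        stunted,
        wasted,
        under,
        over,
    ]
    cats = [
        "CUWS", "CUS", "CUW", "CSO", "stunting", "underweight",
        "wasting", "stunting", "wasting", "underweight", "overweight_obese",
    ]
    category = np.select(conds, cats, default="normal")

    flag = np.full(haz.shape, "none", dtype=object)
    flag[under & stunted & ~wasted & over] = "underweight_with_overfeeding_pattern"
    flag[under & ~stunted & ~wasted & over] = "underweight_with_overfeeding_pattern"
    flag[stunted & over & wasted & ~under] = "multiple_standalone"
    flag[wasted & over & ~stunted & ~under] = "multiple_standalone"
    flag[stunted & wasted & ~under & ~over] = "stunted_wasted_not_underweight"
    return category, flag


def classify_frame(
    df: pd.DataFrame,
    haz: str = "haz",
    waz: str = "waz",
    whz: str = "whz",
) -> pd.DataFrame:
    """Classify every row of a z-score table.

    Returns a copy with ``retained`` (plausibility), ``disposition``
    (``analyzed`` / ``excluded_incomplete`` / ``excluded_outlier``),
    ``category``, ``conflict_flag``, ``malnourished``, ``cfm`` and ``sfm``
    columns.  Category columns are populated only for analyzed rows.
    """
    out = df.copy()
    h = pd.to_numeric(out[haz], errors="coerce").to_numpy(dtype=float)
    a = pd.to_numeric(out[waz], errors="coerce").to_numpy(dtype=float)
    w = pd.to_numeric(out[whz], errors="coerce").to_numpy(dtype=float)

    complete = np.isfinite(h) & np.isfinite(a) & np.isfinite(w)
    outlier = np.zeros(len(out), dtype=bool)
    for vals, name in ((h, "haz"), (a, "waz"), (w, "whz")):
        lo, hi = PLAUSIBILITY_BOUNDS[name]
        outlier |= np.isfinite(vals) & ((vals < lo) | (vals > hi))

    disposition = np.where(
        ~complete, "excluded_incomplete", np.where(outlier, "excluded_outlier", "analyzed")
    )
    analyzed = disposition == "analyzed"

    category = np.full(len(out), "", dtype=object)
    flag = np.full(len(out), "", dtype=object)
    if analyzed.any():
        category[analyzed], flag[analyzed] = _classify_arrays(h[analyzed], a[analyzed], w[analyzed])

    out["retained"] = ~outlier
    out["disposition"] = disposition
    out["category"] = category
    out["conflict_flag"] = flag
    out["malnourished"] = analyzed & (category != "normal")
    out["cfm"] = analyzed & np.isin(category, CFM_CATEGORIES)
    out["sfm"] = analyzed & np.isin(category, SFM_CATEGORIES)
    return out


def derive_group_counts(statuses: Iterable) -> Dict[str, int]:
    """Tally categories plus the malnourished/SFM/CFM totals.

    Accepts :class:`NutritionStatus` objects or category strings.  By
    construction malnourished = SFM + CFM and CFM = CUW + CUS + CUWS + CSO.
    """
    counts: Dict[str, int] = {c: 0 for c in CATEGORIES}
    for s in statuses:
        cat = s.category if isinstance(s, NutritionStatus) else str(s)
        if cat not in counts:
            raise ValueError(f"unknown category {cat!r}")
        counts[cat] += 1
    counts["cfm"] = sum(counts[c] for c in CFM_CATEGORIES)
    counts["sfm"] = sum(counts[c] for c in SFM_CATEGORIES)
    counts["malnourished"] = counts["cfm"] + counts["sfm"]
    counts["total"] = counts["malnourished"] + counts["normal"]
    return counts
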