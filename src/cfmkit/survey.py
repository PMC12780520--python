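"""Survey-weighted prevalence estimation at national, regional and global levels.

Point estimates are Horvitz-Thompson ratios, 100 * sum(w_i * 1[case_i]) /
sum(w_i).  Confidence intervals are Wilson score intervals (default; Wald
optional) evaluated on the Kish effective sample size n_eff = (sum w)^2 /
sum w^2, which discounts the nominal n for weight variation.  DHS-style
weights are only relatively scaled within a survey, so when countries are
pooled for regional/global estimates each country's weights are first
rescaled; the default ``sample_size`` pooling rescales them to sum to that
country's unweighted n, an optional ``population`` pooling accepts
user-supplied country population shares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .classification import CFM_CATEGORIES, SFM_CATEGORIES
from .regions import map_country_region

__all__ = [
    "PrevalenceEstimate",
    "OUTCOME_COLUMNS",
    "effective_sample_size",
    "proportion_ci",
    "weighted_prevalence",
    "aggregate",
    "validate_report",
]

#: Outcome columns of the standard prevalence report, in report order.
OUTCOME_COLUMNS = ("malnourished", "sfm", "cfm", "CUW", "CUS", "CUWS", "CSO")


@dataclass
class PrevalenceEstimate:
    level: str          # national | regional | global
    unit: str           # country name, region code, or "global"
    category: str
    point_pct: float
    ci_low_pct: float
    ci_high_pct: float
    n_unweighted: int
    n_weighted: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low_pct <= self.point_pct + 1e-9):
            raise ValueError("CI lower bound exceeds point estimate")
        if not (self.point_pct - 1e-9 <= self.ci_high_pct <= 100.0):
            raise ValueError("CI upper bound below point estimate or above 100")


def effective_sample_size(weights: Sequence[float]) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("effective_sample_size of empty weight list")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(w.sum() ** 2 / (w ** 2).sum())


def proportion_ci(p: float, n_eff: float, method: str = "wilson"):
    """95% CI for a proportion at effective sample size ``n_eff``.

    ``method`` is ``wilson`` (score interval, default) or ``wald`` (normal
    approximation); both clamped to [0, 1].
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"proportion {p} outside [0, 1]")
    if n_eff <= 0:
        raise ValueError("n_eff must be positive")
    if method == "wilson":
        lo, hi = proportion_confint(p * n_eff, n_eff, alpha=0.05, method="wilson")
    elif method == "wald":
        lo, hi = proportion_confint(p * n_eff, n_eff, alpha=0.05, method="normal")
    else:
        raise ValueError(f"unknown CI method {method!r}; use 'wilson' or 'wald'")
    lo = min(float(np.clip(lo, 0.0, 1.0)), p)
    hi = max(float(np.clip(hi, 0.0, 1.0)), p)
    return lo, hi


def weighted_prevalence(
    case: Sequence[bool],
    weights: Sequence[float],
    level: str = "national",
    unit: str = "",
    category: str = "",
    ci_method: str = "wilson",
) -> PrevalenceEstimate:
    """Horvitz-Thompson weighted prevalence of ``case`` with 95% CI."""
    case_arr = np.asarray(case, dtype=bool)
    w = np.asarray(weights, dtype=float)
    if case_arr.size == 0:
        raise ValueError(f"empty group for unit {unit!r}")
    if case_arr.shape != w.shape:
        raise ValueError("case and weights length mismatch")
    total_w = w.sum()
    if total_w <= 0:
        raise ValueError(f"zero total weight in unit {unit!r}")
    p = float((w * case_arr).sum() / total_w)
    n_eff = effective_sample_size(w)
    lo, hi = proportion_ci(p, n_eff, method=ci_method)
    # degenerate single-record groups: interval still clamped to [0, 100]
    lo = min(lo, p)
    hi = max(hi, p)
    return PrevalenceEstimate(
        level=level,
        unit=unit,
        category=category,
        point_pct=100.0 * p,
        ci_low_pct=100.0 * lo,
        ci_high_pct=100.0 * hi,
        n_unweighted=int(case_arr.size),
        n_weighted=float(total_w),
    )


def _outcome_flags(df: pd.DataFrame) -> pd.DataFrame:
    flags = pd.DataFrame(index=df.index)
    cat = df["category"]
    flags["malnourished"] = cat != "normal"
    flags["sfm"] = cat.isin(SFM_CATEGORIES)
    flags["cfm"] = cat.isin(CFM_CATEGORIES)
    for c in CFM_CATEGORIES + SFM_CATEGORIES + ("normal",):
        flags[c] = cat == c
    return flags


def _rescale_weights(df: pd.DataFrame, pooling: str, population_shares: Optional[Dict[str, float]]):
    """Per-country weight rescaling for pooled (regional/global) estimates."""
    w = df["weight"].to_numpy(dtype=float).copy()
    for country, idx in df.groupby("country").indices.items():
        sub = w[idx]
        if pooling == "sample_size":
            target = float(len(idx))
        elif pooling == "population":
            if not population_shares or country not in population_shares:
                raise ValueError(f"population pooling requires a share for {country!r}")
            target = float(population_shares[country])
        else:
            raise ValueError(f"unknown pooling rule {pooling!r}")
        w[idx] = sub * (target / sub.sum())
    return w


def aggregate(
    records: pd.DataFrame,
    levels: Iterable[str] = ("national", "regional", "global"),
    ci_method: str = "wilson",
    pooling: str = "sample_size",
    population_shares: Optional[Dict[str, float]] = None,
    categories: Sequence[str] = OUTCOME_COLUMNS,
) -> pd.DataFrame:
    """Prevalence report over the requested stratification levels.

    ``records`` must carry ``category``, ``weight`` and ``country`` columns
    (analyzed records only); a ``region`` column is derived from the
    country lookup when absent.  Returns one row per (level, unit,
    category) as a tidy DataFrame.
    """
    df = records.copy()
    required = {"category", "weight", "country"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if "region" not in df.columns:
        df["region"] = df["country"].map(map_country_region)

    flags = _outcome_flags(df)
    rows: List[PrevalenceEstimate] = []

    def emit(sub_idx, weights, level, unit):
        for category in categories:
            rows.append(
                weighted_prevalence(
                    flags.loc[sub_idx, category].to_numpy(),
                    weights,
                    level=level,
                    unit=unit,
                    category=category,
                    ci_method=ci_method,
                )
            )

    levels = list(levels)
    if "national" in levels:
        for country, sub in df.groupby("country", sort=True):
            emit(sub.index, sub["weight"].to_numpy(dtype=float), "national", str(country))
    if "regional" in levels or "global" in levels:
        pooled_w = pd.Series(_rescale_weights(df, pooling, population_shares), index=df.index)
        if "regional" in levels:
            for region, sub in df.groupby("region", sort=True):
                emit(sub.index, pooled_w.loc[sub.index].to_numpy(), "regional", str(region))
        if "global" in levels:
            emit(df.index, pooled_w.to_numpy(), "global", "global")

    return pd.DataFrame([vars(r) for r in rows])


def validate_report(table: pd.DataFrame, tol_pct: float = 1e-9) -> List[str]:
    """Check the additivity identities of a prevalence report.

    For every (level, unit): |malnourished - (SFM + CFM)| <= tol and
    |CFM - (CUW + CUS + CUWS + CSO)| <= tol, in percentage points.
    Returns a list of human-readable violations (empty when valid).
    """
    violations: List[str] = []
    wide = table.pivot_table(
        index=["level", "unit"], columns="category", values="point_pct", aggfunc="first"
    )
    def _ok(*vals):
        return all(v is not None and np.isfinite(v) for v in vals)

    for (level, unit), row in wide.iterrows():
        mal, sfm, cfm = row.get("malnourished"), row.get("sfm"), row.get("cfm")
        if _ok(mal, sfm, cfm):
            gap = abs(mal - (sfm + cfm))
            if gap > tol_pct:
                violations.append(
                    f"{level}/{unit}: malnourished {mal:.4f} != SFM+CFM {sfm + cfm:.4f} (gap {gap:.4f})"
                )
        parts = [row.get(c) for c in CFM_CATEGORIES]
        if _ok(cfm, *parts):
            gap = abs(cfm - sum(parts))
            if gap > tol_pct:
                violations.append(
                    f"{level}/{unit}: CFM {cfm:.4f} != sum of types {sum(parts):.4f} (gap {gap:.4f})"
                )
    return violations
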