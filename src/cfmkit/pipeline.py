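"""End-to-end pipeline: read -> (z-score) -> plausibility -> classify ->
prevalence -> (model).

Each stage logs its record counts; any stage failure aborts with a
diagnostic.  The pipeline consumes either precomputed z-scores or raw
measurements (scored through a supplied growth reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import models as assoc
from .classification import classify_frame
from .growth_reference import Measurement, ReferenceSet, compute_indices
from .survey import aggregate, validate_report

__all__ = ["PipelineConfig", "PipelineResult", "zscore_frame", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    levels: Sequence[str] = ("national", "regional", "global")
    ci_method: str = "wilson"
    stages: Sequence[str] = ("zscore", "classify", "prevalence")
    model_covariates: Sequence[str] = ()
    model_alpha: float = 0.05
    reference_levels: Optional[Dict[str, str]] = None


@dataclass
class PipelineResult:
    records: pd.DataFrame
    prevalence: Optional[pd.DataFrame] = None
    or_table: Optional[pd.DataFrame] = None
    models: Dict[str, object] = field(default_factory=dict)
    violations: List[str] = field(default_factory=list)
    stage_counts: Dict[str, int] = field(default_factory=dict)


def zscore_frame(df: pd.DataFrame, refs: ReferenceSet) -> pd.DataFrame:
    """Score raw measurements into haz/waz/whz columns (row-wise LMS engine)."""
    out = df.copy()
    haz = np.full(len(out), np.nan)
    waz = np.full(len(out), np.nan)
    whz = np.full(len(out), np.nan)
    ages = pd.to_numeric(out["age_months"], errors="coerce")
    weights = pd.to_numeric(out.get("weight_kg"), errors="coerce")
    statures = pd.to_numeric(out.get("length_or_height_cm", out.get("height_cm")), errors="coerce")
    recumbent = out.get("measured_recumbent")
    for i in range(len(out)):
        age = ages.iloc[i]
        if not np.isfinite(age) or not (0 <= age < 60):
            continue
        w = weights.iloc[i] if weights is not None else np.nan
        s = statures.iloc[i] if statures is not None else np.nan
        rec = None
        if recumbent is not None and pd.notna(recumbent.iloc[i]):
            rec = bool(recumbent.iloc[i])
        try:
            m = Measurement(
                age_months=float(age),
                sex=str(out["sex"].iloc[i]),
                weight_kg=float(w) if np.isfinite(w) else None,
                length_or_height_cm=float(s) if np.isfinite(s) else None,
                measured_recumbent=rec,
            )
        except ValueError:
            continue
        triple = compute_indices(m, refs)
        haz[i], waz[i], whz[i] = triple.haz, triple.waz, triple.whz
    out["haz"], out["waz"], out["whz"] = haz, waz, whz
    return out


def run_pipeline(
    records: pd.DataFrame,
    config: PipelineConfig,
    refs: Optional[ReferenceSet] = None,
) -> PipelineResult:
    """Execute the configured stages over canonical child records."""
    df = records.copy()
    counts = {"input": len(df)}

    if "zscore" in config.stages:
        has_measurements = {"weight_kg"} <= set(df.columns) and (
            "length_or_height_cm" in df.columns or "height_cm" in df.columns
        )
        if has_measurements:
            if refs is None:
                raise ValueError("zscore stage requires a growth reference")
            df = zscore_frame(df, refs)
            logger.info("zscore stage scored %d records", len(df))
        elif not {"haz", "waz", "whz"} <= set(df.columns):
            raise ValueError("no measurements or z-score columns available")

    classified = classify_frame(df)
    counts["analyzed"] = int((classified["disposition"] == "analyzed").sum())
    counts["excluded_incomplete"] = int((classified["disposition"] == "excluded_incomplete").sum())
    counts["excluded_outlier"] = int((classified["disposition"] == "excluded_outlier").sum())
    logger.info("classify stage: %s", counts)

    result = PipelineResult(records=classified, stage_counts=counts)

    analyzed = classified[classified["disposition"] == "analyzed"]
    if "prevalence" in config.stages:
        if analyzed.empty:
            raise ValueError("no analyzable records for prevalence stage")
        result.prevalence = aggregate(
            analyzed, levels=config.levels, ci_method=config.ci_method
        )
        result.violations = validate_report(result.prevalence)
        if result.violations:
            logger.warning("prevalence report violations: %s", result.violations)

    if "model" in config.stages and config.model_covariates:
        undernut = analyzed[analyzed["category"].isin(["underweight", "CUW", "CUS", "CUWS"])]
        stunted = analyzed[analyzed["category"].isin(["stunting", "CSO"])]
        fitted = {}
        if undernut["category"].nunique() >= 2:
            fitted["undernutrition"] = assoc.backward_eliminate(
                undernut, "category", list(config.model_covariates),
                ref_outcome="underweight", alpha=config.model_alpha,
                reference_levels=config.reference_levels,
            )
        if stunted["category"].nunique() == 2:
            fitted["cso"] = assoc.backward_eliminate(
                stunted, "category", list(config.model_covariates),
                ref_outcome="stunting", alpha=config.model_alpha,
                reference_levels=config.reference_levels,
            )
        result.models = fitted
        if fitted:
            result.or_table = assoc.or_table(fitted)
    return result
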