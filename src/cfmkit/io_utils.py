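"""Readers/writers for the pipeline's tabular formats.

Canonical interchange format is CSV.  Two dialects are understood:

* ``generic`` -- columns already on canonical scales (z-scores in SD
  units, weights on their natural scale, age in months);
* ``dhs_kr`` -- the DHS child-recode storage conventions: z-scores stored
  as integers x100 with flag codes >= 9990 meaning missing/implausible,
  sampling weights stored x1,000,000, age in completed months.

Every input row receives exactly one disposition (``analyzed``,
``excluded_incomplete``, ``excluded_outlier``, ``excluded_age``) so that
exclusions are auditable per run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ColumnMap",
    "DHS_KR_COLMAP",
    "read_children",
    "encode_dhs_kr",
    "write_reports",
]

logger = logging.getLogger(__name__)

DIALECTS = ("generic", "dhs_kr")

#: DHS flag codes at or above this value mean missing/implausible.
DHS_SENTINEL_MIN = 9990
DHS_Z_SCALE = 100.0
DHS_WEIGHT_SCALE = 1_000_000.0

CANONICAL_FIELDS = (
    "age_months", "sex", "weight_kg", "height_cm",
    "haz", "waz", "whz",
    "weight_raw", "cluster", "stratum", "country",
)


@dataclass
class ColumnMap:
    """Mapping from canonical field names to source column names.

    ``covariates`` lists additional categorical columns carried through
    unchanged.  Fields absent from the source are simply omitted from the
    mapping; which fields are required depends on the pipeline entry point
    (raw measurements need age/sex/weight/height, precomputed z-scores
    need haz/waz/whz).
    """

    mapping: Dict[str, str]
    dialect: str = "generic"
    covariates: tuple = ()

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        seen = {}
        for canon, src in self.mapping.items():
            if canon in seen:
                raise ValueError(f"duplicate canonical field {canon!r}")
            seen[canon] = src


#: Preset for the DHS child-recode variable conventions.
DHS_KR_COLMAP = ColumnMap(
    mapping={
        "age_months": "hw1",
        "haz": "hw70",
        "waz": "hw71",
        "whz": "hw72",
        "weight_raw": "v005",
        "cluster": "v001",
        "stratum": "v022",
        "country": "country",
        "sex": "b4",
    },
    dialect="dhs_kr",
)


def read_children(path, colmap: ColumnMap):
    """Read a children CSV and return (canonical DataFrame, dispositions).

    Applies the dialect decoding, the 0-59 months age filter, and emits a
    per-row disposition.  Unparseable numeric cells become missing values
    (a per-row matter), never a global failure; missing mapped columns
    raise immediately, listing them.
    """
    raw = pd.read_csv(path)
    missing_cols = [src for src in colmap.mapping.values() if src not in raw.columns]
    missing_cols += [c for c in colmap.covariates if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"input missing mapped columns: {missing_cols}")

    df = pd.DataFrame(index=raw.index)
    for canon, src in colmap.mapping.items():
        if canon == "sex":
            df[canon] = raw[src].astype(str).str.strip().str.lower().map(
                {"male": "male", "female": "female", "m": "male", "f": "female",
                 "1": "male", "2": "female"}
            )
        elif canon in ("cluster", "stratum", "country"):
            df[canon] = raw[src].astype(str)
        else:
            df[canon] = pd.to_numeric(raw[src], errors="coerce")
    for cov in colmap.covariates:
        df[cov] = raw[cov]

    if colmap.dialect == "dhs_kr":
        for z in ("haz", "waz", "whz"):
            if z in df.columns:
                vals = df[z].to_numpy(dtype=float)
                vals = np.where(np.abs(vals) >= DHS_SENTINEL_MIN, np.nan, vals / DHS_Z_SCALE)
                df[z] = vals
        if "weight_raw" in df.columns:
            df["weight"] = df["weight_raw"] / DHS_WEIGHT_SCALE
    elif "weight_raw" in df.columns:
        df["weight"] = df["weight_raw"]

    disposition = np.full(len(df), "analyzed", dtype=object)
    if "age_months" in df.columns:
        age = df["age_months"].to_numpy(dtype=float)
        out_of_age = np.isfinite(age) & ((age < 0) | (age >= 60))
        disposition[out_of_age] = "excluded_age"

    z_cols = [c for c in ("haz", "waz", "whz") if c in df.columns]
    meas_cols = [c for c in ("weight_kg", "height_cm") if c in df.columns]
    if z_cols and not meas_cols:
        no_index = df[z_cols].isna().all(axis=1).to_numpy()
        disposition[(disposition == "analyzed") & no_index] = "excluded_incomplete"

    dispositions = pd.DataFrame(
        {"record_id": df.index, "status": disposition}
    )
    logger.info(
        "read %d rows: %s", len(df),
        dispositions["status"].value_counts().to_dict(),
    )
    return df, dispositions


def encode_dhs_kr(df: pd.DataFrame) -> pd.DataFrame:
    """Encode canonical records into DHS child-recode storage conventions.

    Z-scores are rounded to integer x100 (the dialect's 0.01 SD storage
    resolution); missing values become the 9998 flag code; the sampling
    weight is stored x1,000,000.
    """
    out = pd.DataFrame(index=df.index)
    out["hw1"] = df["age_months"].round().astype(int) if "age_months" in df else 0
    for canon, src in (("hw70", "haz"), ("hw71", "waz"), ("hw72", "whz")):
        vals = df[src].to_numpy(dtype=float)
        coded = np.where(np.isfinite(vals), np.round(vals * DHS_Z_SCALE), 9998.0)
        out[canon] = coded.astype(int)
    out["v005"] = (df["weight"].to_numpy(dtype=float) * DHS_WEIGHT_SCALE).round().astype(int)
    out["v001"] = df["cluster"].astype(str) if "cluster" in df else "1"
    out["v022"] = df["stratum"].astype(str) if "stratum" in df else "1"
    out["country"] = df["country"].astype(str) if "country" in df else ""
    out["b4"] = df["sex"].astype(str) if "sex" in df else "male"
    return out


def write_reports(
    out_dir,
    prevalence: Optional[pd.DataFrame] = None,
    or_results: Optional[pd.DataFrame] = None,
    dispositions: Optional[pd.DataFrame] = None,
    summary: Optional[Mapping] = None,
) -> Dict[str, Path]:
    """Write report CSVs plus a JSON run summary with stable column order.

    Deterministic: identical inputs produce byte-identical files.
    Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    if prevalence is not None:
        p = out_dir / "prevalence.csv"
        cols = ["level", "unit", "category", "point_pct", "ci_low_pct",
                "ci_high_pct", "n_unweighted", "n_weighted"]
        prevalence.reindex(columns=cols).to_csv(p, index=False, float_format="%.6f")
        written["prevalence"] = p
    if or_results is not None:
        p = out_dir / "or_table.csv"
        cols = ["outcome", "covariate", "level", "or_value", "ci_low",
                "ci_high", "adjusted", "significant", "is_reference"]
        or_results.reindex(columns=cols).to_csv(p, index=False, float_format="%.6f")
        written["or_table"] = p
    if dispositions is not None:
        p = out_dir / "dispositions.csv"
        dispositions.to_csv(p, index=False)
        written["dispositions"] = p

    summary_obj = dict(summary or {})
    if dispositions is not None:
        counts = dispositions["status"].value_counts().to_dict()
        summary_obj["disposition_counts"] = {k: int(v) for k, v in sorted(counts.items())}
        summary_obj["n_input_rows"] = int(len(dispositions))
    p = out_dir / "run_summary.json"
    p.write_text(json.dumps(summary_obj, indent=2, sort_keys=True, default=str) + "\n")
    written["summary"] = p
    return written
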