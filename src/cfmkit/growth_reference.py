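"""WHO-style LMS growth-reference engine.

Converts raw child measurements (weight, length/height) into the three
anthropometric indices used throughout the package:

* HAZ/LAZ -- length/height-for-age z-score,
* WAZ     -- weight-for-age z-score,
* WHZ/WLZ -- weight-for-length/height z-score,

using the LMS parameterisation (Box-Cox power ``L``, median ``M``,
coefficient of variation ``S``) of the 2006 WHO child growth standards:

    z = ((y / M)**L - 1) / (L * S)        (L != 0)
    z = ln(y / M) / S                     (L -> 0 limit)

Weight-based indices additionally receive the WHO *restricted application*
adjustment, which linearises z-scores beyond |z| = 3 in units of the
SD2-SD3 band so that extreme weights do not produce unstable Box-Cox
z-scores.

Reference tables are pluggable: any CSV with columns ``t, L, M, S`` can be
loaded.  The test suite uses a synthetic toy reference generated by
:mod:`cfmkit.synthetic`; real WHO tables can be supplied by the user in the
same format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GrowthReferenceTable",
    "Measurement",
    "ZScoreTriple",
    "ReferenceSet",
    "ReferenceError",
    "load_reference",
    "lms_zscore",
    "invert_zscore",
    "restricted_adjust",
    "compute_indices",
    "DAYS_PER_MONTH",
]

logger = logging.getLogger(__name__)

#: DHS age variables store completed months; day-keyed tables are converted.
DAYS_PER_MONTH = 30.4375

#: |L| below this is treated as the log-normal (L -> 0) limit.
_L_EPS = 1e-8

INDICATORS = ("length_height_for_age", "weight_for_age", "weight_for_length_height")
SEXES = ("male", "female")
AXIS_KINDS = ("age_days", "age_months", "length_cm", "height_cm")

#: Age (months) below which the recumbent-length convention applies.
STANDING_AGE_MONTHS = 24.0
#: Average difference between recumbent length and standing height (cm).
POSITION_CORRECTION_CM = 0.7


class ReferenceError(ValueError):
    """Structured validation error for growth-reference tables."""


@dataclass(frozen=True)
class GrowthReferenceTable:
    """LMS rows for one (indicator, sex, axis) combination.

    ``t`` is the lookup axis (age in months or stature in cm), strictly
    increasing.  ``L``, ``M``, ``S`` are interpolated piecewise-linearly
    and independently between knots.
    """

    indicator: str
    sex: str
    axis_kind: str
    t: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "L", "M", "S"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.indicator not in INDICATORS:
            raise ReferenceError(f"unknown indicator {self.indicator!r}")
        if self.sex not in SEXES:
            raise ReferenceError(f"unknown sex {self.sex!r}")
        if self.axis_kind not in AXIS_KINDS:
            raise ReferenceError(f"unknown axis_kind {self.axis_kind!r}")
        if self.t.size < 2:
            raise ReferenceError("reference table needs at least 2 rows")
        if not np.all(np.diff(self.t) > 0):
            raise ReferenceError("axis values t must be strictly increasing")
        bad_m = np.nonzero(~(self.M > 0))[0]
        if bad_m.size:
            raise ReferenceError(f"non-positive M at row {bad_m[0]}")
        bad_s = np.nonzero(~(self.S > 0))[0]
        if bad_s.size:
            raise ReferenceError(f"non-positive S at row {bad_s[0]}")

    @property
    def t_min(self) -> float:
        return float(self.t[0])

    @property
    def t_max(self) -> float:
        return float(self.t[-1])

    def interpolate(self, t: float) -> Tuple[float, float, float]:
        """Linearly interpolated (L, M, S) at axis value ``t``.

        Raises :class:`ReferenceError` outside the table range; the WHO
        method never extrapolates.
        """
        t = float(t)
        if not (self.t_min <= t <= self.t_max):
            raise ReferenceError(
                f"axis value {t} outside reference range "
                f"[{self.t_min}, {self.t_max}] for {self.indicator}/{self.sex}"
            )
        L = float(np.interp(t, self.t, self.L))
        M = float(np.interp(t, self.t, self.M))
        S = float(np.interp(t, self.t, self.S))
        return L, M, S

    def covers(self, t: float) -> bool:
        return self.t_min <= float(t) <= self.t_max


def load_reference(
    source,
    indicator: Optional[str] = None,
    sex: Optional[str] = None,
    axis_kind: Optional[str] = None,
) -> GrowthReferenceTable:
    """Load one LMS table from a CSV with columns ``t, L, M, S``.

    Metadata (indicator/sex/axis) comes from extra columns if present,
    else from the keyword arguments, else from a ``<indicator>__<sex>__<axis>.csv``
    filename convention.  Rows out of order are sorted with a warning;
    non-positive M or S raises a :class:`ReferenceError` naming the row.
    Day-keyed age axes are converted to months (30.4375 days/month).
    """
    df = pd.read_csv(source)
    missing = [c for c in ("t", "L", "M", "S") if c not in df.columns]
    if missing:
        raise ReferenceError(f"reference file missing columns: {missing}")

    meta = {"indicator": indicator, "sex": sex, "axis_kind": axis_kind}
    for key in meta:
        if meta[key] is None and key in df.columns:
            vals = df[key].unique()
            if len(vals) != 1:
                raise ReferenceError(f"column {key!r} is not constant in file")
            meta[key] = str(vals[0])
    if any(v is None for v in meta.values()) and isinstance(source, (str, Path)):
        stem = Path(source).stem
        parts = stem.split("__")
        if len(parts) == 3:
            for key, part in zip(("indicator", "sex", "axis_kind"), parts):
                if meta[key] is None:
                    meta[key] = part
    unresolved = [k for k, v in meta.items() if v is None]
    if unresolved:
        raise ReferenceError(f"cannot determine table metadata: {unresolved}")

    t = df["t"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        logger.warning("reference rows out of order in %s; sorting by t", source)
        df = df.sort_values("t")
        t = df["t"].to_numpy(dtype=float)

    if meta["axis_kind"] == "age_days":
        t = t / DAYS_PER_MONTH
        meta["axis_kind"] = "age_months"

    return GrowthReferenceTable(
        indicator=meta["indicator"],
        sex=meta["sex"],
        axis_kind=meta["axis_kind"],
        t=t,
        L=df["L"].to_numpy(dtype=float),
        M=df["M"].to_numpy(dtype=float),
        S=df["S"].to_numpy(dtype=float),
    )


def lms_zscore(y: float, L: float, M: float, S: float) -> float:
    """LMS z-score of measurement ``y`` given (L, M, S).

    Continuous across L -> 0, where the Box-Cox transform degenerates to
    ``ln(y/M)/S``.
    """
    if not (y > 0 and M > 0 and S > 0):
        raise ValueError(f"lms_zscore requires positive y, M, S (got {y}, {M}, {S})")
    if abs(L) < _L_EPS:
        return float(np.log(y / M) / S)
    return float(((y / M) ** L - 1.0) / (L * S))


def invert_zscore(z: float, L: float, M: float, S: float) -> float:
    """Measurement at z-score ``z``: the inverse of :func:`lms_zscore`."""
    if not (M > 0 and S > 0):
        raise ValueError(f"invert_zscore requires positive M, S (got {M}, {S})")
    if abs(L) < _L_EPS:
        return float(M * np.exp(S * z))
    base = 1.0 + L * S * z
    if base <= 0:
        raise ValueError(f"z={z} outside Box-Cox domain for L={L}, S={S}")
    return float(M * base ** (1.0 / L))


def restricted_adjust(z: float, y: float, L: float, M: float, S: float) -> float:
    """WHO restricted-application adjustment for weight-based indices.

    Identity on [-3, 3]; beyond that the z-score is recomputed as 3 (or -3)
    plus the measurement's linear excess over the SD3 cut-off in units of
    the SD2-SD3 band, computed from the inverse LMS transform.  Continuous
    at |z| = 3 by construction.
    """
    if -3.0 <= z <= 3.0:
        return float(z)
    if z > 3.0:
        sd3 = invert_zscore(3.0, L, M, S)
        sd2 = invert_zscore(2.0, L, M, S)
        band = sd3 - sd2
        if band <= 0 or not np.isfinite(band):
            raise ValueError("degenerate SD2-SD3 band in restricted adjustment")
        return float(3.0 + (y - sd3) / band)
    sd3 = invert_zscore(-3.0, L, M, S)
    sd2 = invert_zscore(-2.0, L, M, S)
    band = sd2 - sd3
    if band <= 0 or not np.isfinite(band):
        raise ValueError("degenerate SD2-SD3 band in restricted adjustment")
    return float(-3.0 + (y - sd3) / band)


@dataclass
class Measurement:
    """One child's raw anthropometry.

    ``measured_recumbent`` records the measurement position when known
    (True = lying, False = standing, None = unknown); it drives the WHO
    0.7 cm length/height conversion.
    """

    age_months: float
    sex: str
    weight_kg: Optional[float] = None
    length_or_height_cm: Optional[float] = None
    measured_recumbent: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.age_months < 60.0):
            raise ValueError(f"age_months {self.age_months} outside [0, 60)")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        for name in ("weight_kg", "length_or_height_cm"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")


@dataclass
class ZScoreTriple:
    """HAZ/WAZ/WHZ in SD units; NaN marks a missing component."""

    haz: float = np.nan
    waz: float = np.nan
    whz: float = np.nan
    all_missing: bool = False

    def present(self) -> Tuple[bool, bool, bool]:
        return (
            bool(np.isfinite(self.haz)),
            bool(np.isfinite(self.waz)),
            bool(np.isfinite(self.whz)),
        )


@dataclass
class ReferenceSet:
    """All tables needed to score one child, keyed (indicator, sex, axis_kind)."""

    tables: Mapping[Tuple[str, str, str], GrowthReferenceTable] = field(default_factory=dict)

    def add(self, table: GrowthReferenceTable) -> None:
        key = (table.indicator, table.sex, table.axis_kind)
        self.tables = {**self.tables, key: table}

    def get(self, indicator: str, sex: str, axis_kind: str) -> Optional[GrowthReferenceTable]:
        return self.tables.get((indicator, sex, axis_kind))

    @classmethod
    def from_tables(cls, tables: Iterable[GrowthReferenceTable]) -> "ReferenceSet":
        return cls({(t.indicator, t.sex, t.axis_kind): t for t in tables})

    @classmethod
    def from_directory(cls, path) -> "ReferenceSet":
        tables = [load_reference(p) for p in sorted(Path(path).glob("*.csv"))]
        if not tables:
            raise ReferenceError(f"no reference CSVs found under {path}")
        return cls.from_tables(tables)


def _convention_stature(m: Measurement, apply_correction: bool = True) -> Optional[float]:
    """Stature on the age-appropriate convention (length < 24 mo, height >= 24 mo).

    When the measured position is known and disagrees with the convention,
    the WHO 0.7 cm correction converts between recumbent length and
    standing height.  Unknown position assumes the convention.
    """
    if m.length_or_height_cm is None:
        return None
    stature = float(m.length_or_height_cm)
    if not apply_correction or m.measured_recumbent is None:
        return stature
    recumbent_convention = m.age_months < STANDING_AGE_MONTHS
    if recumbent_convention and m.measured_recumbent is False:
        return stature + POSITION_CORRECTION_CM
    if not recumbent_convention and m.measured_recumbent is True:
        return stature - POSITION_CORRECTION_CM
    return stature


def compute_indices(
    m: Measurement,
    refs: ReferenceSet,
    apply_position_correction: bool = True,
    apply_restricted: bool = True,
) -> ZScoreTriple:
    """Compute the (HAZ, WAZ, WHZ) triple for one child.

    * HAZ from the age axis of the length/height-for-age table;
    * WAZ from the age axis of the weight-for-age table, with the
      restricted adjustment;
    * WHZ from the length axis (< 24 months) or height axis (>= 24 months)
      of the weight-for-stature table, on the convention-corrected
      stature, with the restricted adjustment.

    Missing inputs or out-of-range lookups yield NaN components rather
    than exceptions; a triple with every component missing carries the
    record-level ``all_missing`` flag.
    """
    stature = _convention_stature(m, apply_position_correction)
    out = ZScoreTriple()

    if stature is not None:
        tab = refs.get("length_height_for_age", m.sex, "age_months")
        if tab is not None and tab.covers(m.age_months):
            L, M, S = tab.interpolate(m.age_months)
            out.haz = lms_zscore(stature, L, M, S)

    if m.weight_kg is not None:
        tab = refs.get("weight_for_age", m.sex, "age_months")
        if tab is not None and tab.covers(m.age_months):
            L, M, S = tab.interpolate(m.age_months)
            z = lms_zscore(m.weight_kg, L, M, S)
            out.waz = restricted_adjust(z, m.weight_kg, L, M, S) if apply_restricted else z

    if m.weight_kg is not None and stature is not None:
        axis = "length_cm" if m.age_months < STANDING_AGE_MONTHS else "height_cm"
        tab = refs.get("weight_for_length_height", m.sex, axis)
        if tab is not None and tab.covers(stature):
            L, M, S = tab.interpolate(stature)
            z = lms_zscore(m.weight_kg, L, M, S)
            out.whz = restricted_adjust(z, m.weight_kg, L, M, S) if apply_restricted else z

    out.all_missing = not any(out.present())
    return out
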