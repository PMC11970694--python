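"""Box-Cox LMS z-scores, measurement-mode handling and outlier rules.

The LMS transform converts a measurement ``y`` into SD units of the reference
distribution at the child's age and sex::

    z = ((y / M) ** L - 1) / (L * S)     for L != 0
    z = ln(y / M) / S                    for L == 0

Height-for-age (HAZ) and BMI-for-age (BAZ) z-scores both go through this
transform.  Cohort-level conventions implemented here:

* children under 24 months are measured recumbent, older children standing;
  a measurement taken in the non-conforming position is corrected by the
  conventional 0.7 cm offset (switchable off);
* z-scores strictly below -4 or strictly above +4 are flagged as outliers
  and excluded from analysis (the boundaries themselves are retained);
* BAZ classifies nutritional status as underweight (< -2), normal
  (-2 to just below +2) or overweight-obese (>= +2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .reference_model import (
    ReferenceTable,
    interpolate_lms,
    lms_params_at,
    normalize_sex,
)

__all__ = [
    "Z_OUTLIER_LIMIT",
    "RECUMBENT_STANDING_OFFSET_CM",
    "MODE_AGE_CUTOFF_MONTHS",
    "NUTRITIONAL_CATEGORIES",
    "Measurement",
    "ZScoreResult",
    "zscore_lms",
    "inverse_lms",
    "adjust_measurement",
    "adjust_height_array",
    "compute_haz",
    "compute_baz",
    "filter_outliers",
    "outlier_mask",
    "classify_nutritional_status",
    "add_zscores",
]

logger = logging.getLogger(__name__)

Z_OUTLIER_LIMIT = 4.0
RECUMBENT_STANDING_OFFSET_CM = 0.7
MODE_AGE_CUTOFF_MONTHS = 24.0
NUTRITIONAL_CATEGORIES = ("underweight", "normal", "overweight_obese")


def _as_float_arrays(*xs):
    return [np.asarray(x, dtype=float) for x in xs]


def zscore_lms(value, L, M, S):
    """LMS z-score; scalar in, scalar out; broadcasts over arrays.

    Exact zero at ``value == M`` for any L.  Raises ``ValueError`` on
    non-positive value, M or S.
    """
    value_a, L_a, M_a, S_a = _as_float_arrays(value, L, M, S)
    if np.any(value_a <= 0) or np.any(M_a <= 0) or np.any(S_a <= 0):
        raise ValueError("zscore_lms requires value > 0, M > 0 and S > 0")
    L_safe = np.where(L_a == 0, 1.0, L_a)
    log_ratio = np.log(value_a / M_a)
    # expm1 formulation keeps precision as L -> 0 (the log branch is the limit)
    z = np.where(
        L_a == 0,
        log_ratio / S_a,
        np.expm1(L_safe * log_ratio) / (L_safe * S_a),
    )
    if np.isscalar(value) and z.ndim == 0:
        return float(z)
    return z


def inverse_lms(z, L, M, S):
    """Measurement value whose LMS z-score is ``z``; round-trips zscore_lms.

    For L != 0 the transform is only defined while ``1 + L*S*z > 0``; outside
    that range a ``ValueError`` is raised.
    """
    z_a, L_a, M_a, S_a = _as_float_arrays(z, L, M, S)
    if np.any(M_a <= 0) or np.any(S_a <= 0):
        raise ValueError("inverse_lms requires M > 0 and S > 0")
    base = 1.0 + L_a * S_a * z_a
    if np.any((L_a != 0) & (base <= 0)):
        raise ValueError("z outside representable range: 1 + L*S*z must be > 0")
    L_safe = np.where(L_a == 0, 1.0, L_a)
    # log1p formulation mirrors zscore_lms and stays exact as L -> 0
    arg = np.where(L_a == 0, 0.0, L_a * S_a * z_a)
    value = np.where(
        L_a == 0,
        M_a * np.exp(S_a * z_a),
        M_a * np.exp(np.log1p(arg) / L_safe),
    )
    if np.isscalar(z) and value.ndim == 0:
        return float(value)
    return value


@dataclass(frozen=True)
class Measurement:
    """A single height (cm) or BMI (kg/m^2) measurement."""

    value: float
    mode: str  # recumbent | standing | not_applicable
    age_months: float
    sex: str

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("measurement value must be > 0")


@dataclass(frozen=True)
class ZScoreResult:
    z: float
    excluded: bool
    indicator: str  # HAZ | BAZ


def adjust_measurement(m: Measurement, enabled: bool = True) -> Measurement:
    """Correct a height taken in the non-conforming position.

    Under 24 months the convention is recumbent length; a standing height is
    raised by 0.7 cm.  From 24 months on, standing height; a recumbent length
    is lowered by 0.7 cm.  The returned copy carries the conforming mode, so
    the operation is idempotent.  BMI measurements (mode ``not_applicable``)
    pass through untouched.
    """
    if not enabled or m.mode == "not_applicable":
        return m
    if m.age_months < MODE_AGE_CUTOFF_MONTHS and m.mode == "standing":
        return replace(m, value=m.value + RECUMBENT_STANDING_OFFSET_CM, mode="recumbent")
    if m.age_months >= MODE_AGE_CUTOFF_MONTHS and m.mode == "recumbent":
        return replace(m, value=m.value - RECUMBENT_STANDING_OFFSET_CM, mode="standing")
    return m


def adjust_height_array(height_cm, age_months, mode, enabled: bool = True):
    """Vectorised :func:`adjust_measurement` for cohort columns."""
    height = np.asarray(height_cm, dtype=float).copy()
    if not enabled:
        return height
    age = np.asarray(age_months, dtype=float)
    mode = np.asarray(mode, dtype=object)
    young = age < MODE_AGE_CUTOFF_MONTHS
    height[young & (mode == "standing")] += RECUMBENT_STANDING_OFFSET_CM
    height[~young & (mode == "recumbent")] -= RECUMBENT_STANDING_OFFSET_CM
    return height


def _record_get(record, key, default=None):
    if isinstance(record, Mapping) or isinstance(record, pd.Series):
        return record.get(key, default)
    return getattr(record, key, default)


def _zresult(z: float, indicator: str) -> ZScoreResult:
    return ZScoreResult(z=z, excluded=bool(abs(z) > Z_OUTLIER_LIMIT), indicator=indicator)


def compute_haz(record, std: ReferenceTable, adjust: bool = True) -> ZScoreResult:
    """Height-for-age z-score for one child record.

    ``record`` is any mapping/namespace with ``age_months``, ``sex``,
    ``height_cm`` and optionally ``measurement_mode``.  The measurement is
    mode-adjusted, the LMS parameters interpolated at the child's age, and
    the outlier flag set per the +/-4 SD rule.
    """
    age = float(_record_get(record, "age_months"))
    sex = normalize_sex(_record_get(record, "sex"))
    mode = _record_get(record, "measurement_mode") or (
        "recumbent" if age < MODE_AGE_CUTOFF_MONTHS else "standing"
    )
    m = adjust_measurement(
        Measurement(float(_record_get(record, "height_cm")), mode, age, sex), enabled=adjust
    )
    L, M, S = lms_params_at(std, sex, age)
    return _zresult(zscore_lms(m.value, L, M, S), "HAZ")


def compute_baz(record, bmi_std: ReferenceTable, adjust: bool = True) -> ZScoreResult:
    """BMI-for-age z-score; BMI = weight / (height in m)^2 with the height
    mode-adjusted first, no further adjustment of the BMI value."""
    age = float(_record_get(record, "age_months"))
    sex = normalize_sex(_record_get(record, "sex"))
    mode = _record_get(record, "measurement_mode") or (
        "recumbent" if age < MODE_AGE_CUTOFF_MONTHS else "standing"
    )
    m = adjust_measurement(
        Measurement(float(_record_get(record, "height_cm")), mode, age, sex), enabled=adjust
    )
    bmi = float(_record_get(record, "weight_kg")) / (m.value / 100.0) ** 2
    L, M, S = lms_params_at(bmi_std, sex, age)
    return _zresult(zscore_lms(bmi, L, M, S), "BAZ")


def outlier_mask(z):
    """True where a z-score is an outlier (strictly below -4 or above +4)."""
    z = np.asarray(z, dtype=float)
    return (z < -Z_OUTLIER_LIMIT) | (z > Z_OUTLIER_LIMIT)


def filter_outliers(results: Iterable):
    """Split z-score results into retained and excluded per the +/-4 SD rule.

    Accepts ``ZScoreResult`` objects or bare z values; returns
    ``(retained_list, n_excluded)``.  The boundaries -4 and +4 are retained.
    """
    retained, n_excluded = [], 0
    for r in results:
        z = r.z if hasattr(r, "z") else float(r)
        if z < -Z_OUTLIER_LIMIT or z > Z_OUTLIER_LIMIT:
            n_excluded += 1
        else:
            retained.append(r)
    return retained, n_excluded


def classify_nutritional_status(baz: float) -> str:
    """underweight (< -2), normal (-2 to just below +2), overweight_obese (>= +2)."""
    if baz < -2.0:
        return "underweight"
    if baz < 2.0:
        return "normal"
    return "overweight_obese"


def add_zscores(
    cohort: pd.DataFrame,
    child_std: ReferenceTable,
    bmi_std: ReferenceTable | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Append z-score columns to a cohort table.

    Adds ``height_adj_cm``, ``haz``, ``haz_excluded``, ``age_in_range`` and,
    when a BMI reference is given, ``bmi``, ``baz``, ``baz_excluded`` and
    ``nutritional_status``.  Rows whose age falls outside a reference's range
    get NaN z-scores and ``age_in_range=False`` rather than failing.
    """
    out = cohort.copy()
    sexes = out["sex"].to_numpy(dtype=object)
    ages = out["age_months"].to_numpy(dtype=float)
    h_adj = adjust_height_array(
        out["height_cm"], ages, out.get("measurement_mode", "recumbent"), enabled=adjust
    )
    out["height_adj_cm"] = h_adj

    L, M, S, ok = interpolate_lms(child_std, sexes, ages)
    haz = np.full(len(out), np.nan)
    haz[ok] = zscore_lms(h_adj[ok], L[ok], M[ok], S[ok])
    out["haz"] = haz
    out["haz_excluded"] = ok & outlier_mask(np.where(ok, haz, 0.0))
    out["age_in_range"] = ok
    n_out = int((~ok).sum())
    if n_out:
        logger.info("add_zscores: %d row(s) outside reference age range", n_out)

    if bmi_std is not None and "weight_kg" in out.columns:
        bmi = out["weight_kg"].to_numpy(dtype=float) / (h_adj / 100.0) ** 2
        out["bmi"] = bmi
        Lb, Mb, Sb, okb = interpolate_lms(bmi_std, sexes, ages)
        baz = np.full(len(out), np.nan)
        baz[okb] = zscore_lms(bmi[okb], Lb[okb], Mb[okb], Sb[okb])
        out["baz"] = baz
        out["baz_excluded"] = okb & outlier_mask(np.where(okb, baz, 0.0))
        status = pd.array([None] * len(out), dtype="object")
        usable = okb & ~out["baz_excluded"].to_numpy()
        status[usable] = [classify_nutritional_status(b) for b in baz[usable]]
        out["nutritional_status"] = status
    return out
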