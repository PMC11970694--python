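"""Sex-corrected mid-parental target heights and their z-scores.

The target height (TH) of a child is the adult height predicted from the
parents::

    TH = (F + M + d) / 2   (boys)
    TH = (F + M - d) / 2   (girls)

where ``F`` and ``M`` are the father's and mother's heights in cm and ``d``
is the sex correction, estimated as the mean father-mother height difference
in the population (here: within each survey wave).  TH is then expressed in
SD units (THz) against a growth reference at 228 months (19 years) by the
child's sex, under the assumption that adult stature no longer changes after
that age.  Parental heights themselves can be z-scored the same way, each
against their own sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference_model import ReferenceTable, lms_params_at, normalize_sex
from .zscore_engine import zscore_lms

__all__ = [
    "THZ_AGE_MONTHS",
    "DEFAULT_PLAUSIBLE_RANGE_CM",
    "THZ_SUBGROUPS",
    "ParentPair",
    "TargetHeightResult",
    "estimate_d",
    "estimate_d_by_wave",
    "target_height",
    "target_height_z",
    "parental_haz",
    "thz_from_parental_haz",
    "thz_subgroup",
    "plausible_parent_mask",
    "add_target_height",
]

logger = logging.getLogger(__name__)

THZ_AGE_MONTHS = 228.0
#: adult heights outside this window are treated as data errors
DEFAULT_PLAUSIBLE_RANGE_CM = (120.0, 210.0)
#: ordered from shortest to tallest parental background
THZ_SUBGROUPS = ("below_m3", "m3_to_m2", "m2_to_m1", "ge_m1")


@dataclass(frozen=True)
class ParentPair:
    father_height_cm: float
    mother_height_cm: float
    wave: object = None


@dataclass(frozen=True)
class TargetHeightResult:
    d_cm: float
    th_cm: float
    thz: float
    subgroup: str


def _pair_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        return pairs
    return pd.DataFrame(
        {
            "father_height_cm": [p.father_height_cm for p in pairs],
            "mother_height_cm": [p.mother_height_cm for p in pairs],
            "wave": [p.wave for p in pairs],
        }
    )


def estimate_d(pairs, wave=None) -> float:
    """Sex correction d = mean(father heights) - mean(mother heights).

    ``pairs`` is a DataFrame with ``father_height_cm``/``mother_height_cm``
    (and ``wave`` if filtering) or an iterable of :class:`ParentPair`.  With
    ``wave`` given, only that wave's pairs enter the means.
    """
    df = _pair_frame(pairs)
    if wave is not None:
        df = df[df["wave"] == wave]
    if len(df) == 0:
        raise ValueError(f"no parent pairs available (wave={wave!r})")
    return float(df["father_height_cm"].mean() - df["mother_height_cm"].mean())


def estimate_d_by_wave(pairs) -> pd.Series:
    """Per-wave d estimates, indexed by wave identifier."""
    df = _pair_frame(pairs)
    grouped = df.groupby("wave", sort=True)
    return grouped["father_height_cm"].mean() - grouped["mother_height_cm"].mean()


def target_height(pair, sex: str, d: float) -> float:
    """Sex-corrected mid-parental target height in cm."""
    if isinstance(pair, ParentPair):
        F, M = pair.father_height_cm, pair.mother_height_cm
    else:
        F, M = pair
    sign = 1.0 if normalize_sex(sex) == "male" else -1.0
    return (F + M + sign * d) / 2.0


def target_height_z(th_cm: float, sex: str, ref: ReferenceTable) -> float:
    """THz: the target height z-scored at 228 months by the child's sex."""
    L, M, S = lms_params_at(ref, sex, THZ_AGE_MONTHS)
    return float(zscore_lms(th_cm, L, M, S))


def parental_haz(pair: ParentPair, ref: ReferenceTable) -> tuple[float, float]:
    """(father_haz, mother_haz): each parent z-scored at 228 months against
    their own sex."""
    return (
        target_height_z(pair.father_height_cm, "male", ref),
        target_height_z(pair.mother_height_cm, "female", ref),
    )


def thz_from_parental_haz(father_haz: float, mother_haz: float) -> float:
    """Alternative THz definition: the mean of the two parental z-scores."""
    return (father_haz + mother_haz) / 2.0


def thz_subgroup(thz: float) -> str:
    """Bin THz into the four parental-background subgroups:
    (-inf,-3), [-3,-2), [-2,-1), [-1,inf)."""
    if thz < -3.0:
        return "below_m3"
    if thz < -2.0:
        return "m3_to_m2"
    if thz < -1.0:
        return "m2_to_m1"
    return "ge_m1"


def plausible_parent_mask(cohort: pd.DataFrame, plausible_range=DEFAULT_PLAUSIBLE_RANGE_CM):
    lo, hi = plausible_range
    f = cohort["father_height_cm"].to_numpy(dtype=float)
    m = cohort["mother_height_cm"].to_numpy(dtype=float)
    return (f >= lo) & (f <= hi) & (m >= lo) & (m <= hi)


def add_target_height(
    cohort: pd.DataFrame,
    adult_ref: ReferenceTable,
    d_policy="per_wave",
    plausible_range=DEFAULT_PLAUSIBLE_RANGE_CM,
) -> pd.DataFrame:
    """Append target-height columns to a cohort table.

    Adds ``d_cm``, ``th_cm``, ``thz``, ``thz_subgroup``, ``father_haz`` and
    ``mother_haz``.  ``d_policy`` is ``"per_wave"`` (d estimated from the
    plausible parent pairs within each wave, the default) or a fixed number.
    Pairs outside the plausibility window are excluded from d estimation and
    get NaN target heights; their count is logged, not silently dropped.
    """
    out = cohort.copy()
    plausible = plausible_parent_mask(out, plausible_range)
    n_bad = int((~plausible).sum())
    if n_bad:
        logger.info(
            "add_target_height: %d pair(s) outside plausibility window %s excluded",
            n_bad,
            plausible_range,
        )

    if d_policy == "per_wave":
        d_by_wave = estimate_d_by_wave(out[plausible])
        d_col = out["wave"].map(d_by_wave).to_numpy(dtype=float)
    else:
        d_col = np.full(len(out), float(d_policy))
    out["d_cm"] = d_col

    F = out["father_height_cm"].to_numpy(dtype=float)
    M = out["mother_height_cm"].to_numpy(dtype=float)
    sexes = np.asarray([normalize_sex(s) for s in out["sex"]], dtype=object)
    sign = np.where(sexes == "male", 1.0, -1.0)
    th = (F + M + sign * d_col) / 2.0
    th[~plausible] = np.nan
    out["th_cm"] = th

    thz = np.full(len(out), np.nan)
    f_haz = np.full(len(out), np.nan)
    m_haz = np.full(len(out), np.nan)
    for sex in ("male", "female"):
        L, Mref, S = lms_params_at(adult_ref, sex, THZ_AGE_MONTHS)
        child_mask = (sexes == sex) & plausible
        if child_mask.any():
            thz[child_mask] = zscore_lms(th[child_mask], L, Mref, S)
        parent_col = F if sex == "male" else M
        z = np.full(len(out), np.nan)
        z[plausible] = zscore_lms(parent_col[plausible], L, Mref, S)
        if sex == "male":
            f_haz = z
        else:
            m_haz = z
    out["thz"] = thz
    out["father_haz"] = f_haz
    out["mother_haz"] = m_haz
    out["thz_subgroup"] = [thz_subgroup(z) if np.isfinite(z) else None for z in thz]
    return out
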