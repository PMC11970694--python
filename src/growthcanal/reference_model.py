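"""LMS growth-reference tables: loading, validation, interpolation, toy fixtures.

A growth reference summarises the distribution of a body measurement (height
in cm, BMI in kg/m^2) at each age and sex by three parameters: the Box-Cox
power ``L``, the median ``M`` and the coefficient of variation ``S``.  Every
z-score in this package is computed from an (L, M, S) triple obtained from
such a table.  Official references (e.g. the WHO 2006 child standard for
ages 0-60 months, or the WHO 2007 school-age reference whose last row at
228 months anchors adult target heights) are user-supplied CSV files; this
package never bundles or downloads them.  Tests and simulations use toy
tables with closed-form parameters built by :func:`make_toy_reference`.

Two CSV dialects are accepted:

* dialect A (canonical): one file with header ``sex,age_months,L,M,S``;
* dialect B (per-sex): one file per sex with header ``Month,L,M,S``, the sex
  given explicitly by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "INDICATORS",
    "SEXES",
    "LMSRow",
    "ReferenceTable",
    "ReferenceError",
    "ReferenceFormatError",
    "ReferenceValidationError",
    "AgeOutOfRangeError",
    "normalize_sex",
    "load_reference",
    "write_reference",
    "lms_params_at",
    "interpolate_lms",
    "make_toy_reference",
    "default_toy_references",
]

logger = logging.getLogger(__name__)

INDICATORS = ("height_for_age", "bmi_for_age")
SEXES = ("female", "male")

#: accepted spellings in input files, normalised to "male"/"female"
_SEX_ALIASES = {
    "1": "male",
    "m": "male",
    "male": "male",
    "boy": "male",
    "boys": "male",
    "2": "female",
    "f": "female",
    "female": "female",
    "girl": "female",
    "girls": "female",
}

_CANONICAL_COLUMNS = ["sex", "age_months", "L", "M", "S"]


class ReferenceError(ValueError):
    """Base class for growth-reference problems."""


class ReferenceFormatError(ReferenceError):
    """The file lacks an expected column or cannot be parsed."""


class ReferenceValidationError(ReferenceError):
    """The table content violates an invariant (ordering, positivity, ...)."""


class AgeOutOfRangeError(ReferenceError):
    """A query age falls outside the table's supported range."""


def normalize_sex(value) -> str:
    """Map common sex encodings ({1,2}, {M,F}, {male,female}, ...) to
    ``"male"``/``"female"``. Case-insensitive."""
    key = str(value).strip().lower()
    if key.endswith(".0"):  # pandas may read numeric codes as floats
        key = key[:-2]
    try:
        return _SEX_ALIASES[key]
    except KeyError:
        raise ReferenceValidationError(f"unrecognized sex code: {value!r}") from None


@dataclass(frozen=True)
class LMSRow:
    """One row of a growth reference: (L, M, S) for a given sex and age."""

    sex: str
    age_months: float
    L: float
    M: float
    S: float


@dataclass(frozen=True)
class ReferenceTable:
    """A validated LMS reference for one indicator.

    ``data`` holds the canonical frame (columns ``sex, age_months, L, M, S``),
    sorted by (sex, age_months), with sexes normalised. Construct through
    :meth:`from_frame`, :func:`load_reference` or :func:`make_toy_reference`
    so that validation always runs.
    """

    indicator: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise ReferenceValidationError(
                f"unknown indicator {self.indicator!r}; expected one of {INDICATORS}"
            )
        _validate_frame(self.data)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, indicator: str) -> "ReferenceTable":
        """Normalise, sort and validate a raw frame with the canonical columns."""
        missing = [c for c in _CANONICAL_COLUMNS if c not in frame.columns]
        if missing:
            raise ReferenceFormatError(f"missing column(s): {', '.join(missing)}")
        df = frame.loc[:, _CANONICAL_COLUMNS].copy()
        df["sex"] = df["sex"].map(normalize_sex)
        for col in ("age_months", "L", "M", "S"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        df = df.sort_values(["sex", "age_months"], kind="mergesort").reset_index(drop=True)
        return cls(indicator=indicator, data=df)

    # -- queries -----------------------------------------------------------

    @property
    def sexes_present(self) -> frozenset:
        return frozenset(self.data["sex"].unique())

    def age_range(self, sex: str) -> tuple[float, float]:
        ages = self._sex_frame(sex)["age_months"]
        return float(ages.iloc[0]), float(ages.iloc[-1])

    def rows(self) -> Iterator[LMSRow]:
        for rec in self.data.itertuples(index=False):
            yield LMSRow(rec.sex, rec.age_months, rec.L, rec.M, rec.S)

    def __len__(self) -> int:
        return len(self.data)

    def _sex_frame(self, sex: str) -> pd.DataFrame:
        sex = normalize_sex(sex)
        sub = self.data[self.data["sex"] == sex]
        if sub.empty:
            raise ReferenceValidationError(f"no rows for sex {sex!r} in table")
        return sub


def _validate_frame(df: pd.DataFrame) -> None:
    missing = [c for c in _CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ReferenceFormatError(f"missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ReferenceValidationError("reference table has no rows")
    bad_sex = set(df["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise ReferenceValidationError(f"non-normalised sex values: {sorted(bad_sex)}")
    if set(df["sex"].unique()) != set(SEXES):
        raise ReferenceValidationError("both sexes must be present in a reference table")
    for col in ("age_months", "L", "M", "S"):
        if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
            raise ReferenceValidationError(f"non-finite values in column {col!r}")
    for idx, rec in enumerate(df.itertuples(index=False)):
        if rec.age_months < 0:
            raise ReferenceValidationError(f"row {idx}: negative age {rec.age_months}")
        if rec.M <= 0:
            raise ReferenceValidationError(
                f"row {idx} (sex={rec.sex}, age={rec.age_months}): M must be > 0, got {rec.M}"
            )
        if rec.S <= 0:
            raise ReferenceValidationError(
                f"row {idx} (sex={rec.sex}, age={rec.age_months}): S must be > 0, got {rec.S}"
            )
    for sex, sub in df.groupby("sex"):
        ages = sub["age_months"].to_numpy()
        if np.any(np.diff(ages) <= 0):
            j = int(np.argmax(np.diff(ages) <= 0))
            raise ReferenceValidationError(
                f"ages not strictly increasing for sex {sex!r} "
                f"(duplicate or disorder near age {ages[j + 1]})"
            )


# ---------------------------------------------------------------------------
# file I/O


def _read_one_file(path, indicator: str, sex: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ReferenceFormatError(f"reference file not found: {path}")
    raw = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in raw.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    sex_col = pick("sex", "gender")
    age_col = pick("age_months", "agemos", "age", "month", "months")
    l_col, m_col, s_col = pick("l"), pick("m"), pick("s")
    for label, col in (("age", age_col), ("L", l_col), ("M", m_col), ("S", s_col)):
        if col is None:
            raise ReferenceFormatError(f"{path.name}: missing column {label!r}")
    out = pd.DataFrame(
        {
            "age_months": raw[age_col],
            "L": raw[l_col],
            "M": raw[m_col],
            "S": raw[s_col],
        }
    )
    if sex_col is not None:
        out.insert(0, "sex", raw[sex_col])
    else:
        if sex is None:
            raise ReferenceFormatError(
                f"{path.name}: no sex column (per-sex dialect) and no sex given; "
                "pass sex= or a mapping {sex: path}"
            )
        out.insert(0, "sex", sex)
    return out


def load_reference(source, indicator: str, sex: str | None = None) -> ReferenceTable:
    """Load a growth reference from CSV.

    ``source`` is either a single path (dialect A, or dialect B together with
    ``sex=``) or a mapping ``{sex: path}`` for the two-files-per-sex dialect.
    """
    if isinstance(source, Mapping):
        frames = [
            _read_one_file(path, indicator, sex=normalize_sex(s))
            for s, path in sorted(source.items(), key=lambda kv: normalize_sex(kv[0]))
        ]
        frame = pd.concat(frames, ignore_index=True)
    else:
        frame = _read_one_file(source, indicator, sex=normalize_sex(sex) if sex else None)
    return ReferenceTable.from_frame(frame, indicator)


def write_reference(table: ReferenceTable, path) -> None:
    """Write a table in the canonical dialect (round-trips exactly)."""
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# interpolation


def lms_params_at(table: ReferenceTable, sex: str, age_months: float) -> tuple[float, float, float]:
    """(L, M, S) at an exact tabulated age, or linearly interpolated between
    the two bracketing ages. Each parameter is interpolated independently."""
    sub = table._sex_frame(sex)
    ages = sub["age_months"].to_numpy()
    lo, hi = ages[0], ages[-1]
    if not (lo <= age_months <= hi):
        raise AgeOutOfRangeError(
            f"age {age_months} months outside supported range [{lo}, {hi}] "
            f"for sex {normalize_sex(sex)!r}"
        )
    L = float(np.interp(age_months, ages, sub["L"].to_numpy()))
    M = float(np.interp(age_months, ages, sub["M"].to_numpy()))
    S = float(np.interp(age_months, ages, sub["S"].to_numpy()))
    return L, M, S


def interpolate_lms(table: ReferenceTable, sexes, ages):
    """Vectorised LMS lookup.

    Returns arrays ``(L, M, S, in_range)``; rows whose age falls outside the
    table's range for their sex get NaN parameters and ``in_range=False``.
    """
    sexes = np.asarray([normalize_sex(s) for s in np.asarray(sexes, dtype=object)])
    ages = np.asarray(ages, dtype=float)
    L = np.full(ages.shape, np.nan)
    M = np.full(ages.shape, np.nan)
    S = np.full(ages.shape, np.nan)
    in_range = np.zeros(ages.shape, dtype=bool)
    for sex in table.sexes_present:
        mask = sexes == sex
        if not mask.any():
            continue
        sub = table._sex_frame(sex)
        grid = sub["age_months"].to_numpy()
        ok = mask & (ages >= grid[0]) & (ages <= grid[-1])
        in_range |= ok
        L[ok] = np.interp(ages[ok], grid, sub["L"].to_numpy())
        M[ok] = np.interp(ages[ok], grid, sub["M"].to_numpy())
        S[ok] = np.interp(ages[ok], grid, sub["S"].to_numpy())
    return L, M, S, in_range


# ---------------------------------------------------------------------------
# toy references


def make_toy_reference(kind: str, indicator: str = "height_for_age", **params) -> ReferenceTable:
    """Deterministic closed-form reference tables for tests and simulation.

    ``linear_child``
        monthly rows over ``[0, age_max]`` (default 60) with
        ``M(age) = M0 + slope * age`` and constant L, S, identical for both
        sexes.  Params: ``M0``, ``slope``, ``L``, ``S``, optional ``age_max``.
    ``adult_point``
        a single row per sex at one age (default 228 months), the anchor used
        for target-height z-scores.  Params: ``M_male``, ``M_female``, ``L``,
        ``S``, optional ``age``.
    """
    if kind == "linear_child":
        M0 = float(params["M0"])
        slope = float(params["slope"])
        L = float(params.get("L", 1.0))
        S = float(params.get("S", 0.04))
        age_max = int(params.get("age_max", 60))
        ages = np.arange(0, age_max + 1, dtype=float)
        M = M0 + slope * ages
        if np.any(M <= 0):
            raise ReferenceValidationError("linear_child produces non-positive M in range")
        frames = [
            pd.DataFrame({"sex": sex, "age_months": ages, "L": L, "M": M, "S": S})
            for sex in SEXES
        ]
        frame = pd.concat(frames, ignore_index=True)
    elif kind == "adult_point":
        L = float(params.get("L", 1.0))
        S = float(params.get("S", 0.04))
        age = float(params.get("age", 228.0))
        rows = []
        for sex, key in (("female", "M_female"), ("male", "M_male")):
            M = float(params[key])
            if M <= 0:
                raise ReferenceValidationError(f"{key} must be > 0")
            rows.append({"sex": sex, "age_months": age, "L": L, "M": M, "S": S})
        frame = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown toy reference kind {kind!r}")
    return ReferenceTable.from_frame(frame, indicator)


def default_toy_references() -> dict:
    """The toy reference set the simulator and CLI fall back to.

    The child standard is linear in age (49.9 cm at birth, +1 cm/month,
    S = 0.04), roughly tracing the median length/height of a real standard
    over 0-60 months.  The adult anchor places the 19-year medians at
    170 cm (men) and 158 cm (women): simulated parental heights then spread
    the target-height z-scores over several subgroups (mean around -1.25)
    while keeping the whole population well inside the +/-4 SD band, so the
    gross-error filter stays near-inactive on synthetic data, which by
    construction contains no gross errors.  The BMI table is flat at M = 16
    with L = -1.
    """
    return {
        "child_std": make_toy_reference("linear_child", M0=49.9, slope=1.0, L=1.0, S=0.04),
        "adult_ref": make_toy_reference(
            "adult_point", M_male=170.0, M_female=158.0, L=1.0, S=0.04
        ),
        "bmi_std": make_toy_reference(
            "linear_child", indicator="bmi_for_age", M0=16.0, slope=0.0, L=-1.0, S=0.1
        ),
    }
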