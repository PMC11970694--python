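"""Synthetic cross-sectional parent-child cohorts under a canalization model.

Real multi-wave household surveys of under-five children with measured
parental heights are access-restricted, so every pipeline stage here is
exercised on cohorts drawn from an explicit generative model:

* parents per wave from a bivariate normal with wave-specific means/SDs
  (defaults trace the secular increase observed across the 1993-2014 survey
  rounds), truncated to a plausibility window by redraw;
* each child's latent height z-score is its target-height z-score (THz,
  computed from the simulated parents exactly as the analysis pipeline does,
  so the generating THz coefficient is exactly 1) plus a canalization offset
  ``delta(age)`` that starts at ``delta0`` at birth and declines linearly to
  zero at ``t_canal`` months, plus a residency offset, optional covariate
  effects, and N(0, residual_sd) noise;
* the raw measured height is the inverse LMS transform of that z-score on
  the child standard, plus N(0, measurement_sd_cm) instrument noise;
* weight is derived from a BMI-for-age z-score drawn N(baz_mean, baz_sd).

The urban-rural contrast is parameterised by one gap, ``urban_offset``,
applied symmetrically (+gap/2 urban, -gap/2 rural) so that the pooled
discrepancy trajectory keeps the stated anchors (delta0 at birth, zero after
t_canal) while rural children sit below zero, as survey data show.  An
optional ``subgroup_pull`` adds regression toward the mean: children of
shorter-than-average parents get a positive offset proportional to the
distance of their THz below the wave mean.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml

from .reference_model import ReferenceTable, default_toy_references, interpolate_lms, lms_params_at
from .target_height import THZ_AGE_MONTHS, estimate_d
from .zscore_engine import MODE_AGE_CUTOFF_MONTHS, inverse_lms, zscore_lms

__all__ = [
    "CORE_COLUMNS",
    "DERIVED_COLUMNS",
    "WaveParams",
    "DEFAULT_WAVES",
    "SimulationConfig",
    "CohortSchemaError",
    "delta_curve",
    "simulate_parents",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

logger = logging.getLogger(__name__)

#: canonical cohort CSV schema (one parent-child pair per row)
CORE_COLUMNS = [
    "child_id",
    "wave",
    "age_months",
    "sex",
    "height_cm",
    "measurement_mode",
    "weight_kg",
    "father_height_cm",
    "mother_height_cm",
    "residency",
    "island",
    "father_basic_edu",
    "mother_basic_edu",
    "food_share",
    "household_size",
]

#: columns the pipeline stages may append
DERIVED_COLUMNS = [
    "height_adj_cm",
    "bmi",
    "haz",
    "haz_excluded",
    "baz",
    "baz_excluded",
    "nutritional_status",
    "age_in_range",
    "d_cm",
    "th_cm",
    "thz",
    "thz_subgroup",
    "father_haz",
    "mother_haz",
    "discrepancy",
]

_COVARIATE_EFFECT_COLUMNS = (
    "food_share",
    "household_size",
    "father_basic_edu",
    "mother_basic_edu",
    "island_java",
)


class CohortSchemaError(ValueError):
    """A cohort file does not match the canonical column schema."""


@dataclass(frozen=True)
class WaveParams:
    """Per-wave population parameters: parental height distribution plus the
    marginal covariate rates used for cosmetic (zero-effect) covariates."""

    wave: int
    father_mean: float
    father_sd: float
    mother_mean: float
    mother_sd: float
    food_share_mean: float = 0.25
    father_basic_rate: float = 0.70
    mother_basic_rate: float = 0.75
    java_bali_rate: float = 0.57


#: defaults reproduce the per-wave parental height means/SDs and covariate
#: marginals of the 1993/2000/2007/2014 survey rounds (wave id = survey year)
DEFAULT_WAVES = (
    WaveParams(1993, 161.50, 5.75, 150.21, 5.18, 0.33, 0.982, 0.996, 0.591),
    WaveParams(2000, 161.70, 6.07, 150.56, 5.36, 0.25, 0.665, 0.738, 0.622),
    WaveParams(2007, 162.13, 5.92, 151.24, 5.29, 0.21, 0.594, 0.645, 0.579),
    WaveParams(2014, 162.71, 6.16, 151.20, 5.39, 0.19, 0.547, 0.573, 0.513),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters.  ``seed`` is mandatory; a cohort is a pure
    function of the config."""

    n_per_wave: int
    seed: int
    waves: tuple = DEFAULT_WAVES
    parental_corr: float = 0.2
    delta0: float = 1.5
    t_canal: float = 24.0
    urban_offset: float = 0.2
    residual_sd: float = 1.0
    measurement_sd_cm: float = 0.3
    boy_prob: float = 0.512
    urban_prob: float = 0.5
    subgroup_pull: float = 0.0
    covariate_effects: Mapping = field(default_factory=dict)
    baz_mean: float = -0.2
    baz_sd: float = 1.2
    plausible_range: tuple = (120.0, 210.0)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_per_wave < 1:
            raise ValueError("n_per_wave must be >= 1")
        if not (0.0 < self.t_canal <= 60.0):
            raise ValueError("t_canal must be in (0, 60] months")
        if not (-1.0 <= self.parental_corr <= 1.0):
            raise ValueError("parental_corr must be in [-1, 1]")
        for name in ("residual_sd", "measurement_sd_cm", "baz_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for w in self.waves:
            if w.father_sd <= 0 or w.mother_sd <= 0:
                raise ValueError(f"wave {w.wave}: parental SDs must be > 0")
        unknown = set(self.covariate_effects) - set(_COVARIATE_EFFECT_COLUMNS)
        if unknown:
            raise ValueError(
                f"unknown covariate effect(s) {sorted(unknown)}; "
                f"allowed: {_COVARIATE_EFFECT_COLUMNS}"
            )

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["waves"] = [dataclasses.asdict(w) for w in self.waves]
        d["covariate_effects"] = dict(self.covariate_effects)
        d["plausible_range"] = list(self.plausible_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "waves" in d:
            d["waves"] = tuple(
                w if isinstance(w, WaveParams) else WaveParams(**w) for w in d["waves"]
            )
        if "plausible_range" in d:
            d["plausible_range"] = tuple(d["plausible_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def delta_curve(age_months, delta0: float, t_canal: float):
    """Canalization offset: delta0 at birth, linear decline, zero from
    t_canal months on."""
    age = np.asarray(age_months, dtype=float)
    out = np.where(age >= t_canal, 0.0, delta0 * (1.0 - age / t_canal))
    if np.isscalar(age_months):
        return float(out)
    return out


def _wave_params(config: SimulationConfig, wave) -> WaveParams:
    for w in config.waves:
        if w.wave == wave:
            return w
    raise ValueError(f"wave {wave!r} not in config")


def simulate_parents(config: SimulationConfig, wave, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw n (father, mother) height pairs for a wave from a bivariate
    normal, truncated to the plausibility window by redraw."""
    w = _wave_params(config, wave)
    lo, hi = config.plausible_range
    cov = np.array(
        [
            [w.father_sd**2, config.parental_corr * w.father_sd * w.mother_sd],
            [config.parental_corr * w.father_sd * w.mother_sd, w.mother_sd**2],
        ]
    )
    mean = np.array([w.father_mean, w.mother_mean])
    out = np.empty((n, 2))
    need = np.ones(n, dtype=bool)
    while need.any():
        draw = rng.multivariate_normal(mean, cov, size=int(need.sum()), method="cholesky")
        out[need] = draw
        need = ~((out >= lo) & (out <= hi)).all(axis=1)
    return pd.DataFrame(
        {"father_height_cm": out[:, 0], "mother_height_cm": out[:, 1], "wave": w.wave}
    )


def simulate_cohort(
    config: SimulationConfig,
    references: dict | None = None,
    delta_fn: Callable | None = None,
) -> pd.DataFrame:
    """Generate a full cross-sectional cohort table.

    ``references`` supplies ``child_std``, ``adult_ref`` and ``bmi_std``
    tables (defaults: the toy set).  ``delta_fn(age_months) -> offset``
    overrides the piecewise-linear canalization curve.  Identical config and
    seed give a bit-identical frame.
    """
    refs = references or default_toy_references()
    child_std: ReferenceTable = refs["child_std"]
    adult_ref: ReferenceTable = refs["adult_ref"]
    bmi_std: ReferenceTable = refs["bmi_std"]
    rng = np.random.default_rng(config.seed)
    n = config.n_per_wave

    frames = []
    for w in config.waves:
        parents = simulate_parents(config, w.wave, n, rng)
        F = parents["father_height_cm"].to_numpy()
        M = parents["mother_height_cm"].to_numpy()
        age = rng.uniform(0.0, 60.0, n)
        boy = rng.random(n) < config.boy_prob
        sex = np.where(boy, "male", "female")
        urban = rng.random(n) < config.urban_prob
        java = rng.random(n) < w.java_bali_rate
        father_basic = (rng.random(n) < w.father_basic_rate).astype(int)
        mother_basic = (rng.random(n) < w.mother_basic_rate).astype(int)
        nu = 6.0  # beta concentration: food shares spread like survey data
        food_share = rng.beta(w.food_share_mean * nu, (1.0 - w.food_share_mean) * nu, n)
        household_size = 2 + rng.poisson(3.2, n)

        # target-height channel: d from this wave's own pairs, exactly as the
        # analysis pipeline re-estimates it
        d = estimate_d(parents)
        th = (F + M + np.where(boy, d, -d)) / 2.0
        thz = np.empty(n)
        for s in ("male", "female"):
            Ls, Ms, Ss = lms_params_at(adult_ref, s, THZ_AGE_MONTHS)
            m = sex == s
            if m.any():
                thz[m] = zscore_lms(th[m], Ls, Ms, Ss)

        delta = delta_fn(age) if delta_fn is not None else delta_curve(
            age, config.delta0, config.t_canal
        )
        z = thz + delta
        z = z + np.where(urban, config.urban_offset / 2.0, -config.urban_offset / 2.0)
        if config.subgroup_pull:
            z = z + config.subgroup_pull * (thz.mean() - thz)
        effects = {
            "food_share": food_share,
            "household_size": household_size.astype(float),
            "father_basic_edu": father_basic.astype(float),
            "mother_basic_edu": mother_basic.astype(float),
            "island_java": java.astype(float),
        }
        for name, beta in config.covariate_effects.items():
            z = z + beta * effects[name]
        z = z + rng.normal(0.0, config.residual_sd, n)

        Lc, Mc, Sc, ok = interpolate_lms(child_std, sex, age)
        if not ok.all():
            raise ValueError("child standard does not cover the simulated age range")
        height = inverse_lms(z, Lc, Mc, Sc) + rng.normal(0.0, config.measurement_sd_cm, n)
        mode = np.where(age < MODE_AGE_CUTOFF_MONTHS, "recumbent", "standing")

        baz = rng.normal(config.baz_mean, config.baz_sd, n)
        Lb, Mb, Sb, _ = interpolate_lms(bmi_std, sex, age)
        bmi = inverse_lms(baz, Lb, Mb, Sb)
        weight = bmi * (height / 100.0) ** 2

        frames.append(
            pd.DataFrame(
                {
                    "child_id": [f"{w.wave}-{i:05d}" for i in range(n)],
                    "wave": w.wave,
                    "age_months": age,
                    "sex": sex,
                    "height_cm": height,
                    "measurement_mode": mode,
                    "weight_kg": weight,
                    "father_height_cm": F,
                    "mother_height_cm": M,
                    "residency": np.where(urban, "urban", "rural"),
                    "island": np.where(java, "java_bali", "outer"),
                    "father_basic_edu": father_basic,
                    "mother_basic_edu": mother_basic,
                    "food_share": food_share,
                    "household_size": household_size,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as plain CSV with a header row (round-trips exactly)."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, checking it against the canonical schema.

    Missing core columns or columns that are neither core nor known derived
    columns raise :class:`CohortSchemaError` listing them.
    """
    df = pd.read_csv(path)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    unexpected = [c for c in df.columns if c not in CORE_COLUMNS + DERIVED_COLUMNS]
    if missing or unexpected:
        raise CohortSchemaError(
            f"cohort schema mismatch in {path}: missing={missing}, unexpected={unexpected}"
        )
    return df
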