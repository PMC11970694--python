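import time

import numpy as np
import pandas as pd
import pytest

from growthcanal.synthetic_data import (
    CORE_COLUMNS,
    CohortSchemaError,
    SimulationConfig,
    WaveParams,
    delta_curve,
    read_cohort,
    simulate_cohort,
    simulate_parents,
    write_cohort,
)
from growthcanal.trajectory_analysis import lowess_smooth
from growthcanal.target_height import estimate_d_by_wave, target_height_z

from conftest import run_pipeline


class TestDeltaCurve:
    @pytest.mark.parametrize(
        "age, expected", [(0.0, 1.5), (12.0, 0.75), (24.0, 0.0), (40.0, 0.0)]
    )
    def test_linear_decline_then_zero(self, age, expected):
        assert delta_curve(age, 1.5, 24.0) == pytest.approx(expected)

    def test_vectorised(self):
        out = delta_curve(np.array([0.0, 6.0, 30.0]), 2.0, 24.0)
        assert np.allclose(out, [2.0, 1.5, 0.0])


class TestConfig:
    def test_seed_is_mandatory(self):
        with pytest.raises(TypeError):
            SimulationConfig(n_per_wave=10)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_per_wave=0), dict(t_canal=0.0), dict(residual_sd=-1.0),
         dict(parental_corr=1.5), dict(covariate_effects={"no_such": 1.0})],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(n_per_wave=kwargs.pop("n_per_wave", 10), seed=1, **kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(n_per_wave=20, seed=3, delta0=1.2)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg


class TestParents:
    def test_wave_means_recovered(self, toy_refs):
        cfg = SimulationConfig(n_per_wave=10, seed=2)
        rng = np.random.default_rng(2)
        parents = simulate_parents(cfg, 1993, 10000, rng)
        se_f = 5.75 / np.sqrt(10000)
        assert abs(parents["father_height_cm"].mean() - 161.50) < 3 * se_f
        se_m = 5.18 / np.sqrt(10000)
        assert abs(parents["mother_height_cm"].mean() - 150.21) < 3 * se_m

    def test_uncorrelated_when_configured(self):
        cfg = SimulationConfig(n_per_wave=10, seed=2, parental_corr=0.0)
        rng = np.random.default_rng(5)
        parents = simulate_parents(cfg, 2014, 8000, rng)
        r = np.corrcoef(parents["father_height_cm"], parents["mother_height_cm"])[0, 1]
        assert abs(r) < 3 / np.sqrt(8000)

    def test_same_seed_identical_draws(self):
        cfg = SimulationConfig(n_per_wave=10, seed=2)
        a = simulate_parents(cfg, 1993, 100, np.random.default_rng(7))
        b = simulate_parents(cfg, 1993, 100, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)

    def test_truncated_to_plausibility_window(self):
        cfg = SimulationConfig(n_per_wave=10, seed=2, plausible_range=(150.0, 170.0))
        parents = simulate_parents(cfg, 1993, 2000, np.random.default_rng(1))
        assert parents[["father_height_cm", "mother_height_cm"]].min().min() >= 150.0
        assert parents[["father_height_cm", "mother_height_cm"]].max().max() <= 170.0


class TestCohort:
    def test_cardinality_and_columns(self, toy_refs):
        cohort = simulate_cohort(SimulationConfig(n_per_wave=1000, seed=4), toy_refs)
        assert len(cohort) == 4000
        assert list(cohort.columns) == CORE_COLUMNS
        assert cohort["child_id"].is_unique
        assert set(cohort["wave"]) == {1993, 2000, 2007, 2014}
        assert cohort["food_share"].between(0, 1).all()
        young = cohort["age_months"] < 24
        assert (cohort.loc[young, "measurement_mode"] == "recumbent").all()
        assert (cohort.loc[~young, "measurement_mode"] == "standing").all()

    def test_bit_identical_under_same_config(self, toy_refs):
        cfg = SimulationConfig(n_per_wave=200, seed=9)
        a = simulate_cohort(cfg, toy_refs)
        b = simulate_cohort(cfg, toy_refs)
        pd.testing.assert_frame_equal(a, b)

    def test_secular_trend_in_target_heights(self, toy_refs):
        # wave-over-wave increase in mean parental heights must propagate to
        # mean TH and THz
        cohort = simulate_cohort(SimulationConfig(n_per_wave=5000, seed=11), toy_refs)
        pipe = run_pipeline(cohort, toy_refs)
        th_means = pipe.groupby("wave")["th_cm"].mean()
        thz_means = pipe.groupby("wave")["thz"].mean()
        assert list(th_means.index) == sorted(th_means.index)
        assert (th_means.diff().dropna() > 0).all()
        assert (thz_means.diff().dropna() > 0).all()

    def test_flat_curve_when_delta_zero(self, toy_refs):
        cfg = SimulationConfig(n_per_wave=5000, seed=12, delta0=0.0)
        pipe = run_pipeline(simulate_cohort(cfg, toy_refs), toy_refs)
        curve = lowess_smooth(pipe["age_months"], pipe["discrepancy"], bandwidth=0.8)
        assert np.max(np.abs(curve.smoothed)) < 0.05

    def test_after_canalization_bins_are_centred(self, toy_refs):
        cfg = SimulationConfig(n_per_wave=5000, seed=13)
        pipe = run_pipeline(simulate_cohort(cfg, toy_refs), toy_refs)
        old = pipe[pipe["age_months"] >= 24]
        assert abs(old["discrepancy"].mean()) < 0.05

    def test_regression_toward_mean_orders_subgroups(self, toy_refs):
        # with the pull switched on, shorter parental backgrounds show the
        # larger positive discrepancy after canalization
        cfg = SimulationConfig(n_per_wave=1250, seed=14, subgroup_pull=0.3)
        pipe = run_pipeline(simulate_cohort(cfg, toy_refs), toy_refs)
        old = pipe[pipe["age_months"] >= 24]
        means = old.groupby("thz_subgroup")["discrepancy"].mean()
        assert means["m3_to_m2"] > means["m2_to_m1"] > means["ge_m1"]

    def test_custom_delta_shape_pluggable(self, toy_refs):
        cfg = SimulationConfig(n_per_wave=50, seed=15)
        flat = simulate_cohort(cfg, toy_refs, delta_fn=lambda a: np.zeros_like(a))
        boosted = simulate_cohort(cfg, toy_refs, delta_fn=lambda a: np.full_like(a, 2.0))
        # same seed, shifted latent z: boosted children measure taller
        assert (boosted["height_cm"] - flat["height_cm"]).mean() > 0


class TestCohortIO:
    def test_roundtrip_identity(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort(small_cohort, path)
        again = read_cohort(path)
        pd.testing.assert_frame_equal(small_cohort, again)

    def test_missing_column_schema_error(self, tmp_path, small_cohort):
        path = tmp_path / "broken.csv"
        small_cohort.drop(columns=["height_cm"]).to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="height_cm"):
            read_cohort(path)

    def test_unexpected_column_schema_error(self, tmp_path, small_cohort):
        path = tmp_path / "extra.csv"
        small_cohort.assign(mystery=1).to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="mystery"):
            read_cohort(path)

    def test_survey_scale_roundtrip_is_fast(self, tmp_path, toy_refs):
        # ~11,2xx parent-child pairs, the full-survey order of magnitude
        cohort = simulate_cohort(SimulationConfig(n_per_wave=2811, seed=16), toy_refs)
        assert len(cohort) == 11244
        path = tmp_path / "big.csv"
        t0 = time.perf_counter()
        write_cohort(cohort, path)
        again = read_cohort(path)
        assert time.perf_counter() - t0 < 5.0
        assert len(again) == len(cohort)
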