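import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from growthcanal.synthetic_data import SimulationConfig, simulate_cohort
from growthcanal.trajectory_analysis import (
    bin_discrepancy_by_age,
    build_trajectories,
    curves_to_frame,
    discrepancy,
    group_gap_ci,
    lowess_smooth,
)

from conftest import run_pipeline


def brute_force_lowess(x, y, bandwidth, grid):
    """Independent per-point weighted-least-squares oracle (plain loops)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = min(max(math.ceil(bandwidth * n), 2), n)
    out = []
    for x0 in grid:
        d = sorted(abs(xi - x0) for xi in x)
        h = d[k - 1]
        if h == 0:
            out.append(np.mean([yi for xi, yi in zip(x, y) if xi == x0]))
            continue
        w = np.array([max(0.0, 1 - (abs(xi - x0) / h) ** 3) ** 3 for xi in x])
        W = np.diag(w)
        X = np.column_stack([np.ones(n), x - x0])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        out.append(beta[0])
    return np.array(out)


class TestDiscrepancy:
    @pytest.mark.parametrize("haz, thz, expected", [(-1.0, -2.0, 1.0), (0.3, 0.3, 0.0),
                                                    (-2.5, -1.0, -1.5)])
    def test_sign_convention(self, haz, thz, expected):
        assert discrepancy(haz, thz) == pytest.approx(expected)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(derandomize=True, max_examples=100)
    def test_antisymmetry(self, a, b):
        assert discrepancy(a, b) == pytest.approx(-discrepancy(b, a))


class TestLowess:
    @pytest.mark.parametrize("bandwidth", [0.2, 0.5, 1.0])
    def test_reproduces_straight_lines_exactly(self, bandwidth):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 60, 80)
        y = 2.0 - 0.05 * x
        curve = lowess_smooth(x, y, bandwidth=bandwidth, grid=np.linspace(1, 59, 30))
        assert np.allclose(curve.smoothed, 2.0 - 0.05 * curve.grid, atol=1e-10)

    def test_reproduces_constants(self):
        x = np.linspace(0, 60, 50)
        curve = lowess_smooth(x, np.full(50, 3.25), bandwidth=0.4)
        assert np.allclose(curve.smoothed, 3.25, atol=1e-12)

    @pytest.mark.parametrize("n, bandwidth", [(7, 0.6), (12, 0.35), (20, 0.8), (20, 0.3)])
    def test_matches_brute_force_oracle(self, n, bandwidth):
        rng = np.random.default_rng(n)
        x = np.sort(rng.uniform(0, 60, n))
        y = np.sin(x / 9.0) + rng.normal(0, 0.3, n)
        grid = np.linspace(x.min(), x.max(), 17)
        curve = lowess_smooth(x, y, bandwidth=bandwidth, grid=grid)
        assert np.allclose(curve.smoothed, brute_force_lowess(x, y, bandwidth, grid),
                           atol=1e-10)

    def test_invariant_to_permuting_points(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 60, 40)
        y = rng.normal(0, 1, 40)
        perm = rng.permutation(40)
        a = lowess_smooth(x, y, bandwidth=0.5)
        b = lowess_smooth(x[perm], y[perm], bandwidth=0.5)
        assert np.allclose(a.smoothed, b.smoothed, atol=1e-12)

    def test_degenerate_window_falls_back_to_mean(self):
        x = np.full(6, 10.0)
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        curve = lowess_smooth(x, y, bandwidth=1.0, grid=np.array([10.0]))
        assert curve.smoothed[0] == pytest.approx(3.5)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            lowess_smooth([1, 2, 3], [1, 2, 3], bandwidth=0.5)  # < 5 points
        with pytest.raises(ValueError):
            lowess_smooth(np.arange(10), np.arange(10), bandwidth=1.5)


class TestAgeBins:
    def test_half_open_boundaries(self):
        df = pd.DataFrame({"age_months": [24.0, 23.99], "discrepancy": [1.0, 2.0]})
        out = bin_discrepancy_by_age(df)
        assert out.loc[out["bin"] == "24-27", "n"].iloc[0] == 1
        assert out.loc[out["bin"] == "21-24", "n"].iloc[0] == 1

    def test_means_match_hand_computation(self):
        df = pd.DataFrame(
            {"age_months": [1.0, 2.0, 2.5, 10.0, 11.0, 11.5],
             "discrepancy": [1.0, 2.0, 3.0, -1.0, 0.0, 1.0]}
        )
        out = bin_discrepancy_by_age(df).set_index("bin")
        assert out.loc["0-3", "mean"] == pytest.approx(2.0)
        assert out.loc["0-3", "n"] == 3
        assert out.loc["9-12", "mean"] == pytest.approx(0.0)

    def test_bins_partition_in_range_records(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"age_months": rng.uniform(-5, 70, 300),
                           "discrepancy": rng.normal(size=300)})
        out = bin_discrepancy_by_age(df)
        n_in_range = int(((df.age_months >= 0) & (df.age_months < 60)).sum())
        assert out["n"].sum() == n_in_range
        assert len(out) == 20  # 3-month bins tile [0, 60)

    def test_bin_width_must_divide_60(self):
        df = pd.DataFrame({"age_months": [1.0], "discrepancy": [0.0]})
        with pytest.raises(ValueError):
            bin_discrepancy_by_age(df, bin_width=7)


class TestGroupGap:
    def test_identical_groups_gap_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        gap, lo, hi = group_gap_ci(a, a.copy())
        assert gap == pytest.approx(0.0)
        assert lo == pytest.approx(-hi)

    def test_zero_variance_groups(self):
        gap, lo, hi = group_gap_ci([1, 1, 1, 1], [0, 0, 0, 0])
        assert (gap, lo, hi) == (1.0, 1.0, 1.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0.5, 1, 40), rng.normal(0.0, 2, 25)
        gap, lo, hi = group_gap_ci(a, b)
        se = math.sqrt(np.var(a, ddof=1) / 40 + np.var(b, ddof=1) / 25)
        z = stats.norm.ppf(0.975)
        assert gap == pytest.approx(a.mean() - b.mean())
        assert lo == pytest.approx(gap - z * se)
        assert hi == pytest.approx(gap + z * se)

    def test_degenerate_group_errors(self):
        with pytest.raises(ValueError):
            group_gap_ci([1.0], [0.0, 1.0])


class TestBuildTrajectories:
    def test_one_curve_per_wave_at_most(self, analyzed_cohort):
        curves = build_trajectories(analyzed_cohort, ["wave"], bandwidth=0.5)
        assert 1 <= len(curves) <= 4
        assert all(c.stratum.startswith("wave=") for c in curves)

    def test_small_strata_omitted(self, analyzed_cohort):
        curves = build_trajectories(analyzed_cohort, ["wave"], min_n=10**6)
        assert curves == []

    def test_tidy_frame_roundtrip(self, analyzed_cohort):
        curves = build_trajectories(analyzed_cohort, ["wave"], bandwidth=0.5)
        frame = curves_to_frame(curves)
        assert set(frame.columns) == {"stratum", "age_months", "smoothed", "n_points",
                                      "bandwidth"}
        assert len(frame) == sum(len(c.grid) for c in curves)

    def test_null_subgroup_effect_curves_coincide(self, toy_refs):
        # no subgroup pull: discrepancy is independent of THz, so the
        # subgroup-stratified curves agree up to sampling noise
        cohort = run_pipeline(
            simulate_cohort(SimulationConfig(n_per_wave=1250, seed=10), toy_refs), toy_refs
        )
        curves = build_trajectories(cohort, ["thz_subgroup"], bandwidth=0.6, min_n=100)
        assert len(curves) >= 2
        interior = (curves[0].grid >= 30) & (curves[0].grid <= 55)
        stacked = np.vstack([c.smoothed[interior] for c in curves])
        assert np.max(stacked.max(axis=0) - stacked.min(axis=0)) < 0.4
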