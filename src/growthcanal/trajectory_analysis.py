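"""HAZ-THz discrepancy trajectories: LOWESS curves, age bins, group gaps.

The discrepancy ``HAZ - THz`` is positive when a child is currently taller,
in SD units, than the adult height predicted from the parents.  Plotted
against age on a cross-sectional cohort it traces the population's
canalization pattern: a positive offset at birth that shrinks toward zero by
about 24 months if children merely decelerate toward target height, versus a
continuing decline if growth actually falters.

The smoother is locally weighted scatterplot smoothing (LOWESS) with tricube
weights and a local *linear* fit, written out explicitly because the exact
windowing and weighting are load-bearing for the analysis: for each
evaluation point the ``ceil(bandwidth * n)`` nearest neighbours by age form
the window, ``h`` is the window radius, weights are
``w = (1 - (|x - x0|/h)^3)^3``, and a weighted straight line is fitted and
evaluated at ``x0``.  Optional robustness iterations reweight by the
bisquare of the residuals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_GRID",
    "DEFAULT_BANDWIDTH",
    "TrajectoryCurve",
    "AgeBinSummary",
    "discrepancy",
    "add_discrepancy",
    "lowess_smooth",
    "bin_discrepancy_by_age",
    "group_gap_ci",
    "urban_rural_gaps",
    "build_trajectories",
    "curves_to_frame",
    "plot_trajectories",
]

logger = logging.getLogger(__name__)

#: evaluation grid: 121 evenly spaced ages over [0, 60] months
DEFAULT_GRID = np.linspace(0.0, 60.0, 121)
DEFAULT_BANDWIDTH = 0.8
DEFAULT_MIN_STRATUM_N = 30


@dataclass(frozen=True)
class TrajectoryCurve:
    stratum: str
    grid: np.ndarray
    smoothed: np.ndarray
    n_points: int
    bandwidth: float


@dataclass(frozen=True)
class AgeBinSummary:
    bin: str
    n: int
    mean: float
    sd: float


def discrepancy(haz, thz):
    """HAZ minus THz; positive means taller than the parental prediction."""
    return np.asarray(haz, dtype=float) - np.asarray(thz, dtype=float)


def add_discrepancy(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort.copy()
    out["discrepancy"] = discrepancy(out["haz"], out["thz"])
    return out


def _fit_at(x, y, x0, k, robust_w=None):
    """Weighted local linear fit evaluated at x0 (one LOWESS point)."""
    d = np.abs(x - x0)
    h = np.partition(d, k - 1)[k - 1]
    if h <= 0.0:
        # all neighbours share one age: no line to fit, use their plain mean
        logger.warning("lowess: degenerate window at x0=%g, falling back to mean", x0)
        return float(np.mean(y[d == 0]))
    w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
    if robust_w is not None:
        w = w * robust_w
    sw = w.sum()
    if sw <= 0.0:
        nearest = np.argsort(d, kind="stable")[:k]
        return float(np.mean(y[nearest]))
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    dx = x - xm
    sxx = (w * dx * dx).sum()
    if sxx <= 1e-12 * max(1.0, xm * xm):
        logger.warning("lowess: collapsed window at x0=%g, weighted mean used", x0)
        return float(ym)
    slope = (w * dx * (y - ym)).sum() / sxx
    return float(ym + slope * (x0 - xm))


def _lowess(x, y, bandwidth, robust_iters, grid):
    n = len(x)
    k = min(max(int(math.ceil(bandwidth * n)), 2), n)
    robust_w = None
    for _ in range(robust_iters):
        fitted = np.array([_fit_at(x, y, xi, k, robust_w) for xi in x])
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 0.0:
            break
        robust_w = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return np.array([_fit_at(x, y, g, k, robust_w) for g in grid])


def lowess_smooth(
    x,
    y,
    bandwidth: float = DEFAULT_BANDWIDTH,
    robust_iters: int = 0,
    grid=None,
    stratum: str = "all",
) -> TrajectoryCurve:
    """LOWESS-smooth ``y`` against ``x`` on an evaluation grid.

    ``bandwidth`` is the fraction of points in each local window (0 < b <= 1);
    ``robust_iters`` adds bisquare robustness reweighting passes.  The result
    is deterministic in the inputs and invariant to permuting the points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 5:
        raise ValueError("lowess_smooth needs at least 5 points")
    if not (0.0 < bandwidth <= 1.0):
        raise ValueError("bandwidth must be in (0, 1]")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    smoothed = _lowess(x, y, bandwidth, robust_iters, grid)
    return TrajectoryCurve(
        stratum=stratum,
        grid=grid,
        smoothed=smoothed,
        n_points=len(x),
        bandwidth=bandwidth,
    )


def bin_discrepancy_by_age(
    records: pd.DataFrame,
    bin_width: float = 3.0,
    value_col: str = "discrepancy",
    by=None,
) -> pd.DataFrame:
    """Per-age-bin n/mean/sd of the discrepancy over [0, 60) months.

    Bins are half-open ``[a, a+w)`` and labelled ``"a-b"`` (e.g. ``"21-24"``).
    ``by`` adds extra grouping columns (e.g. ``"wave"``).  Records outside
    [0, 60) are counted, logged and left unbinned.
    """
    if 60.0 % bin_width != 0:
        raise ValueError("bin_width must divide 60")
    df = records.copy()
    ages = df["age_months"].to_numpy(dtype=float)
    in_range = (ages >= 0.0) & (ages < 60.0)
    n_out = int((~in_range).sum())
    if n_out:
        logger.info("bin_discrepancy_by_age: %d record(s) outside [0, 60) dropped", n_out)
    df = df[in_range]
    edges = np.arange(0.0, 60.0 + bin_width, bin_width)
    labels = [f"{_fmt(lo)}-{_fmt(lo + bin_width)}" for lo in edges[:-1]]
    df = df.assign(
        bin=pd.cut(df["age_months"], bins=edges, right=False, labels=labels, include_lowest=True)
    )
    keys = ["bin"] if by is None else ([by] if isinstance(by, str) else list(by)) + ["bin"]
    grouped = df.groupby(keys, observed=False)[value_col]
    out = grouped.agg(n="count", mean="mean", sd="std").reset_index()
    out["bin"] = out["bin"].astype(str)
    return out


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


def group_gap_ci(group_a, group_b, level: float = 0.95):
    """Difference of group means with a Welch-style normal CI.

    gap = mean(a) - mean(b);  CI = gap +/- z * sqrt(s_a^2/n_a + s_b^2/n_b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    gap = a.mean() - b.mean()
    se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return float(gap), float(gap - zq * se), float(gap + zq * se)


def urban_rural_gaps(
    cohort: pd.DataFrame,
    age_range=(24.0, 60.0),
    by: str = "wave",
    value_col: str = "discrepancy",
    level: float = 0.95,
) -> pd.DataFrame:
    """Urban minus rural mean discrepancy with CI, by wave, among children in
    ``age_range`` (default 2-5 years)."""
    lo, hi = age_range
    df = cohort[(cohort["age_months"] >= lo) & (cohort["age_months"] < hi)]
    rows = []
    for key, sub in df.groupby(by, sort=True):
        urban = sub.loc[sub["residency"] == "urban", value_col].dropna()
        rural = sub.loc[sub["residency"] == "rural", value_col].dropna()
        if len(urban) < 2 or len(rural) < 2:
            logger.info("urban_rural_gaps: %s=%r skipped (degenerate group)", by, key)
            continue
        gap, ci_lo, ci_hi = group_gap_ci(urban, rural, level)
        rows.append(
            {by: key, "gap": gap, "lo": ci_lo, "hi": ci_hi,
             "n_urban": len(urban), "n_rural": len(rural)}
        )
    return pd.DataFrame(rows)


def build_trajectories(
    cohort: pd.DataFrame,
    strata,
    bandwidth: float = DEFAULT_BANDWIDTH,
    robust_iters: int = 0,
    grid=None,
    min_n: int = DEFAULT_MIN_STRATUM_N,
    value_col: str = "discrepancy",
) -> list:
    """One LOWESS curve per stratum level per requested stratification.

    ``strata`` is an iterable whose entries are a column name or a tuple of
    column names (crossed strata, e.g. ``("residency", "wave")``).  Strata
    with fewer than ``min_n`` usable points are omitted with a logged reason.
    """
    curves = []
    df = cohort.dropna(subset=["age_months", value_col])
    for spec in strata:
        cols = [spec] if isinstance(spec, str) else list(spec)
        for key, sub in df.groupby(cols, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            label = "|".join(f"{c}={v}" for c, v in zip(cols, key))
            if len(sub) < max(min_n, 5):
                logger.info(
                    "build_trajectories: stratum %s omitted (n=%d < %d)",
                    label, len(sub), max(min_n, 5),
                )
                continue
            curves.append(
                lowess_smooth(
                    sub["age_months"], sub[value_col],
                    bandwidth=bandwidth, robust_iters=robust_iters,
                    grid=grid, stratum=label,
                )
            )
    return curves


def curves_to_frame(curves) -> pd.DataFrame:
    """Tidy (stratum, age_months, smoothed) frame for CSV output."""
    frames = [
        pd.DataFrame(
            {"stratum": c.stratum, "age_months": c.grid, "smoothed": c.smoothed,
             "n_points": c.n_points, "bandwidth": c.bandwidth}
        )
        for c in curves
    ]
    if not frames:
        return pd.DataFrame(
            columns=["stratum", "age_months", "smoothed", "n_points", "bandwidth"]
        )
    return pd.concat(frames, ignore_index=True)


def plot_trajectories(curves, path, title: str | None = None) -> None:
    """Write a simple line plot of the smoothed curves (one line per stratum)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for c in curves:
        ax.plot(c.grid, c.smoothed, label=c.stratum)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("age (months)")
    ax.set_ylabel("HAZ - THz (SD units)")
    if title:
        ax.set_title(title)
    if curves:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
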