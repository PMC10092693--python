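"""Group comparisons, regressions and box-plot summaries over metric tables.

Downstream statistics over per-cell metric tables (one row per analysed
cell): two groups are compared with an unpaired two-sided t-test, three
groups with one-way ANOVA; metric-vs-Feret relationships are fit by
ordinary least squares with the slope p-value from the standard t statistic;
box summaries use the median, linearly interpolated quartiles (25-75%), and
full-range whiskers (0-100%).

The t-test defaults to Student's (equal variance); Welch is available via
``equal_var=False``.  No multiple-testing correction is applied by default
(per-panel p-values); :func:`holm_adjust` is available for callers who want
family-wise control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "RegressionFit",
    "BoxSummary",
    "compare_groups",
    "fit_regression",
    "summarize_box",
    "holm_adjust",
    "plot_box",
    "plot_regression",
]


@dataclass
class ComparisonResult:
    test: str  # "unpaired t-test" | "one-way ANOVA"
    statistic: float
    p_value: float
    group_ns: tuple[int, ...]
    group_means: tuple[float, ...]


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # slope t-test
    n: int


@dataclass
class BoxSummary:
    median: float
    q25: float
    q75: float
    min: float
    max: float
    n: int


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    groups: list[str],
    group_col: str = "group",
    equal_var: bool = True,
) -> ComparisonResult:
    """Unpaired t-test (2 groups) or one-way ANOVA (3 groups) on a metric."""
    if len(groups) not in (2, 3):
        raise ValueError("compare_groups handles exactly 2 or 3 groups")
    samples = []
    for g in groups:
        vals = table.loc[table[group_col] == g, metric].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        samples.append(vals)
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in all groups: test undefined")
    if len(groups) == 2:
        res = sps.ttest_ind(samples[0], samples[1], equal_var=equal_var)
        name = "unpaired t-test"
    else:
        res = sps.f_oneway(*samples)
        name = "one-way ANOVA"
    return ComparisonResult(
        test=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_ns=tuple(len(s) for s in samples),
        group_means=tuple(float(s.mean()) for s in samples),
    )


def fit_regression(table: pd.DataFrame, x: str, y: str) -> RegressionFit:
    """Ordinary least squares of ``y`` on ``x`` (e.g. length vs Feret)."""
    data = table[[x, y]].dropna()
    xv = data[x].to_numpy(dtype=float)
    yv = data[y].to_numpy(dtype=float)
    if len(xv) < 3:
        raise ValueError("regression needs at least 3 observations")
    if np.ptp(xv) == 0:
        raise ValueError("x is constant: slope undefined")
    model = sm.OLS(yv, sm.add_constant(xv)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=len(xv),
    )


def summarize_box(values) -> BoxSummary:
    """Median, linearly interpolated quartiles and full range of a vector."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("cannot summarise an empty vector")
    q25, med, q75 = np.percentile(v, [25, 50, 75], method="linear")
    return BoxSummary(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        min=float(v.min()),
        max=float(v.max()),
        n=len(v),
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# optional plots
# ---------------------------------------------------------------------------

def plot_box(table: pd.DataFrame, metric: str, group_col: str, path) -> None:
    """Box plot per group: median line, 25-75% box, 0-100% whiskers, points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(table[group_col].dropna().unique())
    data = [table.loc[table[group_col] == g, metric].dropna() for g in groups]
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 1.5, 3.5))
    ax.boxplot(data, tick_labels=groups, whis=(0, 100))
    rng = np.random.default_rng(0)
    for i, vals in enumerate(data, start=1):
        ax.plot(i + rng.uniform(-0.08, 0.08, len(vals)), vals, "o", ms=3, alpha=0.6)
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_regression(table: pd.DataFrame, x: str, y: str, path) -> None:
    """Scatter with the OLS line, annotated with R² and the slope p-value."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = fit_regression(table, x, y)
    data = table[[x, y]].dropna()
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.plot(data[x], data[y], "o", ms=4, alpha=0.7)
    xs = np.linspace(data[x].min(), data[x].max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "-")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.set_title(f"R² = {fit.r_squared:.3f}, p = {fit.p_value:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
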