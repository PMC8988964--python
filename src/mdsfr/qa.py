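"""Quality analyses over calibration SNR reports.

Three analyses mirror routine instrument surveillance:

* **variability** — per-group coefficient of variation (100 * sample SD /
  mean) of the SNR, with each group additionally compared against a
  designated reference group (reference-phantom convention);
* **drift_regression** — ordinary least-squares slope of SNR on time with
  a two-sided test of zero slope;
* **group_tests** — two-group and multi-group location comparisons.

Parametric and rank-based tests are always reported side by side (t-test
with Mann-Whitney, one-way ANOVA with Kruskal-Wallis) rather than
gate-keeping on a normality test; a Holm-adjusted column accompanies the
raw p-values.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import QualityReport

__all__ = [
    "reports_frame",
    "variability",
    "drift_regression",
    "group_tests",
    "DriftResult",
]


def reports_frame(reports: Iterable[QualityReport | dict]) -> pd.DataFrame:
    """Tabulate QualityReports (or pre-flattened rows) for the analyses."""
    rows = [r.row() if isinstance(r, QualityReport) else dict(r) for r in reports]
    df = pd.DataFrame(rows)
    if "snr" not in df.columns:
        raise ValueError("reports carry no 'snr' column")
    return df


def _cv_percent(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(100.0 * x.std(ddof=1) / x.mean())


def variability(
    reports: Iterable[QualityReport | dict],
    group_by: str,
    reference: object | None = None,
) -> pd.DataFrame:
    """Per-group SNR coefficient of variation plus reference comparisons.

    Groups with fewer than two observations are skipped with a warning.
    Each non-reference group is compared to the reference group (default:
    the first group in sorted order) with both an unpaired t-test and a
    Mann-Whitney test.
    """
    df = reports_frame(reports)
    if group_by not in df.columns:
        raise KeyError(f"no grouping column {group_by!r} in reports")
    rows = []
    groups: dict[object, np.ndarray] = {}
    for key, sub in df.groupby(group_by, sort=True):
        if len(sub) < 2:
            warnings.warn(f"group {key!r} has a single observation; skipped")
            continue
        groups[key] = sub["snr"].to_numpy(dtype=float)
    if not groups:
        raise ValueError("no group holds >= 2 observations")
    if reference is None:
        reference = next(iter(groups))
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} absent or singleton")
    ref_vals = groups[reference]
    for key, vals in groups.items():
        row = {
            group_by: key,
            "n": vals.size,
            "mean_snr": float(vals.mean()),
            "cv_percent": _cv_percent(vals),
            "is_reference": key == reference,
        }
        if key != reference:
            t_p = stats.ttest_ind(vals, ref_vals, equal_var=False).pvalue
            u_p = stats.mannwhitneyu(vals, ref_vals, alternative="two-sided").pvalue
            row["t_p_vs_reference"] = float(t_p)
            row["mannwhitney_p_vs_reference"] = float(u_p)
        else:
            row["t_p_vs_reference"] = np.nan
            row["mannwhitney_p_vs_reference"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


class DriftResult:
    """OLS drift of SNR over time: slope, 95% CI, two-sided p-value."""

    __slots__ = ("slope", "intercept", "slope_ci", "p_value", "n")

    def __init__(self, slope, intercept, slope_ci, p_value, n):
        self.slope = float(slope)
        self.intercept = float(intercept)
        self.slope_ci = (float(slope_ci[0]), float(slope_ci[1]))
        self.p_value = float(p_value)
        self.n = int(n)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"DriftResult(slope={self.slope:.4g}/day, "
            f"ci={self.slope_ci}, p={self.p_value:.3g}, n={self.n})"
        )


def drift_regression(
    reports: Iterable[QualityReport | dict], time_column: str = "date"
) -> DriftResult:
    """Simple linear regression of SNR on time.

    Time values may be numbers (days) or anything ``pandas.to_datetime``
    parses; datetimes are converted to days since the first observation.
    Degenerate time axes (fewer than three distinct points) are refused.
    """
    df = reports_frame(reports)
    if time_column not in df.columns:
        raise KeyError(f"no time column {time_column!r} in reports")
    t_raw = df[time_column]
    if np.issubdtype(t_raw.dtype, np.number):
        t = t_raw.to_numpy(dtype=float)
    else:
        dt = pd.to_datetime(t_raw)
        t = (dt - dt.min()).dt.total_seconds().to_numpy() / 86400.0
    y = df["snr"].to_numpy(dtype=float)
    if np.unique(t).size < 3:
        raise ValueError("drift regression needs >= 3 distinct time points")
    res = stats.linregress(t, y)
    n = t.size
    if res.stderr == 0.0 or not np.isfinite(res.stderr):
        # perfectly collinear data: zero residual variance
        p = 1.0 if res.slope == 0.0 else 0.0
        half = 0.0
    else:
        p = res.pvalue
        half = stats.t.ppf(0.975, n - 2) * res.stderr
    return DriftResult(
        slope=res.slope,
        intercept=res.intercept,
        slope_ci=(res.slope - half, res.slope + half),
        p_value=p,
        n=n,
    )


def group_tests(
    reports: Iterable[QualityReport | dict],
    factor: str,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Location comparisons of SNR across the levels of one factor.

    Two levels: unpaired (Welch) t-test and Mann-Whitney.  More than two:
    one-way ANOVA and Kruskal-Wallis.  Both families are always emitted;
    a Holm-adjusted column is added across the rows of this call.  Levels
    with fewer than ``min_per_group`` observations are dropped with a
    warning.
    """
    df = reports_frame(reports)
    if factor not in df.columns:
        raise KeyError(f"no factor column {factor!r} in reports")
    levels: list[object] = []
    samples: list[np.ndarray] = []
    for key, sub in df.groupby(factor, sort=True):
        if len(sub) < min_per_group:
            warnings.warn(f"level {key!r} has < {min_per_group} observations; dropped")
            continue
        levels.append(key)
        samples.append(sub["snr"].to_numpy(dtype=float))
    if len(samples) < 2:
        raise ValueError("group tests need >= 2 levels with enough observations")

    rows = []
    if len(samples) == 2:
        a, b = samples
        with np.errstate(invalid="ignore"):
            t_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if np.array_equal(np.sort(a), np.sort(b)):
            u_p = 1.0  # identical samples: no evidence of a shift
        else:
            u_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"factor": factor, "comparison": f"{levels[0]} vs {levels[1]}",
                     "test": "t_unpaired", "p_value": t_p})
        rows.append({"factor": factor, "comparison": f"{levels[0]} vs {levels[1]}",
                     "test": "mann_whitney", "p_value": u_p})
    else:
        f_p = float(stats.f_oneway(*samples).pvalue)
        k_p = float(stats.kruskal(*samples).pvalue)
        comparison = " vs ".join(str(l) for l in levels)
        rows.append({"factor": factor, "comparison": comparison,
                     "test": "anova_oneway", "p_value": f_p})
        rows.append({"factor": factor, "comparison": comparison,
                     "test": "kruskal_wallis", "p_value": k_p})
    out = pd.DataFrame(rows)
    out["n_groups"] = len(samples)
    out["significant_0.05"] = out["p_value"] < 0.05
    finite = out["p_value"].notna()
    adjusted = np.full(len(out), np.nan)
    if finite.any():
        from statsmodels.stats.multitest import multipletests

        adjusted[finite.to_numpy()] = multipletests(
            out.loc[finite, "p_value"], method="holm"
        )[1]
    out["p_holm"] = adjusted
    return out
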