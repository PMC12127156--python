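"""Survey-weighted descriptive statistics and group tests.

The estimators here take a :class:`SurveyDesign` carrying the sampling
weights (the dietary day-one weight when the input is an NHANES-style
survey) and, optionally, stratum and primary-sampling-unit identifiers.

Two variance modes are supported:

``weights_only_robust`` (default)
    Treat observations as independent with known sampling weights; the
    variance of the ratio-estimator mean uses the linearised residuals
    ``w_i (x_i - xbar) / sum(w)`` with an ``n/(n-1)`` factor, so equal
    weights reduce every estimate to its classical unweighted form.

``taylor_linearization``
    With-replacement Taylor linearisation across PSUs within strata
    (the standard first-stage approximation for complex surveys).

Group comparisons follow the descriptive-table conventions of survey
epidemiology: a design-weighted Wald test of equal means for continuous
variables (a two-sample t statistic with Satterthwaite degrees of freedom
for two groups, a chi-square Wald statistic for more), and a Rao-Scott
style corrected Pearson chi-square for categorical variables that reduces
to the ordinary Pearson test under equal weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyDesign",
    "weighted_mean_se",
    "weighted_percent",
    "weighted_median",
    "group_test",
    "GroupTestResult",
    "table_one",
]


@dataclass(frozen=True)
class SurveyDesign:
    weights: np.ndarray
    strata: np.ndarray | None = None
    psu: np.ndarray | None = None
    variance_mode: str = "weights_only_robust"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-d array")
        if not np.isfinite(w).all() or (w <= 0).any():
            raise ValueError("weights must be positive and finite")
        if self.variance_mode not in ("weights_only_robust", "taylor_linearization"):
            raise ValueError(f"unknown variance_mode: {self.variance_mode}")
        if self.variance_mode == "taylor_linearization":
            if self.strata is None or self.psu is None:
                raise ValueError("taylor_linearization requires strata and psu ids")
            for name in ("strata", "psu"):
                object.__setattr__(self, name, np.asarray(getattr(self, name)))

    def __len__(self) -> int:
        return self.weights.size

    def take(self, idx: np.ndarray) -> "SurveyDesign":
        return SurveyDesign(
            self.weights[idx],
            None if self.strata is None else self.strata[idx],
            None if self.psu is None else self.psu[idx],
            self.variance_mode,
        )


def _linearised_variance(z: np.ndarray, design: SurveyDesign) -> float:
    """Variance of a weighted-total-based estimator from its linearised
    contributions ``z_i`` (already including the weights)."""
    n = z.size
    if design.variance_mode == "weights_only_robust" or design.strata is None:
        return float(n / (n - 1) * np.sum(z**2)) if n > 1 else np.nan
    var = 0.0
    df = pd.DataFrame({"z": z, "h": design.strata, "psu": design.psu})
    for _, g in df.groupby("h", observed=True):
        t = g.groupby("psu", observed=True)["z"].sum()
        nh = len(t)
        if nh > 1:
            var += nh / (nh - 1) * float(((t - t.mean()) ** 2).sum())
    return var


def weighted_mean_se(
    values: np.ndarray | pd.Series, design: SurveyDesign
) -> tuple[float, float]:
    """Survey-weighted mean and its standard error.

    Equal weights give the sample mean with SE ``sd/sqrt(n)`` exactly.
    """
    x = np.asarray(values, dtype=float)
    if x.size != len(design):
        raise ValueError("values and design lengths differ")
    wsum = design.weights.sum()
    if wsum <= 0:
        raise ValueError("zero total weight")
    mean = float(np.sum(design.weights * x) / wsum)
    z = design.weights * (x - mean) / wsum
    var = _linearised_variance(z, design)
    return mean, float(np.sqrt(var))


def weighted_percent(
    categories: Sequence | pd.Series, design: SurveyDesign
) -> pd.Series:
    """Weighted percentage of each category level (sums to 100)."""
    cats = pd.Series(categories).reset_index(drop=True)
    if cats.size == 0:
        raise ValueError("empty input")
    if cats.size != len(design):
        raise ValueError("categories and design lengths differ")
    totals = pd.Series(design.weights).groupby(cats, observed=False).sum()
    return 100.0 * totals / totals.sum()


def weighted_median(values: np.ndarray | pd.Series, weights: np.ndarray) -> float:
    """Weighted sample median.

    The smallest value whose cumulative weight reaches half the total;
    when the half-total falls exactly on an observation boundary (as with
    equal weights and even n) the two adjacent values are averaged, so
    equal weights reproduce the ordinary median.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    half = 0.5 * cw[-1]
    k = int(np.searchsorted(cw, half))
    if k + 1 < v.size and abs(cw[k] - half) <= 1e-12 * cw[-1]:
        return float(0.5 * (v[k] + v[k + 1]))
    return float(v[k])


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    df: float
    pvalue: float
    kind: str  # "t", "wald_chi2" or "chi2"
    detail: dict = field(default_factory=dict)


def _continuous_group_test(
    x: np.ndarray, groups: pd.Series, design: SurveyDesign
) -> GroupTestResult:
    levels = groups.unique()
    means, variances, dfs = [], [], []
    for lev in levels:
        idx = np.flatnonzero(groups.to_numpy() == lev)
        if idx.size < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 observations")
        m, se = weighted_mean_se(x[idx], design.take(idx))
        means.append(m)
        variances.append(se**2)
        dfs.append(idx.size - 1)
    means = np.asarray(means)
    variances = np.asarray(variances)
    if len(levels) == 2:
        t = (means[0] - means[1]) / np.sqrt(variances.sum())
        # Welch-Satterthwaite df; equal weights recover the classical test
        df = variances.sum() ** 2 / np.sum(variances**2 / np.asarray(dfs))
        p = 2.0 * stats.t.sf(abs(t), df)
        return GroupTestResult(float(t), float(df), float(p), "t")
    # Wald test of equal means: contrasts against the last group
    d = means[:-1] - means[-1]
    v = np.diag(variances[:-1]) + variances[-1]
    stat = float(d @ np.linalg.solve(v, d))
    df = len(levels) - 1
    p = float(stats.chi2.sf(stat, df))
    return GroupTestResult(stat, float(df), p, "wald_chi2")


def _categorical_group_test(
    cats: pd.Series, groups: pd.Series, design: SurveyDesign
) -> GroupTestResult:
    w = design.weights
    tab = pd.crosstab(cats, groups, values=w, aggfunc="sum").fillna(0.0)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("categorical test needs at least a 2x2 table")
    n = w.size
    # rescale weighted counts to the sample size, then Pearson X^2
    counts = tab.to_numpy() * n / w.sum()
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / counts.sum()
    x2 = float(np.sum((counts - expected) ** 2 / expected))
    # first-order Rao-Scott style correction via the Kish design effect
    deff = 1.0 + float(np.var(w) / np.mean(w) ** 2)
    x2 /= deff
    df = (tab.shape[0] - 1) * (tab.shape[1] - 1)
    return GroupTestResult(x2, float(df), float(stats.chi2.sf(x2, df)), "chi2")


def group_test(
    values: Sequence | pd.Series,
    groups: Sequence | pd.Series,
    design: SurveyDesign,
    kind: str = "auto",
) -> GroupTestResult:
    """Design-weighted test of no group difference.

    Continuous values get a weighted Wald test of equal means (t for two
    groups, chi-square for more); categorical values get a design-effect
    corrected Pearson chi-square.  ``kind`` may force ``"continuous"`` or
    ``"categorical"``.
    """
    g = pd.Series(groups).reset_index(drop=True)
    v = pd.Series(values).reset_index(drop=True)
    if g.nunique() < 2:
        raise ValueError("need at least 2 groups")
    if kind == "auto":
        kind = (
            "continuous"
            if pd.api.types.is_numeric_dtype(v) and v.nunique() > 5
            else "categorical"
        )
    if kind == "continuous":
        return _continuous_group_test(v.to_numpy(dtype=float), g, design)
    return _categorical_group_test(v, g, design)


def table_one(
    data: pd.DataFrame,
    variables: dict[str, str],
    group: str,
    design: SurveyDesign,
) -> pd.DataFrame:
    """Descriptive table: per-group weighted mean (SE) or n (weighted %).

    ``variables`` maps column name to ``"continuous"`` or
    ``"categorical"``; ``group`` names the stratifying column.  The last
    column holds the group-difference p-value.
    """
    rows = []
    groups = data[group]
    levels = [lev for lev in groups.unique() if pd.notna(lev)]
    for var, vkind in variables.items():
        test = group_test(data[var], groups, design, kind=vkind)
        if vkind == "continuous":
            cells = {}
            for lev in levels:
                idx = np.flatnonzero((groups == lev).to_numpy())
                m, se = weighted_mean_se(
                    data[var].to_numpy(dtype=float)[idx], design.take(idx)
                )
                cells[str(lev)] = f"{m:.2f} ({se:.2f})"
            rows.append({"variable": var, "level": "", **cells, "p": test.pvalue})
        else:
            pct = {
                str(lev): weighted_percent(
                    data[var][groups == lev],
                    design.take(np.flatnonzero((groups == lev).to_numpy())),
                )
                for lev in levels
            }
            counts = pd.crosstab(data[var], groups)
            for i, cat in enumerate(counts.index):
                cells = {
                    str(lev): f"{counts.loc[cat, lev]} ({pct[str(lev)].get(cat, 0.0):.2f})"
                    for lev in levels
                }
                rows.append(
                    {
                        "variable": var,
                        "level": str(cat),
                        **cells,
                        "p": test.pvalue if i == 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows)
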