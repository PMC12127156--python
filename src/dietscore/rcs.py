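"""Restricted cubic spline (natural spline) dose-response models.

The basis is the standard truncated-power construction: for knots
``t_1 < ... < t_k`` the model carries the linear term plus ``k - 2``
nonlinear terms

    s_j(x) = [ (x-t_j)_+^3 - (x-t_{k-1})_+^3 (t_k-t_j)/(t_k-t_{k-1})
                          + (x-t_k)_+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2

which is linear beyond the boundary knots and has continuous first and
second derivatives everywhere.  Fitted with the survey-weighted logistic
model of :mod:`dietscore.glm`, the dose-response surface reports

* ``p_overall`` — joint Wald test of all spline terms (any association);
* ``p_nonlinear`` — joint Wald test of the nonlinear terms only
  (departure from a straight-line logit);
* a curve grid of log-odds (and odds ratios) relative to a reference
  exposure value (the weighted median by default) with pointwise CIs.

Default knots: 4, at the 5th/35th/65th/95th weighted percentiles of the
exposure (3 knots use 10/50/90, 5 use 5/27.5/50/72.5/95).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dobs import weighted_quantile
from .glm import SurveyGLM, SurveyGLMResults, build_design_matrix
from .survey import SurveyDesign

__all__ = ["rcs_basis", "default_knots", "RCSLogistic", "RCSResults"]

_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def default_knots(
    x: np.ndarray, k: int = 4, weights: np.ndarray | None = None
) -> np.ndarray:
    """Knot locations at the conventional quantiles of the exposure."""
    if k not in _KNOT_QUANTILES:
        raise ValueError("k must be 3, 4 or 5")
    x = np.asarray(x, dtype=float)
    q = np.asarray(_KNOT_QUANTILES[k])
    if weights is None:
        knots = np.quantile(x, q)
    else:
        knots = weighted_quantile(x, q, weights)
    if np.unique(knots).size != k:
        raise ValueError("degenerate knots: exposure quantiles coincide")
    return knots


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis: column 0 the linear term, then the
    ``k - 2`` nonlinear terms (all zero below the first knot)."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = t.size
    if k < 3:
        raise ValueError("need at least 3 knots")
    if (np.diff(t) <= 0).any():
        raise ValueError("knots must be strictly increasing (no duplicates)")
    span2 = (t[-1] - t[0]) ** 2

    def pos3(u: np.ndarray) -> np.ndarray:
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        s = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / span2
        cols.append(s)
    return np.column_stack(cols)


@dataclass
class RCSResults:
    """Spline dose-response fit: tests plus a relative-odds curve."""

    fit: SurveyGLMResults
    knots: np.ndarray
    exposure_name: str
    reference: float
    p_overall: float
    p_nonlinear: float
    _spline_names: list[str] = field(repr=False, default_factory=list)

    def curve(
        self, grid: np.ndarray | None = None, alpha: float = 0.05, n_points: int = 100
    ) -> pd.DataFrame:
        """Log-odds (and OR) at each grid point relative to the reference
        exposure, with pointwise Wald CIs from the robust covariance."""
        model = self.fit.model
        x_obs = model._rcs_exposure
        if grid is None:
            grid = np.linspace(x_obs.min(), x_obs.max(), n_points)
        grid = np.asarray(grid, dtype=float)
        b_grid = rcs_basis(grid, self.knots)
        b_ref = rcs_basis(np.array([self.reference]), self.knots)
        contrast = b_grid - b_ref
        idx = [list(self.fit.params.index).index(n) for n in self._spline_names]
        beta = self.fit.params.to_numpy()[idx]
        cov = self.fit.cov_params.to_numpy()[np.ix_(idx, idx)]
        eta = contrast @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", contrast, cov, contrast))
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {
                self.exposure_name: grid,
                "log_odds": eta,
                "log_odds_low": eta - z * se,
                "log_odds_high": eta + z * se,
                "or": np.exp(eta),
                "or_low": np.exp(eta - z * se),
                "or_high": np.exp(eta + z * se),
            }
        )

    def plot(self, ax=None, **curve_kws):
        """Convenience plot of the OR curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        c = self.curve(**curve_kws)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(c[self.exposure_name], c["or"], color="red")
        ax.fill_between(
            c[self.exposure_name], c["or_low"], c["or_high"], alpha=0.25, color="red"
        )
        ax.axhline(1.0, ls="--", color="grey", lw=0.8)
        ax.set_xlabel(self.exposure_name)
        ax.set_ylabel("odds ratio")
        return ax


class RCSLogistic:
    """Survey-weighted logistic regression with a spline-coded exposure."""

    def __init__(
        self,
        endog: np.ndarray | pd.Series,
        exposure: np.ndarray | pd.Series,
        design: SurveyDesign,
        covariates: pd.DataFrame | None = None,
        covariate_terms: list[str] | None = None,
        k: int = 4,
        knots: np.ndarray | None = None,
        exposure_name: str = "exposure",
        reference: float | None = None,
    ) -> None:
        x = np.asarray(exposure, dtype=float)
        if knots is None:
            knots = default_knots(x, k=k, weights=design.weights)
        knots = np.asarray(knots, dtype=float)
        if knots.min() < x.min() or knots.max() > x.max():
            raise ValueError("knots must lie inside the exposure range")
        basis = rcs_basis(x, knots)
        if isinstance(exposure, pd.Series) and exposure.name:
            exposure_name = exposure.name
        names = [exposure_name] + [
            f"{exposure_name}_nl{j+1}" for j in range(basis.shape[1] - 1)
        ]
        X = pd.DataFrame(basis, columns=names)
        X.insert(0, "Intercept", 1.0)
        if covariates is not None:
            terms = covariate_terms or list(covariates.columns)
            C = build_design_matrix(covariates, terms, add_intercept=False)
            X = pd.concat([X.reset_index(drop=True), C.reset_index(drop=True)], axis=1)
        self._model = SurveyGLM(endog, X, design, family="binomial")
        self._model._rcs_exposure = x
        self.knots = knots
        self.exposure_name = exposure_name
        self._spline_names = names
        self.reference = (
            float(weighted_quantile(x, [0.5], design.weights)[0])
            if reference is None
            else float(reference)
        )

    def fit(self, **fit_kws) -> RCSResults:
        res = self._model.fit(**fit_kws)
        _, _, p_overall = res.wald_test(self._spline_names)
        nonlinear = self._spline_names[1:]
        _, _, p_nonlinear = res.wald_test(nonlinear)
        return RCSResults(
            fit=res,
            knots=self.knots,
            exposure_name=self.exposure_name,
            reference=self.reference,
            p_overall=p_overall,
            p_nonlinear=p_nonlinear,
            _spline_names=self._spline_names,
        )
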