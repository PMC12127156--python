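"""Causal mediation of diet-score effects through obesity indicators.

Two-model counterfactual estimator in the potential-outcomes framework:

1. mediator model   M ~ X + C        (survey-weighted linear)
2. outcome model    Y ~ X + M + C    (survey-weighted logistic for binary
                                      Y, linear for continuous)

Uncertainty is propagated quasi-Bayesianly: ``n_draws`` parameter vectors
are sampled from the asymptotic (robust) sampling distribution of each
fitted model; every draw simulates the counterfactual mediator under the
control and treated exposure values (including the mediator model's
residual noise, shared across arms within a draw) and averages the
resulting potential outcomes over the analytic sample's covariate
distribution with the survey weights.  Effects are reported on the
risk-difference scale for binary outcomes and the mean-difference scale
for continuous ones, so

    ACME + ADE = total effect        (exactly, draw by draw)
    proportion mediated = ACME / total effect.

No exposure-mediator interaction is modelled.  The default exposure
contrast for a continuous score is one weighted SD above the weighted
mean; binary exposures contrast 1 vs 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .glm import SurveyGLM, SurveyGLMResults, build_design_matrix, _expit
from .survey import SurveyDesign

__all__ = [
    "MediationSpec",
    "MediationModel",
    "MediationResults",
    "mediate",
    "mediation_table",
]


@dataclass(frozen=True)
class MediationSpec:
    """One mediation analysis: exposure -> mediator -> outcome."""

    exposure: str
    mediator: str
    outcome: str
    outcome_family: str = "binomial"
    covariate_set: str | None = "core"
    n_draws: int = 1000
    seed: int | None = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_draws < 100:
            raise ValueError("n_draws must be at least 100")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


def _ci_and_p(draws: np.ndarray, level: float) -> tuple[float, float, float]:
    lo, hi = np.quantile(draws, [(1 - level) / 2, (1 + level) / 2])
    frac_pos = np.mean(draws > 0)
    p = 2.0 * min(frac_pos, 1.0 - frac_pos)
    return float(lo), float(hi), float(max(p, 1.0 / draws.size))


@dataclass
class MediationResults:
    """ACME/ADE/total decomposition with Monte-Carlo uncertainty."""

    acme: float
    ade: float
    total_effect: float
    prop_mediated: float
    ci: dict[str, tuple[float, float]]
    pvalues: dict[str, float]
    scale: str
    contrast: tuple[float, float]
    n_draws: int
    seed: int | None
    prop_unstable: bool
    mediator_fit: SurveyGLMResults = field(repr=False, default=None)
    outcome_fit: SurveyGLMResults = field(repr=False, default=None)
    draws: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, value in (
            ("acme", self.acme),
            ("ade", self.ade),
            ("total_effect", self.total_effect),
            ("prop_mediated", self.prop_mediated),
        ):
            lo, hi = self.ci[name]
            rows.append(
                {
                    "effect": name,
                    "estimate": value,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": self.pvalues[name],
                }
            )
        out = pd.DataFrame(rows)
        out.attrs["scale"] = self.scale
        out.attrs["contrast"] = self.contrast
        return out


class MediationModel:
    """Counterfactual mediation model on arrays (see module docstring)."""

    def __init__(
        self,
        outcome: np.ndarray | pd.Series,
        exposure: np.ndarray | pd.Series,
        mediator: np.ndarray | pd.Series,
        design: SurveyDesign,
        covariates: pd.DataFrame | None = None,
        covariate_terms: Sequence[str] | None = None,
        outcome_family: str = "binomial",
        contrast: tuple[float, float] | None = None,
    ) -> None:
        self.y = np.asarray(outcome, dtype=float)
        self.x = np.asarray(exposure, dtype=float)
        self.m = np.asarray(mediator, dtype=float)
        self.design = design
        self.family = outcome_family
        if covariates is not None:
            terms = list(covariate_terms or covariates.columns)
            self.C = build_design_matrix(
                covariates, terms, add_intercept=False
            ).to_numpy(dtype=float)
            self._cov_names = list(
                build_design_matrix(covariates, terms, add_intercept=False).columns
            )
        else:
            self.C = np.empty((self.y.size, 0))
            self._cov_names = []
        if contrast is None:
            uniq = np.unique(self.x)
            if uniq.size == 2 and set(uniq) == {0.0, 1.0}:
                contrast = (0.0, 1.0)
            else:
                w = design.weights
                mean = float(np.sum(w * self.x) / w.sum())
                var = float(np.sum(w * (self.x - mean) ** 2) / w.sum())
                contrast = (mean, mean + np.sqrt(var))
        self.contrast = (float(contrast[0]), float(contrast[1]))

    def fit(
        self, n_draws: int = 1000, seed: int | None = None, ci_level: float = 0.95
    ) -> MediationResults:
        n = self.y.size
        ones = np.ones((n, 1))
        Xm = np.column_stack([ones, self.x[:, None], self.C])
        m_names = ["Intercept", "exposure"] + self._cov_names
        med_fit = SurveyGLM(
            self.m, Xm, self.design, family="gaussian", exog_names=m_names
        ).fit()
        w = self.design.weights
        resid = self.m - Xm @ med_fit.params.to_numpy()
        sigma = float(np.sqrt(np.sum(w * resid**2) / w.sum()))

        Xy = np.column_stack([ones, self.x[:, None], self.m[:, None], self.C])
        y_names = ["Intercept", "exposure", "mediator"] + self._cov_names
        out_fit = SurveyGLM(
            self.y, Xy, self.design, family=self.family, exog_names=y_names
        ).fit()

        rng = np.random.default_rng(seed)
        theta_m = rng.multivariate_normal(
            med_fit.params.to_numpy(), med_fit.cov_params.to_numpy(), size=n_draws,
            method="cholesky",
        )
        theta_y = rng.multivariate_normal(
            out_fit.params.to_numpy(), out_fit.cov_params.to_numpy(), size=n_draws,
            method="cholesky",
        )

        x0, x1 = self.contrast
        wn = w / w.sum()
        link = _expit if self.family == "binomial" else (lambda e: e)
        acme = np.empty(n_draws)
        ade = np.empty(n_draws)
        total = np.empty(n_draws)
        cov_m = self.C @ theta_m[:, 2:].T if self.C.shape[1] else 0.0
        cov_y = self.C @ theta_y[:, 3:].T if self.C.shape[1] else 0.0
        for j in range(n_draws):
            bm0, bm1 = theta_m[j, 0], theta_m[j, 1]
            cm = cov_m[:, j] if self.C.shape[1] else 0.0
            eps = sigma * rng.standard_normal(n)  # shared across arms
            m_at = {x: bm0 + bm1 * x + cm + eps for x in (x0, x1)}
            by0, byx, bym = theta_y[j, 0], theta_y[j, 1], theta_y[j, 2]
            cy = cov_y[:, j] if self.C.shape[1] else 0.0

            def ybar(x_t: float, x_m: float) -> float:
                eta = by0 + byx * x_t + bym * m_at[x_m] + cy
                return float(np.sum(wn * link(eta)))

            y11, y10 = ybar(x1, x1), ybar(x1, x0)
            y01, y00 = ybar(x0, x1), ybar(x0, x0)
            acme[j] = 0.5 * ((y11 - y10) + (y01 - y00))
            ade[j] = 0.5 * ((y11 - y01) + (y10 - y00))
            total[j] = y11 - y00

        ci: dict[str, tuple[float, float]] = {}
        pvals: dict[str, float] = {}
        for name, d in (("acme", acme), ("ade", ade), ("total_effect", total)):
            lo, hi, p = _ci_and_p(d, ci_level)
            ci[name] = (lo, hi)
            pvals[name] = p
        total_est = float(total.mean())
        unstable = ci["total_effect"][0] <= 0.0 <= ci["total_effect"][1]
        prop_draws = acme / np.where(np.abs(total) < 1e-300, np.nan, total)
        prop_est = float(acme.mean() / total_est) if total_est != 0 else float("nan")
        lo, hi, p = _ci_and_p(prop_draws[np.isfinite(prop_draws)], ci_level)
        ci["prop_mediated"] = (lo, hi)
        pvals["prop_mediated"] = p
        return MediationResults(
            acme=float(acme.mean()),
            ade=float(ade.mean()),
            total_effect=total_est,
            prop_mediated=prop_est,
            ci=ci,
            pvalues=pvals,
            scale="risk_difference" if self.family == "binomial" else "mean_difference",
            contrast=self.contrast,
            n_draws=n_draws,
            seed=seed,
            prop_unstable=bool(unstable),
            mediator_fit=med_fit,
            outcome_fit=out_fit,
            draws=pd.DataFrame({"acme": acme, "ade": ade, "total": total}),
        )


def mediate(
    spec: MediationSpec, data: pd.DataFrame, design: SurveyDesign
) -> MediationResults:
    """Run one mediation analysis described by a :class:`MediationSpec`
    on a coded cohort table."""
    from .glm import ModelSpec  # covariate-set resolution

    cov_names = list(
        ModelSpec(
            spec.outcome, spec.outcome_family, spec.exposure, spec.covariate_set
        ).covariates()
    )
    cov_names = [c for c in cov_names if c not in (spec.exposure, spec.mediator)]
    model = MediationModel(
        outcome=data[spec.outcome],
        exposure=data[spec.exposure],
        mediator=data[spec.mediator],
        design=design,
        covariates=data[cov_names] if cov_names else None,
        outcome_family=spec.outcome_family,
    )
    return model.fit(n_draws=spec.n_draws, seed=spec.seed, ci_level=spec.ci_level)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def mediation_table(
    results: dict[tuple[str, str, str], MediationResults] | list[MediationResults],
) -> pd.DataFrame:
    """Tidy one-row-per-analysis summary with percent mediated.

    ``results`` maps ``(exposure, mediator, outcome)`` labels to fitted
    results (a bare list gets integer labels).
    """
    if isinstance(results, list):
        results = {(f"analysis_{i}", "", ""): r for i, r in enumerate(results)}
    rows = []
    for (exposure, mediator, outcome), r in results.items():
        rows.append(
            {
                "exposure": exposure,
                "mediator": mediator,
                "outcome": outcome,
                "acme": r.acme,
                "acme_low": r.ci["acme"][0],
                "acme_high": r.ci["acme"][1],
                "acme_sig": _stars(r.pvalues["acme"]),
                "ade": r.ade,
                "ade_low": r.ci["ade"][0],
                "ade_high": r.ci["ade"][1],
                "ade_sig": _stars(r.pvalues["ade"]),
                "total": r.total_effect,
                "pct_mediated": 100.0 * r.acme / r.total_effect
                if r.total_effect != 0
                else np.nan,
                "prop_unstable": r.prop_unstable,
                "scale": r.scale,
            }
        )
    return pd.DataFrame(rows)
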