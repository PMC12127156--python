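"""End-to-end analysis pipeline: scoring -> cohort prep -> descriptives ->
regression -> spline dose-response -> mediation.

Every number written by the pipeline is produced by one operation of the
library modules; this orchestrator only sequences them and serialises
results.  A run is fully described by a :class:`PipelineConfig` (YAML
round-trippable) and is deterministic given the config and seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    apply_exclusions,
    classify_obesity,
    classify_wc,
    code_covariates,
    dichotomize_at_median,
    read_table,
)
from .dii import compute_dii, default_dii_params, load_dii_params
from .dobs import (
    assign_tertiles,
    classify_diet,
    compute_dobs,
    default_dobs_spec,
    load_dobs_spec,
)
from .glm import ModelSpec, SeparationError, fit_model, ConvergenceError
from .mediation import MediationSpec, mediate, mediation_table
from .rcs import RCSLogistic
from .survey import SurveyDesign, table_one
from .synthetic import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "prepare_cohort"]

_FLOAT_FMT = "%.10g"


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One analysis run: input source, scoring tables, stages and seed."""

    output_dir: str = "dietscore_run"
    seed: int = 0
    # input: either a CSV/XPT path (+ optional varmap YAML) or simulation
    input_path: str | None = None
    varmap_path: str | None = None
    simulate: dict | None = None  # kwargs for CohortConfig
    dii_params_path: str | None = None
    dobs_spec_path: str | None = None
    weighted_medians: bool = True
    covariate_set: str = "core"
    # stage switches
    do_descriptives: bool = True
    do_models: bool = True
    do_rcs: bool = True
    do_mediation: bool = True
    rcs_knots: int = 4
    mediation_n_draws: int = 1000
    mediation_exposures: list[str] = field(default_factory=lambda: ["dii_std", "dobs"])
    mediation_mediators: list[str] = field(default_factory=lambda: ["bmi", "wc"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=True)


def prepare_cohort(config: PipelineConfig):
    """Load/simulate, score, filter and code: returns (data, design, info)."""
    if (config.input_path is None) == (config.simulate is None):
        raise ValueError("config must set exactly one of input_path or simulate")
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        raw = generate_cohort(CohortConfig(**sim_kwargs)).frame
    else:
        raw = read_table(config.input_path, config.varmap_path)

    dii_params = (
        load_dii_params(config.dii_params_path)
        if config.dii_params_path
        else default_dii_params()
    )
    dobs_spec = (
        load_dobs_spec(config.dobs_spec_path)
        if config.dobs_spec_path
        else default_dobs_spec()
    )
    components = sorted(set(dii_params.components) | set(dobs_spec.components))
    cohort = apply_exclusions(raw, components)
    df = code_covariates(cohort.records)

    df["dii"] = compute_dii(df[dii_params.components], dii_params).dii.to_numpy()
    df["dobs"] = compute_dobs(df[dobs_spec.components], dobs_spec).dobs.to_numpy()
    df["dii_std"] = (df["dii"] - df["dii"].mean()) / df["dii"].std(ddof=0)
    df["diet_class"] = classify_diet(df["dii"], df["dobs"]).to_numpy()
    for score in ("dii", "dobs"):
        df[f"{score}_tertile"] = pd.Categorical(
            [f"T{t}" for t in assign_tertiles(df[score])], categories=["T1", "T2", "T3"]
        )
    df["obesity"] = classify_obesity(df["bmi"])
    df["wc_group"] = classify_wc(df["wc"])

    weights = df["survey_weight"].to_numpy(dtype=float)
    design = SurveyDesign(weights)
    cutpoints = {}
    for hormone in ("shbg", "tt", "e2"):
        labels, cut = dichotomize_at_median(
            df[hormone], weights if config.weighted_medians else None
        )
        df[f"{hormone}_high"] = labels
        cutpoints[hormone] = cut
    info = {
        "n_input": cohort.n_input,
        "n_analytic": cohort.n,
        "exclusion_log": cohort.exclusion_log,
        "median_cutpoints": cutpoints,
        "dii_components": dii_params.components,
        "dobs_components": dobs_spec.components,
    }
    return df, design, info


def _tidy_fit(spec: ModelSpec, data: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    try:
        res = fit_model(spec, data, design)
    except (SeparationError, ConvergenceError, ValueError) as exc:
        return pd.DataFrame(
            [
                {
                    "outcome": spec.outcome,
                    "exposure": spec.exposure,
                    "family": spec.family,
                    "term": "",
                    "status": f"failed: {exc}",
                }
            ]
        )
    tab = res.summary().reset_index(names="term")
    tab.insert(0, "outcome", spec.outcome)
    tab.insert(1, "exposure", spec.exposure)
    tab.insert(2, "family", spec.family)
    tab["n"] = res.nobs
    tab["status"] = "ok"
    return tab


def _default_logistic_specs(covset: str) -> list[ModelSpec]:
    specs = []
    for outcome in ("infertility", "shbg_high", "tt_high", "e2_high"):
        for exposure in ("dii", "dii_tertile", "dobs", "dobs_tertile", "diet_class"):
            specs.append(ModelSpec(outcome, "binomial", exposure, covset))
        for exposure in ("bmi", "wc"):
            specs.append(ModelSpec(outcome, "binomial", exposure, covset))
    return specs


def _default_linear_specs(covset: str) -> list[ModelSpec]:
    specs = []
    for outcome in ("shbg", "tt", "e2", "bmi", "wc"):
        for exposure in ("dii", "dii_tertile", "dobs", "dobs_tertile", "diet_class"):
            if exposure in (outcome,):
                continue
            specs.append(ModelSpec(outcome, "gaussian", exposure, covset))
    return specs


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute all enabled stages; returns a map of artifact name -> path."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                return None

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    report = {"stage": name, "error": str(exc)}
                    (outdir / "error_report.json").write_text(
                        json.dumps(report, indent=2)
                    )
                    raise PipelineStageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("prepare"):
        data, design, info = prepare_cohort(config)
        flow = pd.DataFrame(
            [{"step": k, "n_removed": v} for k, v in info["exclusion_log"].items()]
        )
        flow.loc[len(flow)] = {"step": "analytic_sample", "n_removed": info["n_analytic"]}
        path = outdir / "exclusion_flow.csv"
        flow.to_csv(path, index=False)
        artifacts["exclusion_flow"] = str(path)

    if config.do_descriptives:
        with stage("descriptives"):
            frames = []
            for strat_col, strat_name in (("obesity", "obesity"), ("wc_group", "wc")):
                for level in data[strat_col].unique():
                    sub = data[data[strat_col] == level]
                    idx = np.flatnonzero((data[strat_col] == level).to_numpy())
                    t1 = table_one(
                        sub.assign(
                            fertility=np.where(
                                sub["infertility"] == 1, "infertile", "fertile"
                            )
                        ),
                        {"dii": "continuous", "dobs": "continuous",
                         "diet_class": "categorical"},
                        group="fertility",
                        design=design.take(idx),
                    )
                    t1.insert(0, "stratum", f"{strat_name}={level}")
                    frames.append(t1)
            path = outdir / "table1.csv"
            pd.concat(frames, ignore_index=True).to_csv(
                path, index=False, float_format=_FLOAT_FMT
            )
            artifacts["table1"] = str(path)

    if config.do_models:
        with stage("logistic_models"):
            tabs = [
                _tidy_fit(s, data, design)
                for s in _default_logistic_specs(config.covariate_set)
            ]
            path = outdir / "logistic_models.csv"
            pd.concat(tabs, ignore_index=True).to_csv(
                path, index=False, float_format=_FLOAT_FMT
            )
            artifacts["logistic_models"] = str(path)
        with stage("linear_models"):
            tabs = [
                _tidy_fit(s, data, design)
                for s in _default_linear_specs(config.covariate_set)
            ]
            path = outdir / "linear_models.csv"
            pd.concat(tabs, ignore_index=True).to_csv(
                path, index=False, float_format=_FLOAT_FMT
            )
            artifacts["linear_models"] = str(path)

    if config.do_rcs:
        with stage("rcs"):
            tests, curves = [], []
            covset = ModelSpec("infertility", "binomial", "dii", config.covariate_set)
            for outcome in ("infertility", "shbg_high"):
                for exposure in ("dii", "dobs"):
                    model = RCSLogistic(
                        data[outcome],
                        data[exposure],
                        design,
                        covariates=data[list(covset.covariates())],
                        k=config.rcs_knots,
                        exposure_name=exposure,
                    )
                    res = model.fit()
                    tests.append(
                        {
                            "outcome": outcome,
                            "exposure": exposure,
                            "knots": ",".join(f"{k:.6g}" for k in res.knots),
                            "p_overall": res.p_overall,
                            "p_nonlinear": res.p_nonlinear,
                        }
                    )
                    c = res.curve()
                    c = c.rename(columns={exposure: "exposure_value"})
                    c.insert(0, "outcome", outcome)
                    c.insert(1, "exposure", exposure)
                    curves.append(c)
            path = outdir / "rcs_tests.csv"
            pd.DataFrame(tests).to_csv(path, index=False, float_format=_FLOAT_FMT)
            artifacts["rcs_tests"] = str(path)
            path = outdir / "rcs_curves.csv"
            pd.concat(curves, ignore_index=True).to_csv(
                path, index=False, float_format=_FLOAT_FMT
            )
            artifacts["rcs_curves"] = str(path)

    if config.do_mediation:
        with stage("mediation"):
            results = {}
            for exposure in config.mediation_exposures:
                for mediator in config.mediation_mediators:
                    spec = MediationSpec(
                        exposure=exposure,
                        mediator=mediator,
                        outcome="infertility",
                        outcome_family="binomial",
                        covariate_set=config.covariate_set,
                        n_draws=config.mediation_n_draws,
                        seed=config.seed,
                    )
                    results[(exposure, mediator, "infertility")] = mediate(
                        spec, data, design
                    )
            path = outdir / "mediation.csv"
            mediation_table(results).to_csv(path, index=False, float_format=_FLOAT_FMT)
            artifacts["mediation"] = str(path)

    with stage("manifest"):
        manifest = {
            "dietscore_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "config": {
                k: v for k, v in config.__dict__.items() if not k.startswith("_")
            },
            "cohort": info,
            "artifacts": artifacts,
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        artifacts["manifest"] = str(path)
    return artifacts
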