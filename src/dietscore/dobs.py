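"""Dietary Oxidative Balance Score (DOBS) and joint diet classification.

The DOBS sums per-nutrient scores of 1-3 over 17 dietary components
(14 anti-oxidants, 3 pro-oxidants).  Tertile-scored components use the
analytic sample's tertiles: anti-oxidants score 1/2/3 from bottom to top
tertile, pro-oxidants inversely (4 - tertile).  Alcohol is scored
categorically: nondrinker 3, nonheavy drinker 2, heavy drinker 1.  Higher
DOBS means a more anti-oxidative diet; with the 17-component reference
spec the total ranges from 17 to 51.

The joint DII&DOBS class partitions a cohort into a pro-inflammatory /
pro-oxidative group (DII tertile 3 and DOBS tertile 1), an
anti-inflammatory / anti-oxidative group (DII tertile 1 and DOBS tertile
3), and a composite group (everyone else).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DOBSSpec",
    "DOBSResult",
    "load_dobs_spec",
    "default_dobs_spec",
    "assign_tertiles",
    "score_component",
    "compute_dobs",
    "classify_diet",
    "DIET_CLASSES",
    "HEAVY_DRINKING_G_PER_DAY",
]

#: grams of ethanol per day at/above which a woman counts as a heavy
#: drinker (oxidative-balance-score convention); nondrinker is exactly 0.
HEAVY_DRINKING_G_PER_DAY = 15.0

DIET_CLASSES = (
    "pro_inflammatory_pro_oxidative",
    "anti_inflammatory_anti_oxidative",
    "composite",
)

_POLARITIES = {"anti_oxidant", "pro_oxidant"}
_RULES = {"tertile", "alcohol_category"}
_TRANSFORMS = {"identity", "log"}


@dataclass(frozen=True)
class DOBSSpec:
    """Component list with polarity, scoring rule and optional transform."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("component", "polarity", "rule", "transform"):
            if col not in t.columns:
                raise ValueError(f"DOBS spec missing column: {col}")
        if len(t) == 0:
            raise ValueError("DOBS spec is empty")
        if t["component"].duplicated().any():
            raise ValueError("duplicate DOBS components")
        for col, allowed in (
            ("polarity", _POLARITIES),
            ("rule", _RULES),
            ("transform", _TRANSFORMS),
        ):
            bad = set(t[col]) - allowed
            if bad:
                raise ValueError(f"invalid {col} values: {sorted(bad)}")

    @property
    def components(self) -> list[str]:
        return list(self.table["component"])

    def __len__(self) -> int:
        return len(self.table)

    @property
    def score_range(self) -> tuple[int, int]:
        n = len(self)
        return n, 3 * n


def load_dobs_spec(source: str | Path | pd.DataFrame) -> DOBSSpec:
    if isinstance(source, pd.DataFrame):
        return DOBSSpec(source.copy())
    return DOBSSpec(pd.read_csv(source))


def default_dobs_spec() -> DOBSSpec:
    """The packaged 17-component spec (14 anti-oxidants, 3 pro-oxidants)."""
    with resources.files("dietscore.data").joinpath("dobs_components.csv").open() as fh:
        return load_dobs_spec(pd.read_csv(fh))


def weighted_quantile(
    values: np.ndarray, q: np.ndarray | list[float], weights: np.ndarray
) -> np.ndarray:
    """Weighted quantiles by linear interpolation of the weighted ECDF.

    Reduces to ``np.quantile(..., method='linear')`` under equal weights.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    # plotting positions generalising (i - 1)/(n - 1) to unequal weights
    cw = np.cumsum(w)
    pos = cw - w / 2.0 - w[0] / 2.0
    denom = cw[-1] - w[0] / 2.0 - w[-1] / 2.0
    pos = pos / denom if denom > 0 else np.zeros_like(pos)
    return np.interp(np.asarray(q, dtype=float), pos, v)


def assign_tertiles(
    values: np.ndarray | pd.Series, weights: np.ndarray | None = None
) -> np.ndarray:
    """Label values 1/2/3 by the sample's 33.3% and 66.7% quantiles.

    Cutpoints use the linear-interpolation quantile definition; ties at a
    cutpoint go to the lower tertile (label by ``value <= cutpoint``).
    Cutpoints are unweighted by default; pass survey ``weights`` for
    weighted tertiles.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("tertiles need at least 3 values")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values in tertile assignment")
    if weights is None:
        q1, q2 = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0])
    else:
        q1, q2 = weighted_quantile(v, [1.0 / 3.0, 2.0 / 3.0], weights)
    if q1 == q2:
        raise ValueError("degenerate tertiles: cutpoints coincide")
    return np.where(v <= q1, 1, np.where(v <= q2, 2, 3)).astype(int)


def _alcohol_scores(values: np.ndarray) -> np.ndarray:
    if (values < 0).any():
        raise ValueError("negative alcohol intake")
    return np.where(
        values == 0, 3, np.where(values < HEAVY_DRINKING_G_PER_DAY, 2, 1)
    ).astype(int)


def score_component(
    values: np.ndarray | pd.Series,
    polarity: str,
    rule: str = "tertile",
    transform: str = "identity",
) -> np.ndarray:
    """Score one component 1-3 for every participant.

    ``transform='log'`` applies log1p before tertile assignment; it never
    changes tertile membership (monotone) and is retained for fidelity to
    the published scoring recipes.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("negative intake")
    if rule == "alcohol_category":
        return _alcohol_scores(v)
    if rule != "tertile":
        raise ValueError(f"unknown rule: {rule}")
    if transform == "log":
        v = np.log1p(v)
    tert = assign_tertiles(v)
    if polarity == "anti_oxidant":
        return tert
    if polarity == "pro_oxidant":
        return 4 - tert
    raise ValueError(f"unknown polarity: {polarity}")


@dataclass(frozen=True)
class DOBSResult:
    scores: pd.DataFrame  # integer 1..3 per component
    dobs: pd.Series

    def __post_init__(self) -> None:
        if not (self.scores.sum(axis=1) == self.dobs).all():
            raise ValueError("dobs must equal the sum of component scores")


def compute_dobs(intakes: pd.DataFrame, spec: DOBSSpec | None = None) -> DOBSResult:
    """Score every participant against the spec and sum.

    Tertile cutpoints are those of the supplied analytic sample, so the
    DOBS is sample-relative by construction (as the scoring recipe is).
    """
    if spec is None:
        spec = default_dobs_spec()
    df = intakes
    if "participant_id" in df.columns:
        df = df.set_index("participant_id")
    missing = [c for c in spec.components if c not in df.columns]
    if missing:
        raise KeyError(f"intake table missing DOBS components: {missing}")
    cols = {}
    for row in spec.table.itertuples(index=False):
        cols[row.component] = score_component(
            df[row.component], row.polarity, row.rule, row.transform
        )
    score_df = pd.DataFrame(cols, index=df.index)
    return DOBSResult(scores=score_df, dobs=score_df.sum(axis=1).rename("dobs"))


def classify_diet(dii: np.ndarray | pd.Series, dobs: np.ndarray | pd.Series) -> pd.Series:
    """Joint DII&DOBS diet class for every participant.

    DII tertile 3 with DOBS tertile 1 is the pro-inflammatory /
    pro-oxidative group; DII tertile 1 with DOBS tertile 3 the
    anti-inflammatory / anti-oxidative group; everyone else composite.
    """
    dii_v = np.asarray(dii, dtype=float)
    dobs_v = np.asarray(dobs, dtype=float)
    if dii_v.shape != dobs_v.shape:
        raise ValueError("dii and dobs must be the same length")
    t_dii = assign_tertiles(dii_v)
    t_dobs = assign_tertiles(dobs_v)
    labels = np.full(dii_v.shape, "composite", dtype=object)
    labels[(t_dii == 3) & (t_dobs == 1)] = "pro_inflammatory_pro_oxidative"
    labels[(t_dii == 1) & (t_dobs == 3)] = "anti_inflammatory_anti_oxidative"
    index = dii.index if isinstance(dii, pd.Series) else None
    return pd.Series(
        pd.Categorical(labels, categories=list(DIET_CLASSES)),
        index=index,
        name="diet_class",
    )
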