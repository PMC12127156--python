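"""Dietary Inflammatory Index (DII) scoring.

The DII summarises the inflammatory potential of a day's diet.  For each
dietary component with a literature-derived global reference mean ``m``,
standard deviation ``s`` and inflammatory effect score ``e``, a participant
with daily intake ``x`` contributes

    z = (x - m) / s
    p = Phi(z)                    # standard normal CDF -> percentile
    centred = 2 * p - 1           # symmetric in (-1, 1)
    component score = centred * e

and the DII is the sum of component scores.  Positive scores are
pro-inflammatory, negative anti-inflammatory; the total is strictly bounded
by the sum of |effect score| over the components used.

The shipped 26-component reference table
(``data/dii_parameters_synthetic.csv``) is a constructed stand-in with
values representative of the published global reference database; it is
synthetic in the sense that it was not transcribed from any single
authoritative source, and users scoring real cohorts should supply their
own parameter table via :func:`load_dii_params`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DIIParameterTable",
    "DIIResult",
    "load_dii_params",
    "default_dii_params",
    "compute_dii",
]

_REQUIRED_COLS = ("component", "global_mean", "global_sd", "effect_score")


@dataclass(frozen=True)
class DIIParameterTable:
    """Per-component global reference mean/SD and inflammatory effect score."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _REQUIRED_COLS if c not in t.columns]
        if missing:
            raise ValueError(f"DII parameter table missing columns: {missing}")
        if len(t) == 0:
            raise ValueError("DII parameter table is empty")
        dup = t["component"][t["component"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate DII components: {sorted(set(dup))}")
        bad_sd = t.loc[~(t["global_sd"] > 0), "component"]
        if len(bad_sd):
            raise ValueError(
                f"non-positive global_sd for components: {list(bad_sd)}"
            )
        if not np.isfinite(t[["global_mean", "global_sd", "effect_score"]]).all().all():
            raise ValueError("non-finite values in DII parameter table")

    @property
    def components(self) -> list[str]:
        return list(self.table["component"])

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, components: Iterable[str]) -> "DIIParameterTable":
        """Restrict the table to the named components (order preserved)."""
        comps = list(components)
        known = set(self.components)
        unknown = [c for c in comps if c not in known]
        if unknown:
            raise KeyError(f"components not in parameter table: {unknown}")
        sub = self.table.set_index("component").loc[comps].reset_index()
        return DIIParameterTable(sub)

    @property
    def max_abs_dii(self) -> float:
        """Strict upper bound on |DII| for any finite intake profile."""
        return float(np.abs(self.table["effect_score"]).sum())


def load_dii_params(source: str | Path | pd.DataFrame) -> DIIParameterTable:
    """Load and validate a DII parameter table from CSV (or a DataFrame).

    The file must carry columns ``component, global_mean, global_sd,
    effect_score``; extra columns (e.g. units) are kept but unused.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        try:
            df = pd.read_csv(source)
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"empty DII parameter file: {source}") from exc
    return DIIParameterTable(df)


def default_dii_params() -> DIIParameterTable:
    """The packaged 26-component reference table (synthetic stand-in)."""
    with resources.files("dietscore.data").joinpath(
        "dii_parameters_synthetic.csv"
    ).open() as fh:
        return load_dii_params(pd.read_csv(fh))


@dataclass(frozen=True)
class DIIResult:
    """Per-participant component scores and their total DII."""

    scores: pd.DataFrame  # index participant_id, one column per component
    dii: pd.Series  # index participant_id

    def __post_init__(self) -> None:
        if not np.allclose(self.scores.sum(axis=1), self.dii, atol=1e-10):
            raise ValueError("dii must equal the sum of component scores")


def compute_dii(
    intakes: pd.DataFrame,
    params: DIIParameterTable,
    components: Sequence[str] | None = None,
    effect_inside_z: bool = False,
) -> DIIResult:
    """Compute the DII for every row of an intake table.

    Parameters
    ----------
    intakes
        One row per participant, one column per dietary component (daily
        amounts in the parameter table's units).  If a ``participant_id``
        column is present it becomes the result index.
    params
        Reference table; every active component must appear in ``intakes``
        (a missing component is an error, never a silent zero).
    components
        Optional subset of the parameter table to use; the DII remains
        valid with fewer components.
    effect_inside_z
        Compatibility switch: multiply the effect score into the z-score
        *before* the percentile transform instead of after centring.  Off
        by default (the canonical construction).
    """
    if components is not None:
        params = params.subset(components)
    df = intakes
    if "participant_id" in df.columns:
        df = df.set_index("participant_id")
    comps = params.components
    missing = [c for c in comps if c not in df.columns]
    if missing:
        raise KeyError(f"intake table missing DII components: {missing}")
    x = df[comps].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        bad = [c for c in comps if not np.isfinite(df[c]).all()]
        raise ValueError(f"non-finite intakes for components: {bad}")
    mean = params.table["global_mean"].to_numpy()
    sd = params.table["global_sd"].to_numpy()
    effect = params.table["effect_score"].to_numpy()
    z = (x - mean) / sd
    if effect_inside_z:
        centred = 2.0 * norm.cdf(z * effect) - 1.0
        scores = centred
    else:
        centred = 2.0 * norm.cdf(z) - 1.0
        scores = centred * effect
    score_df = pd.DataFrame(scores, index=df.index, columns=comps)
    return DIIResult(scores=score_df, dii=score_df.sum(axis=1).rename("dii"))
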