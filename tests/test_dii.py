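"""Dietary Inflammatory Index: worked values, invariants, validation."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from dietscore.dii import (
    DIIParameterTable,
    compute_dii,
    default_dii_params,
    load_dii_params,
)


def _single_param(mean=10.0, sd=2.0, effect=0.5, name="nutrient"):
    return load_dii_params(
        pd.DataFrame(
            {
                "component": [name],
                "global_mean": [mean],
                "global_sd": [sd],
                "effect_score": [effect],
            }
        )
    )


class TestParameterTable:
    def test_packaged_reference_has_26_components(self):
        params = default_dii_params()
        assert len(params) == 26
        assert (params.table["global_sd"] > 0).all()

    def test_zero_sd_rejected_naming_component(self):
        df = default_dii_params().table.copy()
        df.loc[3, "global_sd"] = 0.0
        bad = df.loc[3, "component"]
        with pytest.raises(ValueError, match=bad):
            load_dii_params(df)

    def test_duplicate_component_rejected(self):
        df = default_dii_params().table.copy()
        df.loc[1, "component"] = df.loc[0, "component"]
        with pytest.raises(ValueError, match="duplicate"):
            load_dii_params(df)

    def test_empty_file_rejected(self):
        with pytest.raises(ValueError):
            load_dii_params(io.StringIO(""))
        with pytest.raises(ValueError):
            load_dii_params(
                pd.DataFrame(
                    columns=["component", "global_mean", "global_sd", "effect_score"]
                )
            )

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            load_dii_params(pd.DataFrame({"component": ["a"], "global_mean": [1.0]}))


class TestComputeDII:
    def test_zero_at_global_means(self):
        params = default_dii_params()
        intakes = pd.DataFrame(
            {row.component: [row.global_mean] for row in params.table.itertuples()}
        )
        res = compute_dii(intakes, params)
        assert res.dii.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_component_worked_value(self):
        # intake one SD above the mean with effect +0.5:
        # score = (2*Phi(1) - 1) * 0.5 = 0.3413447...
        params = _single_param(mean=10.0, sd=2.0, effect=0.5)
        res = compute_dii(pd.DataFrame({"nutrient": [12.0]}), params)
        expected = (2.0 * norm.cdf(1.0) - 1.0) * 0.5
        assert res.dii.iloc[0] == pytest.approx(expected, abs=1e-10)
        assert res.dii.iloc[0] == pytest.approx(0.34134, abs=1e-5)

    def test_effect_sign_symmetry(self):
        pos = compute_dii(pd.DataFrame({"nutrient": [12.0]}), _single_param(effect=0.5))
        neg = compute_dii(pd.DataFrame({"nutrient": [12.0]}), _single_param(effect=-0.5))
        assert neg.dii.iloc[0] == pytest.approx(-pos.dii.iloc[0], abs=1e-12)

    def test_intake_antisymmetry_around_mean(self):
        params = _single_param(mean=10.0, sd=2.0, effect=0.7)
        res = compute_dii(pd.DataFrame({"nutrient": [10.0 + 3.0, 10.0 - 3.0]}), params)
        assert res.dii.iloc[0] == pytest.approx(-res.dii.iloc[1], abs=1e-12)

    def test_missing_component_is_error_not_zero(self):
        params = default_dii_params()
        intakes = pd.DataFrame({c: [1.0] for c in params.components[:-1]})
        with pytest.raises(KeyError, match=params.components[-1]):
            compute_dii(intakes, params)

    def test_nonfinite_intake_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            compute_dii(pd.DataFrame({"nutrient": [np.nan]}), _single_param())

    def test_component_subset_filter(self):
        params = default_dii_params()
        subset = params.components[:5]
        intakes = pd.DataFrame({c: [3.0] for c in subset})
        res = compute_dii(intakes, params, components=subset)
        assert list(res.scores.columns) == subset

    def test_compatibility_flag_changes_result(self):
        params = _single_param(mean=10.0, sd=2.0, effect=0.5)
        intakes = pd.DataFrame({"nutrient": [12.0]})
        canonical = compute_dii(intakes, params).dii.iloc[0]
        legacy = compute_dii(intakes, params, effect_inside_z=True).dii.iloc[0]
        assert legacy == pytest.approx(2.0 * norm.cdf(0.5) - 1.0, abs=1e-12)
        assert legacy != pytest.approx(canonical, abs=1e-6)


class TestInvariants:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_boundedness_and_additivity(self, seed):
        params = default_dii_params()
        rng = np.random.default_rng(seed)
        intakes = pd.DataFrame(
            {
                row.component: rng.lognormal(
                    np.log(max(row.global_mean, 1e-6)), 0.6, 4
                )
                for row in params.table.itertuples()
            }
        )
        res = compute_dii(intakes, params)
        # strict bound: |DII| < sum |effect|
        assert (res.dii.abs() < params.max_abs_dii).all()
        # additivity: total equals the sum of single-component runs
        singles = sum(
            compute_dii(intakes, params, components=[c]).dii
            for c in params.components
        )
        assert np.allclose(res.dii, singles, atol=1e-10)

    def test_monotonicity_in_intake(self):
        params = default_dii_params()
        base = pd.DataFrame(
            {row.component: [row.global_mean] for row in params.table.itertuples()}
        )
        for comp, effect in zip(
            params.components, params.table["effect_score"], strict=True
        ):
            bumped = base.copy()
            bumped[comp] = bumped[comp] * 1.5 + 1.0
            delta = (
                compute_dii(bumped, params).dii.iloc[0]
                - compute_dii(base, params).dii.iloc[0]
            )
            if effect > 0:
                assert delta > 0
            elif effect < 0:
                assert delta < 0
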