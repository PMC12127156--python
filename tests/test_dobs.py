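"""Oxidative balance score: tertiles, component scoring, joint classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietscore.dobs import (
    assign_tertiles,
    classify_diet,
    compute_dobs,
    default_dobs_spec,
    load_dobs_spec,
    score_component,
    weighted_quantile,
)


class TestTertiles:
    def test_three_values(self):
        assert list(assign_tertiles([1.0, 2.0, 3.0])) == [1, 2, 3]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(6, 200))
    def test_sorted_labels_nondecreasing_and_balanced(self, seed, n):
        v = np.sort(np.random.default_rng(seed).normal(size=n))
        labels = assign_tertiles(v)
        assert (np.diff(labels) >= 0).all()
        counts = np.bincount(labels, minlength=4)[1:]
        assert counts.max() - counts.min() <= 1 + n % 3

    def test_monotone_transform_invariance(self):
        v = np.random.default_rng(0).lognormal(size=50)
        assert (assign_tertiles(v) == assign_tertiles(np.log(v))).all()
        assert (assign_tertiles(v) == assign_tertiles(np.exp(v / v.max()))).all()

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            assign_tertiles([1.0, 2.0])
        with pytest.raises(ValueError, match="degenerate"):
            assign_tertiles([5.0] * 10)

    def test_weighted_quantile_reduces_to_numpy(self):
        v = np.random.default_rng(1).normal(size=31)
        q = [0.1, 1 / 3, 0.5, 2 / 3, 0.9]
        np.testing.assert_allclose(
            weighted_quantile(v, q, np.ones(31)), np.quantile(v, q), atol=1e-12
        )


class TestScoreComponent:
    def test_antioxidant_ascending(self):
        v = np.array([1.0, 2.0, 3.0])
        assert list(score_component(v, "anti_oxidant")) == [1, 2, 3]

    def test_prooxidant_inverse(self):
        v = np.array([1.0, 2.0, 3.0])
        scores = score_component(v, "pro_oxidant")
        assert list(scores) == [3, 2, 1]

    def test_inversion_duality(self, rng):
        v = rng.lognormal(size=40)
        anti = score_component(v, "anti_oxidant")
        pro = score_component(v, "pro_oxidant")
        assert (pro == 4 - anti).all()

    def test_alcohol_categories(self):
        v = np.array([0.0, 7.5, 14.999, 15.0, 40.0])
        assert list(score_component(v, "pro_oxidant", rule="alcohol_category")) == [
            3,
            2,
            2,
            1,
            1,
        ]

    def test_negative_intake_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            score_component(np.array([-1.0, 2.0, 3.0]), "anti_oxidant")


class TestComputeDOBS:
    def _extreme_intakes(self, spec):
        """3 participants: best / middle / worst oxidative balance."""
        cols = {}
        for row in spec.table.itertuples(index=False):
            if row.rule == "alcohol_category":
                cols[row.component] = [0.0, 5.0, 30.0]
            elif row.polarity == "anti_oxidant":
                cols[row.component] = [30.0, 20.0, 10.0]
            else:
                cols[row.component] = [10.0, 20.0, 30.0]
        return pd.DataFrame(cols)

    def test_reference_spec_counts(self):
        spec = default_dobs_spec()
        assert len(spec) == 17
        pol = spec.table["polarity"].value_counts()
        assert pol["anti_oxidant"] == 14 and pol["pro_oxidant"] == 3
        logged = set(spec.table.loc[spec.table["transform"] == "log", "component"])
        assert logged == {"vitamin_c", "beta_carotene", "vitamin_b12"}
        alc = spec.table.loc[spec.table["rule"] == "alcohol_category", "component"]
        assert list(alc) == ["alcohol"]

    def test_extremal_scores_51_and_17(self):
        spec = default_dobs_spec()
        res = compute_dobs(self._extreme_intakes(spec), spec)
        assert res.dobs.iloc[0] == 51
        assert res.dobs.iloc[2] == 17

    def test_score_range_invariant(self, small_frame):
        spec = default_dobs_spec()
        res = compute_dobs(small_frame[spec.components], spec)
        assert res.scores.isin([1, 2, 3]).all().all()
        assert res.dobs.between(17, 51).all()

    def test_log_transform_is_tertile_noop(self, small_frame):
        spec = default_dobs_spec()
        plain = spec.table.copy()
        plain["transform"] = "identity"
        a = compute_dobs(small_frame[spec.components], spec)
        b = compute_dobs(small_frame[spec.components], load_dobs_spec(plain))
        assert (a.dobs == b.dobs).all()

    def test_missing_component_rejected(self, small_frame):
        spec = default_dobs_spec()
        with pytest.raises(KeyError, match="zinc"):
            compute_dobs(small_frame[spec.components].drop(columns=["zinc"]), spec)


class TestClassifyDiet:
    def test_corner_assignments_and_partition(self, rng):
        n = 300
        dii = rng.normal(size=n)
        dobs = rng.normal(size=n)
        classes = classify_diet(dii, dobs)
        t_dii = assign_tertiles(dii)
        t_dobs = assign_tertiles(dobs)
        assert (
            (classes == "pro_inflammatory_pro_oxidative")
            == ((t_dii == 3) & (t_dobs == 1))
        ).all()
        assert (
            (classes == "anti_inflammatory_anti_oxidative")
            == ((t_dii == 1) & (t_dobs == 3))
        ).all()
        # exhaustive and mutually exclusive
        assert classes.notna().all()
        assert set(classes.unique()) <= {
            "pro_inflammatory_pro_oxidative",
            "anti_inflammatory_anti_oxidative",
            "composite",
        }

    def test_middle_tertiles_are_composite(self):
        dii = np.arange(9, dtype=float)
        dobs = np.arange(9, dtype=float)[::-1]
        classes = classify_diet(dii, dobs)
        t = assign_tertiles(dii)
        assert (classes[t == 2] == "composite").all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            classify_diet(np.arange(5.0), np.arange(6.0))
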