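import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metareg.combinations import (
    ContradictionError,
    PlausibilityRules,
    count_plausible,
    enumerate_plausible,
    find_extremes,
    full_grid,
    predict_combination,
    subgroup_search,
)
from metareg.indicators import ALL_INDICATORS
from metareg.model import interaction_name


def toy_rules() -> PlausibilityRules:
    """5-indicator system: 2 time dummies (mutex), 2 behaviour dummies
    (mutex), 1 mechanism indicator (must be 1 able... at least one of one)."""
    return PlausibilityRules(
        indicators=("medium", "long", "diet_and_pa", "pa_only", "participation"),
        mutex_pairs=(("medium", "long"), ("diet_and_pa", "pa_only")),
        at_least_one=(("participation",),),
    )


class TestEnumeration:
    def test_full_24_indicator_count(self):
        # 2^16 free * 3 * 3 (mutex pairs) * 15 (mechanism block)
        assert count_plausible() == 8_847_360
        assert count_plausible() == 2**16 * 3 * 3 * 15

    def test_toy_system_matches_bruteforce_filter(self):
        rules = toy_rules()
        grid = full_grid(rules)
        brute = np.array(list(itertools.product([0, 1], repeat=5)), np.uint8)
        expected = brute[rules.satisfied(brute)]
        got = {tuple(r) for r in grid}
        want = {tuple(r) for r in expected}
        assert got == want
        assert count_plausible(rules) == len(want)

    def test_fixed_columns_constant_in_output(self):
        rules = toy_rules()
        grid = full_grid(rules, fixed={"diet_and_pa": 1})
        j = rules.indicators.index("diet_and_pa")
        assert (grid[:, j] == 1).all()
        assert len(grid) == count_plausible(rules, {"diet_and_pa": 1})

    def test_contradictory_fixed_assignment(self):
        with pytest.raises(ContradictionError):
            count_plausible(fixed={"medium": 1, "long": 1})

    def test_chunking_invariant(self):
        rules = toy_rules()
        a = np.vstack(list(enumerate_plausible(rules, chunk_size=3)))
        b = np.vstack(list(enumerate_plausible(rules, chunk_size=100)))
        np.testing.assert_array_equal(a, b)

    @given(
        st.sets(st.sampled_from(ALL_INDICATORS[:8]), min_size=0, max_size=3),
        st.booleans(),
    )
    @settings(max_examples=30, deadline=None)
    def test_count_closed_form_matches_enumeration(self, fixed_names, value):
        rules = PlausibilityRules(
            indicators=ALL_INDICATORS[:8],
            mutex_pairs=(("diet_and_pa", "pa_only"),),
            at_least_one=(),
        )
        fixed = {name: int(value) for name in fixed_names}
        try:
            n = count_plausible(rules, fixed)
        except ContradictionError:
            return
        total = sum(len(c) for c in enumerate_plausible(rules, fixed))
        assert total == n


class TestPrediction:
    def test_all_zero_row_gives_uncentred_intercept(self):
        coef = pd.Series({"intercept": -0.05, "school": -0.02})
        pred = predict_combination(
            np.zeros((1, len(ALL_INDICATORS))), coef
        )
        assert pred[0] == pytest.approx(-0.05)

    def test_decentring_identity(self):
        coef = pd.Series({"intercept": -0.05, "school": -0.02, "home": 0.03})
        centering = pd.Series({"school": 0.7, "home": 0.4})
        pred = predict_combination(
            np.zeros((1, len(ALL_INDICATORS))), coef, centering=centering
        )
        # alpha_unc = alpha_c - sum(coef * mean)
        assert pred[0] == pytest.approx(-0.05 - (-0.02 * 0.7 + 0.03 * 0.4))

    def test_toggling_indicator_shifts_by_its_coefficient(self):
        coef = pd.Series({"intercept": 0.0, "school": -0.04})
        base = np.zeros((1, len(ALL_INDICATORS)))
        on = base.copy()
        on[0, ALL_INDICATORS.index("school")] = 1
        d = predict_combination(on, coef) - predict_combination(base, coef)
        assert d[0] == pytest.approx(-0.04)

    def test_linear_in_coefficients(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 2, (10, len(ALL_INDICATORS)))
        c1 = pd.Series({"intercept": 0.1, "school": -0.2, "home": 0.05})
        c2 = pd.Series({"intercept": -0.3, "school": 0.4, "home": -0.15})
        lhs = predict_combination(rows, c1 + c2)
        rhs = predict_combination(rows, c1) + predict_combination(rows, c2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_mean_pseudo_row_recovers_centred_intercept(self):
        coef = pd.Series({"intercept": -0.05, "school": -0.02, "home": 0.03})
        centering = pd.Series({"school": 0.7, "home": 0.4})
        row = np.zeros((1, len(ALL_INDICATORS)))
        row[0, ALL_INDICATORS.index("school")] = 0.7
        row[0, ALL_INDICATORS.index("home")] = 0.4
        pred = predict_combination(row, coef, centering=centering)
        assert pred[0] == pytest.approx(coef["intercept"])

    def test_interaction_product_term(self):
        coef = pd.Series({
            "intercept": 0.0, "age_12_18": 0.0, "electronic": 0.0,
            interaction_name("age_12_18", "electronic"): -0.3,
        })
        row = np.zeros((1, len(ALL_INDICATORS)))
        row[0, ALL_INDICATORS.index("age_12_18")] = 1
        row[0, ALL_INDICATORS.index("electronic")] = 1
        pred = predict_combination(
            row, coef, interactions=[("age_12_18", "electronic")]
        )
        assert pred[0] == pytest.approx(-0.3)


class TestExtremes:
    def test_single_coefficient_best_row(self):
        rules = toy_rules()
        coef = pd.Series({"intercept": 0.0, "participation": -0.1})
        prof = find_extremes(coef, rules=rules)
        assert (prof.best_rows["participation"] == 1).all()
        assert prof.best_md == pytest.approx(-0.1)

    def test_bruteforce_sort_oracle_on_small_grid(self):
        rules = toy_rules()
        rng = np.random.default_rng(5)
        names = ["intercept", *rules.indicators]
        coef = pd.Series(rng.normal(0, 0.1, len(names)), index=names)
        prof = find_extremes(coef, rules=rules, tail=0.25)
        grid = full_grid(rules)
        preds = predict_combination(grid, coef, indicators=rules.indicators)
        order = np.argsort(preds, kind="stable")
        k = math.ceil(0.25 * len(grid))
        cut_lo, cut_hi = preds[order[k - 1]], preds[order[-k]]
        lo_rows = grid[preds <= cut_lo]
        hi_rows = grid[preds >= cut_hi]
        np.testing.assert_allclose(
            prof.prevalence_best.to_numpy(), lo_rows.mean(axis=0)
        )
        np.testing.assert_allclose(
            prof.prevalence_worst.to_numpy(), hi_rows.mean(axis=0)
        )
        assert prof.best_md == pytest.approx(preds.min())
        assert prof.worst_md == pytest.approx(preds.max())

    def test_fraction_beneficial_by_hand(self):
        rules = PlausibilityRules(
            indicators=("school", "participation"),
            mutex_pairs=(),
            at_least_one=(("participation",),),
        )
        # rows: (0,1), (1,1); predictions: 0.05 - 0.1*school
        coef = pd.Series({"intercept": 0.05, "school": -0.1})
        prof = find_extremes(coef, rules=rules, tail=0.5)
        assert prof.n_rows == 2
        assert prof.fraction_beneficial == pytest.approx(0.5)

    def test_ties_at_extremes_all_reported(self):
        rules = PlausibilityRules(
            indicators=("school", "participation"),
            mutex_pairs=(),
            at_least_one=(("participation",),),
        )
        coef = pd.Series({"intercept": 0.0})  # all rows tie
        prof = find_extremes(coef, rules=rules)
        assert len(prof.best_rows) == 2
        assert len(prof.worst_rows) == 2


class TestSubgroups:
    def test_subgroup_grids_partition_full_grid(self):
        n_full = count_plausible()
        total = sum(
            count_plausible(fixed={"age_12_18": a, "high_income": h})
            for a in (0, 1) for h in (0, 1)
        )
        assert total == n_full

    def test_subgroup_best_consistent_with_full_grid(self):
        rng = np.random.default_rng(7)
        names = ["intercept", *ALL_INDICATORS]
        coef = pd.Series(rng.normal(0, 0.05, len(names)), index=names)
        full = find_extremes(coef)
        best = full.best_rows.iloc[0]
        sub = subgroup_search(
            coef,
            {"age_12_18": int(best["age_12_18"]),
             "high_income": int(best["high_income"])},
        )
        assert sub.best_md == pytest.approx(full.best_md)

    def test_interaction_flips_marginal_contribution(self):
        # with age fixed to 1, electronic contributes beta + eta
        coef = pd.Series({
            "intercept": 0.0, "electronic": 0.1, "age_12_18": 0.0,
            interaction_name("age_12_18", "electronic"): -0.3,
        })
        ia = [("age_12_18", "electronic")]
        base = np.zeros((1, len(ALL_INDICATORS)))
        base[0, ALL_INDICATORS.index("age_12_18")] = 1
        on = base.copy()
        on[0, ALL_INDICATORS.index("electronic")] = 1
        d = (predict_combination(on, coef, interactions=ia)
             - predict_combination(base, coef, interactions=ia))
        assert d[0] == pytest.approx(0.1 - 0.3)  # sign flipped by eta
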