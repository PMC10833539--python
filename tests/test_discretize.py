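import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, strategies as st

from signet.discretize import (
    CONSTANT,
    DegenerateRangeError,
    SILENT,
    VARIABLE,
    classify_entity,
    discretize_table,
    is_variable,
    level_of,
    pattern_of,
    population_log_means,
    validate_pattern,
)


class TestPopulationLogMeans:
    def test_closed_form_mean_and_log(self):
        table = pd.DataFrame({"s1": [10.0], "s2": [10.0], "s3": [1000.0], "s4": [1000.0]},
                             index=["g"])
        mat = population_log_means(
            table, {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}, pseudocount=0.0
        )
        assert mat.populations == ("A", "B")
        np.testing.assert_allclose(mat.row("g"), [1.0, 3.0])

    def test_single_sample_single_population(self):
        table = pd.DataFrame({"s1": [1.0]}, index=["g"])
        mat = population_log_means(table, {"s1": "A"}, pseudocount=0.0)
        np.testing.assert_allclose(mat.row("g"), [0.0])

    def test_uneven_samples_mean_then_log(self):
        table = pd.DataFrame({"a1": [9.0], "a2": [11.0], "b1": [99.0], "b2": [101.0]},
                             index=["g"])
        mat = population_log_means(
            table, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, pseudocount=0.0
        )
        np.testing.assert_allclose(mat.row("g"), [1.0, 2.0], atol=1e-3)

    def test_unmapped_sample_fails_with_name(self):
        table = pd.DataFrame({"s1": [1.0], "weird": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="weird"):
            population_log_means(table, {"s1": "A"})

    def test_empty_population_fails(self):
        table = pd.DataFrame({"s1": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="B"):
            population_log_means(table, {"s1": "A"}, populations=["A", "B"])

    def test_population_order_is_user_declared(self):
        table = pd.DataFrame({"s1": [10.0], "s2": [100.0]}, index=["g"])
        mat = population_log_means(table, {"s1": "A", "s2": "B"},
                                   populations=["B", "A"], pseudocount=0.0)
        np.testing.assert_allclose(mat.row("g"), [2.0, 1.0])


class TestLevelOf:
    def test_min_maps_to_1(self):
        assert level_of(1.0, 1.0, 4.0) == 1

    def test_max_maps_to_4(self):
        assert level_of(4.0, 1.0, 4.0) == 4

    @pytest.mark.parametrize("value,expected", [(1.1, 1), (2.0, 2)])
    def test_interior_values(self, value, expected):
        assert level_of(value, 1.0, 4.0) == expected

    def test_boundary_tie_gets_lower_level(self):
        # value exactly at k/4 of the range: ceil of an integer
        assert level_of(0.25, 0.0, 1.0) == 1
        assert level_of(0.5, 0.0, 1.0) == 2
        assert level_of(0.75, 0.0, 1.0) == 3

    def test_degenerate_range_raises(self):
        with pytest.raises(DegenerateRangeError):
            level_of(1.0, 1.0, 1.0)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6).filter(
        lambda vs: max(vs) > min(vs)))
    def test_monotone_in_value(self, values):
        vmin, vmax = min(values), max(values)
        levels = [level_of(v, vmin, vmax) for v in sorted(values)]
        assert levels == sorted(levels)


class TestPatternOf:
    def test_two_low_one_intermediate_one_high_gives_1124(self):
        assert pattern_of([1.0, 1.1, 2.0, 4.0], VARIABLE) == "1124"

    def test_silent_all_zero(self):
        assert pattern_of([3.0, 1.0, 2.0, 0.5], SILENT) == "0000"

    def test_constant_all_five(self):
        assert pattern_of([2.0, 2.0, 2.0, 2.0], CONSTANT) == "5555"

    def test_variable_zero_range_errors(self):
        with pytest.raises(DegenerateRangeError, match="constant"):
            pattern_of([2.0, 2.0], VARIABLE)

    def test_too_many_populations_refused(self):
        with pytest.raises(ValueError, match="9"):
            pattern_of(list(range(10)), VARIABLE)

    @given(st.lists(st.floats(-3, 6, allow_nan=False), min_size=2, max_size=8)
           .filter(lambda vs: max(vs) - min(vs) > 1e-6))
    def test_variable_pattern_contains_both_extremes(self, values):
        pat = pattern_of(values, VARIABLE)
        assert is_variable(pat)
        assert pat[int(np.argmin(values))] == "1"
        assert pat[int(np.argmax(values))] == "4"

    @given(st.lists(st.floats(-3, 6, allow_nan=False), min_size=2, max_size=8)
           .filter(lambda vs: max(vs) - min(vs) > 1e-6),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, values, rnd):
        perm = list(range(len(values)))
        rnd.shuffle(perm)
        base = pattern_of(values, VARIABLE)
        permuted = pattern_of([values[i] for i in perm], VARIABLE)
        assert permuted == "".join(base[i] for i in perm)

    @given(st.lists(st.floats(0.5, 1e4, allow_nan=False), min_size=2, max_size=8)
           .filter(lambda vs: math.log10(max(vs)) - math.log10(min(vs)) > 1e-6),
           st.floats(0.1, 1e3))
    def test_scale_invariance(self, raws, factor):
        # a positive scale factor shifts all log-means equally and cancels;
        # skip draws sitting on a bin boundary, where 1-ulp noise is allowed
        # to flip the level
        logs = [math.log10(v) for v in raws]
        lo, hi = min(logs), max(logs)
        for v in logs:
            x = 4 * (v - lo) / (hi - lo)
            assume(abs(x - round(x)) > 1e-9 or x in (0.0, 4.0))
        scaled = [math.log10(v * factor) for v in raws]
        assert pattern_of(logs, VARIABLE) == pattern_of(scaled, VARIABLE)


class TestClassifyEntity:
    def test_all_zero_row_is_silent(self):
        assert classify_entity([0.0, 0.0], [0.0, 0.0]) == SILENT

    def test_flat_row_is_constant(self):
        logm = [2.0043, 2.0043, 2.0043, 2.0043]
        assert classify_entity([100] * 4, logm, constancy_epsilon=0.01) == CONSTANT

    def test_external_label_overrides_heuristic(self):
        # heuristic would say constant; the external label wins
        assert classify_entity([100] * 4, [2.0] * 4, de_label=VARIABLE) == VARIABLE

    def test_bad_external_label_fails(self):
        with pytest.raises(ValueError):
            classify_entity([1.0], [0.0], de_label="sometimes")

    def test_varying_row_is_variable(self):
        assert classify_entity([10, 1000], [1.0, 3.0]) == VARIABLE


class TestDiscretizeTable:
    def test_classes_and_patterns(self, expression_table):
        table, sample_map = expression_table
        out = discretize_table(table, sample_map, pseudocount=0.0)
        by_id = dict(zip(out["entity_id"], zip(out["class"], out["pattern"])))
        assert by_id["g_var"] == (VARIABLE, "14")
        assert by_id["g_silent"] == (SILENT, "00")
        assert by_id["g_const"] == (CONSTANT, "55")
        for pat in out["pattern"]:
            validate_pattern(pat)

    def test_pseudocount_keeps_zeros_finite(self, expression_table):
        table, sample_map = expression_table
        out = discretize_table(table, sample_map, pseudocount=1.0)
        assert set(out["pattern"]) == {"14", "00", "55"}
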