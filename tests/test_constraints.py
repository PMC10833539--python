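import itertools

import pytest

from signet.constraints import (
    DeviationPolicy,
    FAIL,
    PERFECT,
    REGION_VIOLATING,
    RELAXED,
    SignedTriple,
    cell_status,
    cell_status_from_table,
    evaluate_triple,
    filter_and_sign,
    merge_to_tf_gene,
    perfect_gene_level,
)
from signet.graph import CandidateTriple

import helpers

LEVELS = (1, 2, 3, 4)


class TestPerfectGeneLevel:
    def test_full_tf_full_region(self):
        assert perfect_gene_level(4, 4, "+") == 4

    def test_full_tf_closed_region(self):
        assert perfect_gene_level(4, 1, "+") == 1

    @pytest.mark.parametrize("f,r,expected", [(4, 4, 1), (3, 2, 4)])
    def test_negative_mirror(self, f, r, expected):
        assert perfect_gene_level(f, r, "-") == expected

    def test_out_of_domain_level(self):
        with pytest.raises(ValueError):
            perfect_gene_level(5, 4, "+")
        with pytest.raises(ValueError):
            perfect_gene_level(0, 4, "+")

    def test_unique_perfect_pattern_per_sign(self):
        # for any fixed (f, r) pattern pair exactly one gene tuple is
        # all-perfect per sign
        for n in (2, 3):
            for f in itertools.product(LEVELS, repeat=n):
                for r in itertools.product(LEVELS, repeat=n):
                    for sign in ("+", "-"):
                        perfect = [
                            g for g in itertools.product(LEVELS, repeat=n)
                            if all(cell_status(fi, ri, gi, sign) == PERFECT
                                   for fi, ri, gi in zip(f, r, g))
                        ]
                        assert len(perfect) == 1


class TestCellStatus:
    def test_relaxed_cell(self):
        # f=4, r=3: perfect level 3; g=4 is off by one within the region bound
        assert cell_status(4, 3, 4, "+") == RELAXED

    def test_region_violating_cell(self):
        # f=1, r=1: bound max(1, 1-3+2) = 1 < g=2
        assert cell_status(1, 1, 2, "+") == REGION_VIOLATING

    def test_fail_cell(self):
        assert cell_status(4, 4, 1, "+") == FAIL

    def test_table_matches_equations_on_all_cells(self):
        for sign in ("+", "-"):
            for f, r, g in itertools.product(LEVELS, repeat=3):
                assert cell_status(f, r, g, sign) == \
                    cell_status_from_table(f, r, g, sign), (sign, f, r, g)


class TestEvaluateTriple:
    def test_perfect_positive_delta0(self):
        assert evaluate_triple("4441", "4441", "4441", "delta0") == {"+"}

    def test_perfect_negative_delta0(self):
        assert evaluate_triple("4441", "4441", "1114", "delta0") == {"-"}

    def test_one_relaxed_cell_needs_delta1(self):
        assert evaluate_triple("4441", "4431", "4441", "delta0") == frozenset()
        assert evaluate_triple("4441", "4431", "4441", "delta1") == {"+"}

    def test_all_constant_is_nd(self):
        for policy in DeviationPolicy:
            assert evaluate_triple("5555", "5555", "5555", policy) == {"ND"}

    def test_silent_pattern_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            evaluate_triple("0000", "4441", "4441", "delta0")

    def test_mixed_constant_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            evaluate_triple("5555", "4441", "4441", "delta0")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            evaluate_triple("44", "444", "444", "delta0")

    def test_grey_cell_needs_regoff(self):
        # f=1, r=1 in cell 4 makes g=2 region-violating there
        assert evaluate_triple("4441", "4441", "4442", "delta1") == frozenset()
        assert evaluate_triple("4441", "4441", "4442", "delta1_regOFF") == {"+"}

    def test_sum_mode_matches_cells_at_delta0(self):
        for f, r, g in itertools.product(
                itertools.product(LEVELS, repeat=2), repeat=3):
            fp = "".join(map(str, f))
            rp = "".join(map(str, r))
            gp = "".join(map(str, g))
            assert evaluate_triple(fp, rp, gp, "delta0", mode="sum") == \
                evaluate_triple(fp, rp, gp, "delta0", mode="cells")


class TestMirrorAndNesting:
    def test_sign_mirror_symmetry_n2(self):
        masks = helpers.exhaustive_bitmasks(2)
        for (f, r, g), mask in masks.items():
            mirrored = masks[(f, r, tuple(5 - x for x in g))]
            for policy in helpers.POLICIES:
                assert helpers.admitted(mask, policy, "+") == \
                    helpers.admitted(mirrored, policy, "-")

    def test_policy_nesting_n2(self):
        for mask in helpers.exhaustive_bitmasks(2).values():
            for sign in "+-":
                d0 = helpers.admitted(mask, DeviationPolicy.delta0, sign)
                d1 = helpers.admitted(mask, DeviationPolicy.delta1, sign)
                d1off = helpers.admitted(mask, DeviationPolicy.delta1_regOFF, sign)
                d2 = helpers.admitted(mask, DeviationPolicy.delta2, sign)
                assert not d0 or d1
                assert not d1 or d1off
                assert not d1 or d2


class TestFilterAndSign:
    def _triple(self, tf_pat, reg_pat, gene_pat, tf="TF1", region="R1", gene="G1"):
        return CandidateTriple(tf, region, gene, tf_pat, reg_pat, gene_pat, 0)

    def test_empty_input_empty_output(self):
        assert filter_and_sign([], "delta0") == []

    def test_perfect_triples_survive_with_sign(self):
        out = filter_and_sign([self._triple("4441", "4444", "4441")], "delta0")
        assert [(r.gene_id, r.sign) for r in out] == [("G1", "+")]

    def test_silent_triples_dropped(self):
        assert filter_and_sign([self._triple("1114", "4441", "0000")], "delta2") == []

    def test_constant_triples_kept_as_nd(self):
        out = filter_and_sign([self._triple("5555", "5555", "5555")], "delta0")
        assert [r.sign for r in out] == ["ND"]

    def test_output_subset_of_input(self):
        triples = [
            self._triple("4441", "4444", "4441", gene=f"G{i}") for i in range(3)
        ] + [self._triple("4441", "4444", "2222", gene="G9")]
        out = filter_and_sign(triples, "delta1")
        assert {r.gene_id for r in out} <= {t.gene_id for t in triples}
        assert "G9" not in {r.gene_id for r in out}


class TestMergeToTfGene:
    def _signed(self, tf, gene, sign, region):
        return SignedTriple(tf, region, gene, sign, "4441", "4444", "4441", 0)

    def test_same_pair_through_three_regions_merges(self):
        signed = [self._signed("TF1", "G1", "+", f"R{i}") for i in range(3)]
        merged = merge_to_tf_gene(signed)
        assert len(merged) == 1
        assert merged[0].regions == ("R0", "R1", "R2")
        assert not merged[0].conflicting

    def test_opposite_signs_flagged_conflicting(self):
        signed = [self._signed("TF1", "G1", "+", "R1"),
                  self._signed("TF1", "G1", "-", "R2")]
        merged = merge_to_tf_gene(signed)
        assert len(merged) == 2
        assert all(m.conflicting for m in merged)

    def test_disjoint_pairs_preserved(self):
        signed = [self._signed(f"TF{i}", f"G{i}", "+", "R1") for i in range(4)]
        assert len(merge_to_tf_gene(signed)) == 4
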