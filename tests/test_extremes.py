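"""Closed-form extremal values vs brute-force enumeration."""

import math

import pytest

import metabalance as mb


class TestCollessMin:
    def test_zero_exactly_at_powers_of_two(self):
        for h in range(0, 7):
            assert mb.colless_min(2 ** h) == 0
        for n in (5, 6, 7, 9, 11):
            assert mb.colless_min(n) >= 2

    def test_matches_enumerated_minimum(self):
        for n in range(1, 13):
            enumerated = min(mb.colless(t) for t in mb.enumerate_binary_shapes(n))
            assert mb.colless_min(n) == enumerated


class TestSackinExtremes:
    def test_known_values(self):
        assert mb.sackin_extremes(6)[0] == 16
        assert mb.sackin_extremes(8)[0] == 24  # h * 2^h at a power of two
        assert mb.sackin_extremes(5)[1] == 14

    def test_matches_enumeration_and_gfb(self):
        for n in range(1, 11):
            values = [mb.sackin(t) for t in mb.enumerate_binary_shapes(n)]
            smin, smax = mb.sackin_extremes(n)
            assert (smin, smax) == (min(values), max(values))
            assert mb.sackin(mb.greedy_from_bottom(n)) == smin


class TestSubtreeCounts:
    def test_gfb_closed_form_matches_constructed_tree(self):
        for n in range(1, 65):
            tree = mb.greedy_from_bottom(n)
            counts = {}
            for v in tree.preorder():
                counts[v.n] = counts.get(v.n, 0) + 1
            for i in range(1, n + 1):
                assert mb.gfb_subtree_count(n, i) == counts.get(i, 0), (n, i)

    def test_gfb_examples_and_bounds(self):
        assert mb.gfb_subtree_count(6, 2) == 3
        assert mb.gfb_subtree_count(5, 4) == 0
        for n in (1, 4, 9):
            assert mb.gfb_subtree_count(n, n) == 1
        with pytest.raises(ValueError):
            mb.gfb_subtree_count(5, 6)

    def test_mb_counts(self):
        assert mb.mb_subtree_count(5, 2) == 2
        assert mb.mb_subtree_count(8, 4) == 2
        for n in (1, 6, 13):
            assert mb.mb_subtree_count(n, n) == 1
            assert mb.mb_subtree_count(n, 1) == n

    def test_mb_decomposition_remainder(self):
        assert mb.mb_decomposition_remainder(13, 2) == 1
        assert mb.mb_decomposition_remainder(8, 3) == 0


class TestClosedFormReports:
    def test_bvm_identity_n5(self):
        report = mb.bvm_extremes(mb.identity, 5)
        assert report.min_value == pytest.approx(2)
        assert report.max_value == pytest.approx(6)

    def test_bvm_square_n4_minimized_uniquely_by_fb(self):
        report = mb.extremal_sets_by_enumeration(
            mb.Metaconcept("B", mb.from_expression("x*x")), 4)
        assert report.minimizers == (mb.fully_balanced(2).key,)
        assert report.max_value == pytest.approx(5)
        assert report.maximizers == (mb.caterpillar(4).key,)

    def test_bvm_min_at_powers_of_two_for_any_increasing_f(self, battery):
        for f in battery.values():
            if f.domain_min > 0:
                continue
            for h in (2, 3):
                n = 2 ** h
                assert mb.bvm_extremes(f, n).min_value == \
                    pytest.approx((n - 1) * f(0))

    def test_csm_piecewise_f3_fb_not_minimizer_at_8(self, paper_functions):
        report = mb.csm_extremes(paper_functions["f3"], 8)
        assert report.method == "enumeration"
        assert report.min_value == pytest.approx(29)
        assert mb.fully_balanced(3).key not in report.minimizers

    def test_csm_arbitrary_identity_min_is_f_of_n_at_star(self):
        report = mb.csm_extremes(mb.identity, 6, domain="arbitrary")
        assert report.min_value == pytest.approx(6)
        assert report.minimizers == (mb.star(6).key,)

    def test_csm_sqrt_min_is_gfb_weighted_sum(self, battery):
        f = battery["sqrt"]
        n = 6
        expected = sum(mb.gfb_subtree_count(n, i) * math.sqrt(i)
                       for i in range(2, n + 1))
        report = mb.csm_extremes(f, n)
        assert report.min_value == pytest.approx(expected)
        assert report.minimizers == (mb.greedy_from_bottom(n).key,)
        enum = mb.extremal_sets_by_enumeration(mb.Metaconcept("N", f), n)
        assert enum.minimizers == (mb.greedy_from_bottom(n).key,)

    def test_ldm_identity_n6(self):
        report = mb.ldm_extremes(mb.identity, 6)
        assert report.min_value == pytest.approx(16)
        assert report.max_value == pytest.approx(20)  # = S(cat_6)

    def test_ldm_arbitrary_min_is_n_f1_at_star(self, battery):
        for name in ("identity", "square", "3x+1"):
            f = battery[name]
            report = mb.ldm_extremes(f, 7, domain="arbitrary")
            assert report.min_value == pytest.approx(7 * f(1))
            assert report.minimizers == (mb.star(7).key,)


class TestEnumeratedSets:
    def test_sackin_argmin_set_at_12_matches_known_catalogue(self):
        report = mb.extremal_sets_by_enumeration(
            mb.Metaconcept("N", mb.identity), 12)
        assert len(report.minimizers) == 5
        assert mb.greedy_from_bottom(12).key in report.minimizers
        assert mb.maximally_balanced(12).key in report.minimizers

    def test_colless_argmin_at_12_is_sackin_argmin_minus_one(self):
        sack = set(mb.extremal_sets_by_enumeration(
            mb.Metaconcept("N", mb.identity), 12).minimizers)
        coll = set(mb.extremal_sets_by_enumeration(
            mb.Metaconcept("B", mb.identity), 12).minimizers)
        assert coll < sack
        assert len(coll) == 4
        assert {mb.greedy_from_bottom(12).key, mb.maximally_balanced(12).key} <= coll

    def test_quadratic_colless_argmin_unique_at_powers_of_two(self):
        report = mb.extremal_sets_by_enumeration(
            mb.Metaconcept("B", mb.from_expression("x*x")), 8)
        assert report.minimizers == (mb.fully_balanced(3).key,)

    def test_constructive_sackin_argmin_matches_enumeration_filter(self):
        for n in range(2, 11):
            smin = mb.sackin_extremes(n)[0]
            by_filter = {t.key for t in mb.enumerate_binary_shapes(n)
                         if mb.sackin(t) == smin}
            constructive = {t.key for t in mb.sackin_min_shapes(n)}
            assert constructive == by_filter

    def test_argmin_subtrees_are_themselves_argmin(self):
        """Locality consequence: every pending subtree of a Sackin/Colless
        minimizer is a minimizer at its own leaf count."""
        mins_by_n_sackin = {}
        mins_by_n_colless = {}
        for n in range(1, 13):
            mins_by_n_sackin[n] = {t.key for t in mb.sackin_min_shapes(n)}
            mins_by_n_colless[n] = {t.key for t in mb.colless_min_shapes(n)}
        for n in (11, 12):
            for key_set, mins in ((mins_by_n_sackin, mins_by_n_sackin),
                                  (mins_by_n_colless, mins_by_n_colless)):
                for key in key_set[n]:
                    tree = next(t for t in mb.enumerate_binary_shapes(n)
                                if t.key == key)
                    for v in tree.preorder():
                        assert v.key in mins[v.n]


class TestCoincidence:
    def test_minimal_n_for_different_balance_equal_depth(self):
        assert mb.minimal_sequence_coincidence("Bneq", "Deq") == 6

    def test_witness_pair_really_satisfies_predicates(self):
        t1, t2 = mb.find_coincident_pair(6, "Bneq", "Deq")
        assert t1 != t2
        assert mb.balance_sequence(t1).values != mb.balance_sequence(t2).values
        assert mb.leaf_depth_sequence(t1).values == mb.leaf_depth_sequence(t2).values

    def test_unsatisfiable_raises_within_bound(self):
        with pytest.raises(ValueError):
            mb.minimal_sequence_coincidence("Beq", "Neq", n_max=5)
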