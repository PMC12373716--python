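"""Metaconcept evaluation, induced classical indices, recursion, equivalence."""

import math
import random

import pytest

import metabalance as mb
from metabalance.expressions import ExpressionError

from conftest import cophenetic_by_leaf_pairs


class TestEvaluate:
    def test_empty_sum_conventions_on_single_vertex(self):
        f = mb.identity
        assert mb.evaluate(mb.Metaconcept("B", f), mb.LEAF) == 0
        assert mb.evaluate(mb.Metaconcept("N", f, "arbitrary"), mb.LEAF) == 0
        # the leaf depth sequence of the single vertex is (0)
        assert mb.evaluate(mb.Metaconcept("D", f, "arbitrary"), mb.LEAF) == 0

    def test_balance_kind_rejects_non_binary(self):
        with pytest.raises(mb.NonBinaryError):
            mb.evaluate(mb.Metaconcept("B", mb.identity), mb.star(4))
        with pytest.raises(ValueError):
            mb.Metaconcept("B", mb.identity, "arbitrary")

    def test_domain_error_names_the_entry(self):
        f = mb.ShapeFunction("log(x-1)", lambda x, n=None, ninner=None: math.log(x - 1),
                             domain_min=2)
        with pytest.raises(mb.DomainError, match="entry 0"):
            mb.evaluate(mb.Metaconcept("B", f), mb.fully_balanced(2))

    def test_second_order_function_receives_n(self):
        # average leaf depth = second-order LDM with f(d, n) = d / n
        f = mb.ShapeFunction("d/n", lambda x, n=None, ninner=None: x / n,
                             extras=("n",))
        t = mb.caterpillar(6)
        assert mb.evaluate(mb.Metaconcept("D", f, "arbitrary"), t) == \
            pytest.approx(mb.average_leaf_depth(t))


class TestInducedIndices:
    """The Table-1/2 indices equal the metaconcept route with their f."""

    def test_sackin_closed_form_on_caterpillar(self):
        for n in (2, 5, 8):
            assert mb.sackin(mb.caterpillar(n)) == n * (n + 1) // 2 - 1
        assert mb.sackin(mb.caterpillar(8)) == 35

    def test_total_cophenetic_examples(self):
        assert mb.total_cophenetic(mb.caterpillar(4)) == 4
        assert mb.total_cophenetic(mb.star(9)) == 0

    def test_s_hat_of_star_is_single_log(self):
        for n in (3, 6, 10):
            assert mb.s_hat(mb.star(n)) == pytest.approx(math.log(n - 1))

    def test_colless_examples(self):
        for h in (1, 2, 3):
            assert mb.colless(mb.fully_balanced(h)) == 0
        assert mb.colless(mb.caterpillar(5)) == 6
        assert mb.corrected_colless(mb.caterpillar(4)) == pytest.approx(1.0)
        assert mb.corrected_colless(mb.caterpillar(2)) == 0.0
        assert mb.quadratic_colless(mb.caterpillar(4)) == 5

    def test_metaconcept_route_reproduces_direct_definitions(self):
        f_avg = mb.ShapeFunction("nv/n", lambda x, n=None, ninner=None: x / n,
                                 extras=("n",))
        f_shat = mb.ShapeFunction("log(nv-1)",
                                  lambda x, n=None, ninner=None: math.log(x - 1),
                                  domain_min=2)
        f_tci = mb.ShapeFunction(
            "C(nv,2)-C(n,2)/ninner",
            lambda x, n=None, ninner=None: math.comb(x, 2) - math.comb(n, 2) / ninner,
            extras=("n", "ninner"))
        f_ic = mb.ShapeFunction(
            "2b/((n-1)(n-2))",
            lambda x, n=None, ninner=None: 2 * x / ((n - 1) * (n - 2)),
            extras=("n",))
        sq = mb.from_expression("x*x")
        for n in range(2, 8):
            for t in mb.enumerate_arbitrary_shapes(n):
                assert mb.evaluate(mb.Metaconcept("N", mb.identity, "arbitrary"), t) \
                    == pytest.approx(mb.sackin(t))
                assert mb.evaluate(mb.Metaconcept("D", mb.identity, "arbitrary"), t) \
                    == pytest.approx(mb.sackin(t))
                assert mb.evaluate(mb.Metaconcept("N", f_avg, "arbitrary"), t) \
                    == pytest.approx(mb.average_leaf_depth(t))
                assert mb.evaluate(mb.Metaconcept("N", f_shat, "arbitrary"), t) \
                    == pytest.approx(mb.s_hat(t))
                assert mb.evaluate(mb.Metaconcept("N", f_tci, "arbitrary"), t) \
                    == pytest.approx(mb.total_cophenetic(t))
            for t in mb.enumerate_binary_shapes(n):
                assert mb.evaluate(mb.Metaconcept("B", mb.identity), t) \
                    == pytest.approx(mb.colless(t))
                assert mb.evaluate(mb.Metaconcept("B", sq), t) \
                    == pytest.approx(mb.quadratic_colless(t))
                if n > 2:
                    assert mb.evaluate(mb.Metaconcept("B", f_ic), t) \
                        == pytest.approx(mb.corrected_colless(t))

    def test_total_cophenetic_equals_leaf_pair_lca_sum(self):
        # clade-size formulation vs the original pairwise-LCA definition
        for n in range(2, 8):
            for t in mb.enumerate_arbitrary_shapes(n):
                assert mb.total_cophenetic(t) == cophenetic_by_leaf_pairs(t)


class TestRecursiveEvaluate:
    def test_bvm_recursion_on_fb3(self):
        f = mb.from_expression("x*x + 1")
        t = mb.fully_balanced(3)
        assert mb.recursive_evaluate(mb.Metaconcept("B", f), t) == \
            pytest.approx(mb.evaluate(mb.Metaconcept("B", f), t)) == 7.0

    def test_csm_recursion_with_identity_is_sackin(self):
        t = mb.caterpillar(5)
        assert mb.recursive_evaluate(mb.Metaconcept("N", mb.identity, "arbitrary"), t) \
            == pytest.approx(14.0) == mb.sackin(t)

    def test_ldm_recursion_affine_zero_intercept(self):
        f = mb.affine(2.0, 0.0)
        t = mb.star(4)
        assert mb.recursive_evaluate(mb.Metaconcept("D", f, "arbitrary"), t) == \
            pytest.approx(8.0) == 2 * mb.sackin(t)

    def test_ldm_recursion_rejects_non_qualifying_f(self):
        for f in (mb.affine(2.0, 7.0), mb.from_expression("x*x")):
            with pytest.raises(mb.UnsupportedRecursionError):
                mb.recursive_evaluate(mb.Metaconcept("D", f, "arbitrary"),
                                      mb.caterpillar(4))

    def test_recursive_matches_direct_on_random_trees(self, battery):
        rng = random.Random(5)
        f_bn = [f for f in battery.values() if f.domain_min == 0]
        for _ in range(50):
            n = rng.randint(1, 14)
            tb = mb.random_binary_shape(n, rng)
            ta = mb.random_arbitrary_shape(n, rng)
            for f in f_bn:
                mB = mb.Metaconcept("B", f)
                mN = mb.Metaconcept("N", f, "arbitrary")
                assert mb.recursive_evaluate(mB, tb) == \
                    pytest.approx(mb.evaluate(mB, tb), rel=1e-9)
                assert mb.recursive_evaluate(mN, ta) == \
                    pytest.approx(mb.evaluate(mN, ta), rel=1e-9)
            mD = mb.Metaconcept("D", mb.affine(3.0, 0.0), "arbitrary")
            assert mb.recursive_evaluate(mD, ta) == \
                pytest.approx(mb.evaluate(mD, ta), rel=1e-9)


class TestEquivalence:
    def test_corrected_colless_equivalent_to_colless(self):
        assert mb.equivalent_on(mb.colless, mb.corrected_colless, 6)

    def test_average_leaf_depth_equivalent_to_sackin(self):
        assert mb.equivalent_on(mb.sackin, mb.average_leaf_depth, 7)

    def test_s_hat_base_change_preserves_ranking(self):
        assert mb.equivalent_on(mb.s_hat, lambda t: mb.s_hat(t, base=10.0), 7)

    def test_affine_csm_not_sackin_equivalent_on_arbitrary_trees(self):
        plus2 = mb.Metaconcept("N", mb.affine(1.0, 2.0), "arbitrary")
        report = mb.equivalent_on(mb.sackin, plus2.__call__, 8, domain="arbitrary")
        assert not report.equivalent
        # ... although it is Sackin-equivalent on binary trees
        assert mb.equivalent_on(mb.sackin, plus2.__call__, 8, domain="binary")

    def test_index_is_equivalent_to_itself(self):
        assert mb.equivalent_on(mb.sackin, mb.sackin, 6)


class TestDominanceTransfer:
    def test_entrywise_domination_implies_ordered_values(self, battery):
        """If Seq(T) <= Seq(T') entrywise then Phi_f(T) <= Phi_f(T') for
        every increasing f (the transfer lemma behind every extremal proof)."""
        funcs = [(name, f) for name, f in battery.items()]
        for n in (6, 9):
            shapes = mb.enumerate_binary_shapes(n)
            for kind in ("B", "N", "D"):
                seqs = [mb.sequences.extract(kind, t) for t in shapes]
                for i in range(len(shapes)):
                    for j in range(i + 1, len(shapes)):
                        verdict = mb.dominance(seqs[i], seqs[j])
                        if verdict.relation not in ("a_dominates", "equal"):
                            continue
                        for name, f in funcs:
                            if any(v < f.domain_min for v in seqs[i].values):
                                continue
                            concept = mb.Metaconcept(kind, f,
                                                     "binary")
                            lo = mb.evaluate(concept, shapes[i])
                            hi = mb.evaluate(concept, shapes[j])
                            assert lo <= hi + 1e-9, (kind, name, n)


class TestExpressions:
    def test_piecewise_and_math_functions(self):
        f = mb.from_expression("x if x <= 3 else x + 2")
        assert [f(x) for x in range(6)] == [0, 1, 2, 3, 6, 7]
        g = mb.from_expression("log2(1.5*x + 1)")
        assert g(2) == pytest.approx(2.0)

    @pytest.mark.parametrize("bad", [
        "__import__('os')", "x.__class__", "open('f')", "lambda x: x",
        "[x for x in range(3)]", "y + 1", "x; 1",
    ])
    def test_unsafe_expressions_rejected(self, bad):
        with pytest.raises(ExpressionError):
            mb.from_expression(bad)
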