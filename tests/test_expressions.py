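"""Expression-tree semantics: evaluation, lifting, pruning, serialization."""

import numpy as np
import pytest

import gpkin.expressions as ex
from gpkin.exceptions import ArityError, ParseError, PruneError
from gpkin.gp import GPConfig, crossover, mutate, random_tree
from gpkin.reference_models import (BEST_MODEL, PRUNED_MODEL,
                                    sinusoid_branch_path)


def random_trees(n, seed=0, max_depth=5):
    rng = np.random.default_rng(seed)
    cfg = GPConfig(population_size=1)
    return [random_tree(rng, int(rng.integers(1, max_depth + 1)),
                        ["grow", "full"][int(rng.integers(2))], cfg)
            for _ in range(n)]


class TestEvaluate:
    def test_concentration_zero_annihilates_reference_models(self):
        # every additive term of both reference models carries a factor C0
        for model in (BEST_MODEL, PRUNED_MODEL):
            vals = model.uptake(0.0, np.array([0.0, 1.0, 3.0, 15.0]))
            assert np.all(vals == 0.0)

    def test_matches_arbitrary_precision_oracle_on_smooth_model(self):
        # float64 evaluation agrees with exact-rational evaluation wherever
        # no huge trig argument is involved
        for c0, t in [(20.0, 3.0), (5.0, 15.0), (48.0, 3.0), (7.3, 9.1)]:
            f64 = float(PRUNED_MODEL.uptake(c0, t))
            exact = PRUNED_MODEL.uptake_exact(c0, t)
            assert f64 == pytest.approx(exact, rel=1e-12)

    def test_singular_points_flagged_not_masked(self):
        assert not np.isfinite(ex.evaluate(ex.parse("ln(C0)"), 0.0, 1.0))
        assert not np.isfinite(ex.evaluate(ex.parse("C0/t"), 1.0, 0.0))
        assert not np.isfinite(ex.evaluate(ex.parse("exp(t)"), 0.0, 1e6))

    def test_power_is_real_valued(self):
        tree = ex.parse("C0^t")
        assert float(ex.evaluate(tree, -2.0, 3.0)) == -8.0
        assert not np.isfinite(ex.evaluate(tree, -2.0, 0.5))

    def test_repeated_calls_identical(self):
        tree = BEST_MODEL.tree
        a = ex.evaluate(tree, 20.0, 3.0, BEST_MODEL.beta_mse)
        b = ex.evaluate(tree, 20.0, 3.0, BEST_MODEL.beta_mse)
        assert float(a) == float(b)

    def test_beta_length_mismatch_raises(self):
        with pytest.raises(ArityError):
            ex.evaluate(ex.parse("b1*C0"), 1.0, 1.0, [1.0, 2.0])

    def test_compiled_evaluator_matches_reference(self):
        for tree in random_trees(50, seed=3):
            names = ex.param_names(tree)
            fn = ex.compile_evaluator(tree, names)
            c0 = np.array([0.5, 2.0, 20.0])
            t = np.array([1.0, 3.0, 15.0])
            ref = ex.evaluate(tree, c0, t)
            got = np.broadcast_to(np.asarray(fn(c0, t, ()), float), ref.shape)
            np.testing.assert_array_equal(np.isfinite(ref), np.isfinite(got))
            finite = np.isfinite(ref)
            np.testing.assert_array_equal(got[finite], ref[finite])


class TestParameterize:
    def test_no_constants_is_identity(self):
        tree = ex.parse("C0*t")
        lifted, beta0 = ex.parameterize(tree)
        assert lifted == tree
        assert beta0 == []

    def test_constants_become_slots_in_reading_order(self):
        lifted, beta0 = ex.parameterize(ex.parse("5.0*C0 + 10.0"))
        assert ex.param_names(lifted) == ["b1", "b2"]
        assert beta0 == [5.0, 10.0]

    def test_substitute_round_trip_preserves_evaluation(self, rng):
        for tree in random_trees(30, seed=9):
            lifted, beta0 = ex.parameterize(tree)
            back = ex.substitute(lifted, beta0)
            assert back == tree
            c0 = rng.uniform(0.1, 30, 100)
            t = rng.uniform(0.1, 15, 100)
            a, b = ex.evaluate(tree, c0, t), ex.evaluate(back, c0, t)
            finite = np.isfinite(a)
            np.testing.assert_array_equal(finite, np.isfinite(b))
            np.testing.assert_array_equal(a[finite], b[finite])


class TestPrune:
    def test_best_model_minus_sinusoid_branch_is_pruned_model(self):
        tree = BEST_MODEL.tree
        path = sinusoid_branch_path(tree)
        assert ex.prune(tree, path) == PRUNED_MODEL.tree

    def test_prune_leaf_of_binary_leaves_sibling(self):
        tree = ex.parse("C0 + t")
        assert ex.prune(tree, (0,)) == ex.parse("t")
        assert ex.prune(tree, (1,)) == ex.parse("C0")

    def test_prune_under_unary_parent_raises(self):
        with pytest.raises(PruneError):
            ex.prune(ex.parse("sin(C0)"), (0,))
        with pytest.raises(PruneError):
            ex.prune(ex.parse("C0"), ())

    def test_node_count_strictly_decreases(self):
        tree = BEST_MODEL.tree
        pruned = ex.prune(tree, sinusoid_branch_path(tree))
        assert pruned.size() < tree.size()

    def test_additive_branch_identity(self, rng):
        # full - pruned == removed branch, for a top-level additive branch
        full = ex.parse("(2.0*C0)*t + sin(3.0*t)")
        removed = full.node_at((1,))
        pruned = ex.prune(full, (1,))
        c0 = rng.uniform(0, 25, 100)
        t = rng.uniform(0, 15, 100)
        diff = ex.evaluate(full, c0, t) - ex.evaluate(pruned, c0, t)
        np.testing.assert_allclose(diff, ex.evaluate(removed, c0, t),
                                   rtol=1e-10, atol=1e-12)


class TestConservedFraction:
    def test_self_comparison_is_one(self):
        tree = BEST_MODEL.tree
        assert ex.conserved_fraction(tree, [tree]) == 1.0

    def test_disjoint_root_symbol_is_zero(self):
        assert ex.conserved_fraction(ex.parse("C0"), [ex.parse("t")]) == 0.0

    def test_matches_brute_force_positional_comparison(self):
        def brute(ref, members):
            def collect(node, path, out):
                out[path] = (node.kind, node.value)
                for i, c in enumerate(node.children):
                    collect(c, path + (i,), out)
            ref_pos, mem_pos = {}, []
            collect(ref, (), ref_pos)
            for m in members:
                d = {}
                collect(m, (), d)
                mem_pos.append(d)
            hits = sum(
                all(d.get(p) == s for d in mem_pos)
                for p, s in ref_pos.items())
            return hits / len(ref_pos)

        trees = random_trees(12, seed=21)
        ref = trees[0]
        for subset in ([trees[1]], trees[2:5], trees):
            assert ex.conserved_fraction(ref, subset) == pytest.approx(
                brute(ref, subset))

    def test_pruned_model_share_of_best_model_nodes(self):
        # the pruned tree conserves all but the sinusoid branch's nodes
        frac = ex.conserved_fraction(PRUNED_MODEL.tree, [BEST_MODEL.tree])
        assert 0.5 < frac < 1.0


class TestSerialization:
    def test_reference_expression_parses_with_expected_slots(self):
        tree = ex.parse(PRUNED_MODEL.expression)
        assert ex.param_names(tree) == ["b1", "b6", "b3", "b5", "b4"]
        assert ex.parse("C0") == ex.variable("C0")

    def test_round_trip_500_random_trees(self):
        for tree in random_trees(500, seed=4):
            assert ex.parse(ex.serialize(tree)) == tree

    def test_json_round_trip(self):
        for tree in random_trees(50, seed=5):
            assert ex.from_json(ex.to_json(tree)) == tree

    @pytest.mark.parametrize("bad", ["C0 +", "sin(", "1..2 * t", "C0 ** t",
                                     "foo(", ")", "C0 t"])
    def test_malformed_strings_raise_with_position(self, bad):
        with pytest.raises(ParseError):
            ex.parse(bad)


class TestVariationOperators:
    def test_crossover_and_mutation_preserve_arity_validity(self):
        rng = np.random.default_rng(11)
        cfg = GPConfig(population_size=1)
        trees = random_trees(40, seed=6)
        for i in range(0, 38, 2):
            c1, c2 = crossover(trees[i], trees[i + 1], rng)
            m = mutate(trees[i], rng, cfg)
            for t in (c1, c2, m):
                # Node construction enforces arity; a full walk must succeed
                assert t.size() >= 1
                assert ex.parse(ex.serialize(t)) == t
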