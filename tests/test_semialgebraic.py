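import numpy as np
import pytest
import sympy as sp

import golden_systems as G
from algmle.group_fourier import Z2, LabelingFunction, pattern_index
from algmle.model_param import (
    EdgeRateVector,
    RootedTree,
    leaf_fourier_distribution,
    parametrize_leaf_distribution,
)
from algmle.semialgebraic import (
    cfn_tripod_invariants,
    edge_square_candidates,
    internal_edge_square,
    leaf_edge_square,
    model_constraints,
    normalize_poly,
    p_symbols,
    poly_key,
    q_symbols,
    to_p_coordinates,
    toric_invariants,
)
from conftest import random_interior_fchecks


@pytest.fixture(scope="module")
def case1_q(rerooted_tripod, labeling):
    return model_constraints(rerooted_tripod, Z2, labeling, "biased0")


class TestToricInvariants:
    def test_elimination_matches_known_binomials(self, rerooted_tripod):
        inv = toric_invariants(rerooted_tripod, Z2, "biased0")
        qs = q_symbols(Z2, 3)
        gb1 = sp.groebner(inv, *qs, order="grevlex")
        gb2 = sp.groebner(cfn_tripod_invariants(), *qs, order="grevlex")
        assert set(gb1.exprs) == set(gb2.exprs)

    def test_uniform_appends_parity_forms(self, tripod):
        inv = toric_invariants(tripod, Z2, "uniform")
        qs = q_symbols(Z2, 3)
        odd = {qs[i] for i in (1, 2, 4, 7)}
        assert odd <= set(inv)

    def test_two_leaf_tree(self):
        t = RootedTree.from_newick("(1,2);")
        biased = toric_invariants(t, Z2, "biased0")
        assert biased == []  # the generic-root map on two leaves has trivial kernel
        uniform = toric_invariants(t, Z2, "uniform")
        qs = q_symbols(Z2, 2)
        assert set(uniform) == {qs[1], qs[2]}  # only the parity linear forms

    def test_invariants_vanish_on_parametrized_points(self, rerooted_tripod):
        rng = np.random.default_rng(21)
        qs = q_symbols(Z2, 3)
        inv = cfn_tripod_invariants()
        for _ in range(100):
            fc = random_interior_fchecks(rng)
            dist = leaf_fourier_distribution(rerooted_tripod, fc, Z2, "biased0")
            sub = dict(zip(qs, dist.q))
            for e in inv:
                assert sp.expand(e.subs(sub)) == 0  # exact rational arithmetic


class TestEdgeSquares:
    def test_hidden_root_leaf_formula(self, rerooted_tripod):
        sq = leaf_edge_square(rerooted_tripod, "root", (1,), Z2)
        ni, di = sq.indices(Z2)
        assert sorted(ni) == [2, 4] and di == [6]  # q100*q010 / q110

    def test_leaf3_formula(self, rerooted_tripod):
        sq = leaf_edge_square(rerooted_tripod, "e3", (1,), Z2)
        ni, di = sq.indices(Z2)
        assert sorted(ni) == [3, 5] and di == [6]  # q101*q011 / q110

    def test_evaluation_equals_forward_square(self, rerooted_tripod):
        rng = np.random.default_rng(31)
        for _ in range(25):
            fc = random_interior_fchecks(rng)
            dist = leaf_fourier_distribution(rerooted_tripod, fc, Z2, "biased0")
            for name in ("root", "e1", "e2", "e3"):
                sq = leaf_edge_square(rerooted_tripod, name, (1,), Z2)
                val = sq.evaluate(dist.q, Z2)
                assert sp.nsimplify(val) == fc[name][1] ** 2  # exact

    def test_all_candidates_agree_on_interior(self, rerooted_tripod):
        fc = random_interior_fchecks(np.random.default_rng(7))
        dist = leaf_fourier_distribution(rerooted_tripod, fc, Z2, "biased0")
        qf = dist.q_float()
        for name in ("root", "e1", "e2", "e3"):
            vals = []
            for ni, di in edge_square_candidates(rerooted_tripod, name, (1,), Z2):
                vals.append(np.prod(qf[ni]) / np.prod(qf[di]))
            assert np.allclose(vals, vals[0], rtol=1e-12)

    def test_tripod_has_no_internal_edges(self, rerooted_tripod):
        with pytest.raises(ValueError):
            internal_edge_square(rerooted_tripod, "e1", (1,), Z2)

    def test_quartet_internal_edge_square(self):
        t = RootedTree.from_newick("((1,2),(3,4));").rerooted()
        internal = [e for e in t.edges if not (e.is_leaf_edge or e.is_root_edge)][0]
        sq = internal_edge_square(t, internal, (1,), Z2)
        assert len(sq.numerator) == 2 and len(sq.denominator) == 2
        # oracle: evaluates to the forward squared parameter
        rng = np.random.default_rng(13)
        fc = {e.name: [sp.Integer(1), sp.Rational(int(rng.integers(1, 99)), 100)]
              for e in t.edges}
        dist = leaf_fourier_distribution(t, fc, Z2, "biased0")
        val = sq.evaluate(dist.q, Z2)
        assert sp.nsimplify(val) == fc[internal.name][1] ** 2


class TestConstraintSystems:
    def test_case1_q_level_inequalities(self, case1_q):
        qs = case1_q.variables
        got = frozenset(poly_key(e, qs, orient=True) for e in case1_q.nonstrict)
        want = frozenset(
            poly_key(sp.sympify(s), qs, orient=True) for s in G.CASE1_Q_NONSTRICT
        )
        assert got == want

    def test_strict_positivity_set(self, case1_q):
        assert len(case1_q.strict) == 7  # every non-identity Fourier coordinate

    def test_asymmetric_labeling_rejected(self, rerooted_tripod):
        from algmle.group_fourier import FiniteAbelianGroup

        g3 = FiniteAbelianGroup([3])
        with pytest.raises((ValueError, NotImplementedError)):
            model_constraints(rerooted_tripod, g3, LabelingFunction((0, 1, 2)), "biased0")

    def test_soundness_on_interior_points(self, rerooted_tripod, labeling, case1_q):
        # parametrized interior points satisfy equations exactly and all
        # inequalities strictly
        rng = np.random.default_rng(17)
        qs = case1_q.variables
        for _ in range(30):
            fc = random_interior_fchecks(rng)
            dist = leaf_fourier_distribution(rerooted_tripod, fc, Z2, "biased0")
            sub = dict(zip(qs, dist.q))
            assert all(sp.expand(e.subs(sub)) == 0 for e in case1_q.equations)
            assert all(sp.nsimplify(e.subs(sub)) > 0 for e in case1_q.strict)
            assert all(sp.nsimplify(e.subs(sub)) > 0 for e in case1_q.nonstrict)

    def test_boundary_sharpness(self, rerooted_tripod, labeling, case1_q):
        # zero rate on one edge makes exactly that edge's non-strict
        # inequality tight
        qs = case1_q.variables
        edge_order = ("root", "e1", "e2", "e3")
        for k, zero_edge in enumerate(edge_order):
            fc = {
                name: [sp.Integer(1), sp.Integer(1) if name == zero_edge else sp.Rational(1, 3 + i)]
                for i, name in enumerate(edge_order)
            }
            dist = leaf_fourier_distribution(rerooted_tripod, fc, Z2, "biased0")
            sub = dict(zip(qs, dist.q))
            vals = [sp.nsimplify(e.subs(sub)) for e in case1_q.nonstrict]
            assert vals[k] == 0
            assert all(v > 0 for j, v in enumerate(vals) if j != k)


class TestGoldenSystems:
    """The generated descriptions match the published systems for all
    three root cases, up to positive scaling and reordering."""

    @pytest.mark.parametrize(
        "case,eqs,nonstrict,strict",
        [
            ("biased0", G.CASE1_EQUATIONS, G.CASE1_NONSTRICT, G.CASE1_STRICT),
            ("biased1", G.CASE2_EQUATIONS, G.CASE2_NONSTRICT, G.CASE2_STRICT),
            ("uniform", G.CASE3_EQUATIONS, G.CASE3_NONSTRICT, G.CASE3_STRICT),
        ],
    )
    def test_p_systems(self, tripod, labeling, case, eqs, nonstrict, strict):
        tr = tripod if case == "uniform" else tripod.rerooted()
        system = to_p_coordinates(model_constraints(tr, Z2, labeling, case), Z2, 3)
        ps = system.variables
        ek, nk, sk = system.canonical_keys()
        assert ek == frozenset(poly_key(sp.sympify(s), ps) for s in eqs)
        assert nk == frozenset(poly_key(sp.sympify(s), ps, orient=True) for s in nonstrict)
        assert sk == frozenset(poly_key(sp.sympify(s), ps, orient=True) for s in strict)

    def test_case_symmetry_by_state_swap(self, tripod, labeling):
        # relabeling 0<->1 at every leaf maps the biased-to-0 system to
        # the biased-to-1 system (permuting p by the pattern involution)
        rt = tripod.rerooted()
        sys1 = to_p_coordinates(model_constraints(rt, Z2, labeling, "biased0"), Z2, 3)
        sys2 = to_p_coordinates(model_constraints(rt, Z2, labeling, "biased1"), Z2, 3)
        ps = sys1.variables
        swap = {ps[i]: ps[7 - i] for i in range(8)}  # adding (1,1,1) to patterns
        swapped_strict = frozenset(
            poly_key(e.subs(swap, simultaneous=True), ps, orient=True) for e in sys1.strict
        )
        assert swapped_strict == frozenset(
            poly_key(e, ps, orient=True) for e in sys2.strict
        )
        swapped_eqs = frozenset(
            poly_key(e.subs(swap, simultaneous=True), ps) for e in sys1.equations
        )
        assert swapped_eqs == frozenset(poly_key(e, ps) for e in sys2.equations)


class TestNormalization:
    def test_coprime_integer_scaling(self):
        x, y = sp.symbols("x y")
        assert normalize_poly(sp.Rational(2, 3) * x + sp.Rational(4, 3) * y, (x, y)) == x + 2 * y

    def test_orientation_preserved_for_inequalities(self):
        x, y = sp.symbols("x y")
        assert normalize_poly(-2 * x + 2 * y, (x, y), orient=True) == -x + y
        assert normalize_poly(-2 * x + 2 * y, (x, y)) == x - y
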