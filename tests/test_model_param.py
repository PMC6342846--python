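import math

import numpy as np
import pytest
import sympy as sp

from algmle.group_fourier import Z2, LabelingFunction, pattern_index, patterns
from algmle.model_param import (
    CountVector,
    DEMO_COUNTS,
    EdgeRateVector,
    INF_RATE,
    RootedTree,
    classify_boundary,
    leaf_fourier_distribution,
    loglikelihood,
    parametrize_leaf_distribution,
    psi_to_fcheck,
    rate_matrix,
    recover_parameters,
    reroot_nonuniform,
    sample_counts,
    transition_matrix,
)
from conftest import random_interior_fchecks


class TestTrees:
    def test_tripod_edges(self):
        t = RootedTree.tripod()
        assert t.n_leaves == 3
        assert sorted(e.name for e in t.edges) == ["e1", "e2", "e3"]
        assert t.leaf_edge(2).below == frozenset({2})

    def test_reroot_adds_hidden_leaf(self):
        rt = RootedTree.tripod().rerooted()
        assert rt.has_hidden_root
        root = rt.edge("root")
        assert root.is_root_edge and root.below == frozenset({1, 2, 3})
        assert rt.rerooted() is rt  # idempotent

    def test_quartet_internal_edge(self):
        t = RootedTree.from_newick("((1,2),(3,4));")
        internal = [e for e in t.edges if not e.is_leaf_edge]
        assert sorted(sorted(e.below) for e in internal) == [[1, 2], [3, 4]]


class TestRateAndTransition:
    def test_cfn_rate_matrix(self):
        a = sp.Symbol("a")
        Q = rate_matrix(EdgeRateVector.cfn(a), Z2)
        assert Q == sp.Matrix([[-a, a], [a, -a]])

    def test_zero_rates(self):
        Q = rate_matrix(EdgeRateVector((0, 0)), Z2)
        assert Q == sp.zeros(2, 2)

    def test_cfn_transition_closed_form(self):
        a = sp.Symbol("a", positive=True)
        P = transition_matrix(EdgeRateVector.cfn(a), Z2)
        alpha = (1 + sp.exp(-2 * a)) / 2
        beta = (1 - sp.exp(-2 * a)) / 2
        assert sp.simplify(P - sp.Matrix([[alpha, beta], [beta, alpha]])) == sp.zeros(2, 2)

    def test_transition_matches_scipy_expm(self):
        from scipy.linalg import expm

        for a in (0.1, 0.75, 3.0):
            P = np.array(transition_matrix(EdgeRateVector.cfn(a), Z2).evalf().tolist(),
                         dtype=float)
            Q = np.array([[-a, a], [a, -a]])
            assert np.allclose(P, expm(Q), atol=1e-12)

    def test_limits(self):
        P0 = transition_matrix(EdgeRateVector.cfn(0), Z2)
        assert P0 == sp.eye(2)
        Pbig = np.array(
            transition_matrix(EdgeRateVector.cfn(40.0), Z2).evalf().tolist(), dtype=float
        )
        assert np.allclose(Pbig, 0.5, atol=1e-12)

    def test_fcheck_two_routes_agree(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = float(rng.uniform(0.05, 3.0))
            fc = [complex(sp.N(x)).real for x in psi_to_fcheck(EdgeRateVector.cfn(a), Z2)]
            P = np.array(transition_matrix(EdgeRateVector.cfn(a), Z2).evalf().tolist(),
                         dtype=float)
            via_row = np.array([[1, 1], [1, -1]]) @ P[0]
            assert np.allclose(fc, via_row, atol=1e-12)
            assert abs(fc[0] - 1) < 1e-15  # psi sums to zero


class TestRerooting:
    def test_point_mass_root(self):
        t, froot = reroot_nonuniform(RootedTree.tripod(), [1, 0], Z2)
        assert froot == [1, 1]

    def test_biased_root_fourier(self):
        _, froot = reroot_nonuniform(RootedTree.tripod(), [sp.Rational(7, 10), sp.Rational(3, 10)], Z2)
        assert froot[1] == sp.Rational(2, 5)  # pi0 - pi1

    def test_swapped_case_rejected(self):
        with pytest.raises(ValueError):
            reroot_nonuniform(RootedTree.tripod(), [0.2, 0.8], Z2)


class TestForwardMap:
    def test_all_identity_transitions_give_point_mass(self, rerooted_tripod):
        fc = {e.name: [sp.Integer(1), sp.Integer(1)] for e in rerooted_tripod.edges}
        dist = leaf_fourier_distribution(rerooted_tripod, fc, Z2, "biased0")
        assert dist.q == [1] * 8
        assert dist.p[0] == 1 and all(x == 0 for x in dist.p[1:])

    def test_monomial_structure(self, rerooted_tripod):
        rng = np.random.default_rng(11)
        fc = random_interior_fchecks(rng)
        dist = leaf_fourier_distribution(rerooted_tripod, fc, Z2, "biased0")
        r, a, b, c = (fc[n][1] for n in ("root", "e1", "e2", "e3"))
        # q_{g1 g2 g3} = r(g1+g2+g3) a(g1) b(g2) c(g3)
        assert dist.q[pattern_index(Z2, ((1,), (0,), (0,)))] == r * a
        assert dist.q[pattern_index(Z2, ((1,), (1,), (0,)))] == a * b
        assert dist.q[pattern_index(Z2, ((1,), (1,), (1,)))] == r * a * b * c
        assert sum(dist.p) == 1

    def test_uniform_root_parity_zeros(self, tripod):
        rng = np.random.default_rng(12)
        fc = random_interior_fchecks(rng, rerooted=False)
        dist = leaf_fourier_distribution(tripod, fc, Z2, "uniform")
        for i, pat in enumerate(patterns(Z2, 3)):
            parity = sum(g[0] for g in pat) % 2
            if parity:
                assert dist.q[i] == 0
        assert sum(dist.p) == 1

    def test_explicit_polynomial_parametrization(self, tripod):
        # p_000 = pi0*alpha1*alpha2*alpha3 + pi1*beta1*beta2*beta3, etc.
        rng = np.random.default_rng(4)
        rates = {"e%d" % i: float(rng.uniform(0.1, 1.5)) for i in (1, 2, 3)}
        pi0 = 0.8
        psis = {k: EdgeRateVector.cfn(v) for k, v in rates.items()}
        dist = parametrize_leaf_distribution(
            RootedTree.tripod(), psis, Z2, root=("biased", [pi0, 1 - pi0])
        )
        alpha = {k: (1 + math.exp(-2 * v)) / 2 for k, v in rates.items()}
        beta = {k: (1 - math.exp(-2 * v)) / 2 for k, v in rates.items()}
        p = dist.p_float()
        expect000 = pi0 * alpha["e1"] * alpha["e2"] * alpha["e3"] + (1 - pi0) * beta["e1"] * beta["e2"] * beta["e3"]
        expect011 = pi0 * alpha["e1"] * beta["e2"] * beta["e3"] + (1 - pi0) * beta["e1"] * alpha["e2"] * alpha["e3"]
        assert abs(p[0] - expect000) < 1e-12
        assert abs(p[3] - expect011) < 1e-12


class TestSampling:
    def test_zero_samples(self, rerooted_tripod):
        fc = random_interior_fchecks(np.random.default_rng(0))
        dist = leaf_fourier_distribution(rerooted_tripod, fc, Z2, "biased0")
        assert sample_counts(dist, 0, seed=1).u == (0,) * 8

    def test_point_mass(self, rerooted_tripod):
        fc = {e.name: [sp.Integer(1), sp.Integer(1)] for e in rerooted_tripod.edges}
        dist = leaf_fourier_distribution(rerooted_tripod, fc, Z2, "biased0")
        u = sample_counts(dist, 100, seed=1)
        assert u.u == (100, 0, 0, 0, 0, 0, 0, 0)

    def test_determinism_and_total(self, rerooted_tripod):
        fc = random_interior_fchecks(np.random.default_rng(5))
        dist = leaf_fourier_distribution(rerooted_tripod, fc, Z2, "biased0")
        u1 = sample_counts(dist, 250, seed=42)
        u2 = sample_counts(dist, 250, seed=42)
        u3 = sample_counts(dist, 250, seed=43)
        assert u1.u == u2.u
        assert u1.n_samples == 250
        assert u1.u != u3.u

    def test_demo_fixture_shape(self):
        assert DEMO_COUNTS.n_samples == 100
        assert len(DEMO_COUNTS.u) == 8


class TestRecovery:
    def test_roundtrip_random_interior(self, rerooted_tripod):
        rng = np.random.default_rng(9)
        for _ in range(20):
            rates = {n: float(rng.uniform(0.05, 2.0)) for n in ("root", "e1", "e2", "e3")}
            psis = {k: EdgeRateVector.cfn(v) for k, v in rates.items()}
            dist = parametrize_leaf_distribution(rerooted_tripod, psis, Z2)
            rec = recover_parameters(dist.q_float(), rerooted_tripod, Z2)
            for name, rate in rates.items():
                assert abs(rec[name]["psi"][1] - rate) < 1e-10

    def test_identity_edge_recovers_zero(self, rerooted_tripod):
        psis = {
            "root": EdgeRateVector.cfn(0.3),
            "e1": EdgeRateVector.cfn(0.0),
            "e2": EdgeRateVector.cfn(0.7),
            "e3": EdgeRateVector.cfn(0.4),
        }
        dist = parametrize_leaf_distribution(rerooted_tripod, psis, Z2)
        rec = recover_parameters(dist.q_float(), rerooted_tripod, Z2)
        assert abs(rec["e1"]["psi"][1]) < 1e-10

    def test_vanishing_fourier_parameter_reports_infinite_rate(self, rerooted_tripod):
        fc = {
            "root": [1.0, 0.6],
            "e1": [1.0, 0.3],
            "e2": [1.0, 0.0],
            "e3": [1.0, 0.8],
        }
        dist = leaf_fourier_distribution(rerooted_tripod, {k: [sp.Float(x) for x in v] for k, v in fc.items()}, Z2, "biased0")
        rec = recover_parameters(dist.q_float(), rerooted_tripod, Z2)
        assert rec["e2"]["psi"][1] == INF_RATE
        assert abs(rec["e1"]["psi"][1] + math.log(0.3) / 1) < 1.0  # finite
        status = classify_boundary(rec)
        assert status["e2"] == "infinite-rate"
        assert status["root"] == "interior"


class TestClassifyBoundary:
    def test_thresholds(self):
        rec = {
            "a": {"fcheck": (1.0, 1.0), "psi": (0.0, 0.0)},
            "b": {"fcheck": (1.0, 1e-12), "psi": (-INF_RATE, INF_RATE)},
            "c": {"fcheck": (1.0, 0.5), "psi": (-0.35, 0.35)},
        }
        status = classify_boundary(rec)
        assert status == {"a": "zero-rate", "b": "infinite-rate", "c": "interior"}


class TestLogLikelihood:
    def test_uniform(self):
        u = CountVector((17, 5, 27, 5, 16, 5, 19, 6))
        assert abs(loglikelihood(u, [0.125] * 8) - 100 * math.log(0.125)) < 1e-9

    def test_zero_probability_counted(self):
        u = CountVector((1, 0))
        assert loglikelihood(u, [0.0, 1.0]) == -math.inf

    def test_zero_count_zero_prob_convention(self):
        u = CountVector((0, 3))
        assert abs(loglikelihood(u, [0.0, 1.0])) < 1e-15

    def test_unconstrained_maximum(self):
        u = DEMO_COUNTS
        phat = [x / 100 for x in u.u]
        lhat = loglikelihood(u, phat)
        assert abs(lhat - sum(c * math.log(c / 100) for c in u.u)) < 1e-9
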