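"""Implicit (semialgebraic) descriptions of symmetric group-based models.

A joint leaf distribution lies in the model iff it satisfies

* the toric phylogenetic invariants (binomials in Fourier coordinates),
* the normalization ``q_{0...0} = 1``,
* strict positivity of the Fourier coordinates not forced to zero, and
* one cleared monomial inequality per edge and nonzero dual element,
  obtained by substituting the Matsen square formulas
  ``[f_check^(e)(h)]^2 = (q-monomial quotient)`` into the condition
  that the recovered rates be nonnegative.

Everything is exact rational arithmetic; systems convert between q-
and p-coordinates by the exact linear substitution ``q = H p``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from functools import lru_cache

import sympy as sp

from .group_fourier import (
    FiniteAbelianGroup,
    LabelingFunction,
    character_matrix,
    pattern_index,
    pattern_label,
    patterns,
    site_product_transform,
)
from .model_param import Edge, RootedTree


def q_symbols(group: FiniteAbelianGroup, n: int):
    return [sp.Symbol("q" + pattern_label(pat)) for pat in patterns(group, n)]


def p_symbols(group: FiniteAbelianGroup, n: int):
    return [sp.Symbol("p" + pattern_label(pat)) for pat in patterns(group, n)]


def normalize_poly(expr, syms, orient: bool = False):
    """Scale to coprime integer coefficients; fix the sign convention.

    With ``orient=False`` the leading coefficient (lex in the given
    variable order) is made positive — appropriate for equations, whose
    overall sign is immaterial.  With ``orient=True`` only positive
    scaling is applied, preserving the orientation of an inequality.
    """
    poly = sp.Poly(sp.expand(expr), *syms, domain=sp.QQ)
    coeffs = poly.coeffs()
    if not coeffs:
        return sp.Integer(0)
    denls = sp.ilcm(*[sp.Rational(c).q for c in coeffs]) if len(coeffs) > 1 else sp.Rational(coeffs[0]).q
    scaled = [sp.Rational(c) * denls for c in coeffs]
    g = sp.igcd(*[abs(c.p) for c in scaled]) if len(scaled) > 1 else abs(scaled[0].p)
    scale = sp.Rational(denls, g)
    if not orient:
        lead = sp.Poly(poly.as_expr() * scale, *syms, domain=sp.QQ).LC(order="lex")
        if lead < 0:
            scale = -scale
    return sp.expand(poly.as_expr() * scale)


def poly_key(expr, syms, orient: bool = False) -> str:
    return sp.srepr(sp.Poly(normalize_poly(expr, syms, orient=orient), *syms, domain=sp.QQ).as_expr())


@dataclass
class PolynomialConstraintSystem:
    """Equations + inequalities with exact rational coefficients."""

    variables: list
    equations: list
    nonstrict: list  # poly >= 0
    strict: list  # poly > 0
    coords: str = "q"
    root_case: str = "biased0"
    meta: dict = field(default_factory=dict)

    def normalized(self) -> "PolynomialConstraintSystem":
        v = self.variables
        return PolynomialConstraintSystem(
            v,
            [normalize_poly(e, v) for e in self.equations],
            [normalize_poly(e, v, orient=True) for e in self.nonstrict],
            [normalize_poly(e, v, orient=True) for e in self.strict],
            self.coords,
            self.root_case,
            dict(self.meta),
        )

    def canonical_keys(self):
        v = self.variables
        return (
            frozenset(poly_key(e, v) for e in self.equations),
            frozenset(poly_key(e, v, orient=True) for e in self.nonstrict),
            frozenset(poly_key(e, v, orient=True) for e in self.strict),
        )

    def lambdified(self):
        v = self.variables
        return (
            [sp.lambdify(v, e, "math") for e in self.equations],
            [sp.lambdify(v, e, "math") for e in self.nonstrict],
            [sp.lambdify(v, e, "math") for e in self.strict],
        )

    def evaluate(self, point, tol: float = 1e-7) -> dict:
        """Sign evaluation at a numeric point in this system's coordinates."""
        pt = [float(x) for x in point]
        eqs = [float(e.subs(dict(zip(self.variables, pt)))) for e in self.equations]
        nst = [float(e.subs(dict(zip(self.variables, pt)))) for e in self.nonstrict]
        st = [float(e.subs(dict(zip(self.variables, pt)))) for e in self.strict]
        return {
            "equations_ok": all(abs(x) <= tol for x in eqs),
            "nonstrict_ok": all(x >= -tol for x in nst),
            "strict_ok": all(x > tol for x in st),
            "residuals": {"equations": eqs, "nonstrict": nst, "strict": st},
        }

    def to_json(self) -> str:
        def render(polys):
            out = []
            for e in polys:
                poly = sp.Poly(e, *self.variables, domain=sp.QQ)
                out.append(
                    {
                        "terms": [
                            [str(sp.Rational(c)), list(map(int, m))]
                            for m, c in zip(poly.monoms(), poly.coeffs())
                        ],
                        "string": str(e),
                    }
                )
            return out

        return json.dumps(
            {
                "variables": [str(v) for v in self.variables],
                "coords": self.coords,
                "root_case": self.root_case,
                "equations": render(self.equations),
                "nonstrict": render(self.nonstrict),
                "strict": render(self.strict),
            },
            indent=1,
        )


@dataclass
class EdgeSquareExpression:
    """``[f_check^(e)(h)]^2`` as a monomial quotient in Fourier coordinates."""

    edge: str
    h: tuple
    numerator: list  # list of patterns
    denominator: list

    def indices(self, group: FiniteAbelianGroup):
        n = len(self.numerator[0])
        return (
            [pattern_index(group, pat) for pat in self.numerator],
            [pattern_index(group, pat) for pat in self.denominator],
        )

    def as_expr(self, group: FiniteAbelianGroup, qsyms):
        num = sp.Integer(1)
        for pat in self.numerator:
            num *= qsyms[pattern_index(group, pat)]
        den = sp.Integer(1)
        for pat in self.denominator:
            den *= qsyms[pattern_index(group, pat)]
        return num / den

    def evaluate(self, q, group: FiniteAbelianGroup):
        ni, di = self.indices(group)
        num = sp.Integer(1)
        for i in ni:
            num *= q[i]
        den = sp.Integer(1)
        for i in di:
            den *= q[i]
        return num / den


def _assign_pattern(n: int, group: FiniteAbelianGroup, assignments: dict):
    """Pattern in G^n with given leaf->state assignments, identity elsewhere."""
    return tuple(assignments.get(i, group.identity) for i in range(1, n + 1))


HIDDEN = 0  # pseudo-index for the hidden root leaf in pair enumeration


def _child_branches(tree: RootedTree, below: frozenset):
    """Leaf sets of the subtrees hanging below the vertex under ``below``."""
    subs = [set(e.below) for e in tree.edges if set(e.below) < set(below)]
    return [
        frozenset(s)
        for s in subs
        if not any(s < t for t in subs)
    ]


def _vertex_branches(tree: RootedTree, edge: Edge, endpoint: str):
    """Partition of all leaves (observed + hidden root) into the
    branches around one endpoint of an edge, excluding the branch
    containing the edge itself."""
    n = tree.n_leaves
    all_obs = frozenset(range(1, n + 1))
    hidden = frozenset({HIDDEN}) if tree.has_hidden_root else frozenset()
    if endpoint == "child":
        branches = list(_child_branches(tree, edge.below))
        outside = (all_obs - edge.below) | (hidden if not edge.is_root_edge else frozenset())
        if outside:
            branches.append(frozenset(outside))
        return branches
    # parent endpoint: the vertex above the edge
    enclosing = [e for e in tree.edges if set(e.below) > set(edge.below)]
    if enclosing:
        parent = min(enclosing, key=lambda e: len(e.below))
        P = parent.below
        branches = [b for b in _child_branches(tree, P) if b != edge.below]
        outside = (all_obs - P) | hidden
    else:
        # the parent vertex is the tree's root itself
        branches = [
            b for b in _child_branches(tree, all_obs | frozenset())
            if b != edge.below
        ]
        branches = [b for b in branches if b != edge.below]
        outside = hidden
    if outside:
        branches.append(frozenset(outside))
    return branches


def _ordered_cross_pairs(branches):
    """Ordered pairs of leaves from distinct branches; observed leaves
    ascending first, hidden-root-leaf variants last."""
    pairs = []
    for b1, b2 in itertools.permutations(branches, 2):
        for a in sorted(b1):
            for b in sorted(b2):
                pairs.append((a, b))
    pairs.sort(key=lambda p: (p.count(HIDDEN), p))
    return pairs


def _square_candidates(tree: RootedTree, edge: Edge, h, group: FiniteAbelianGroup):
    """All equivalent monomial-quotient choices, canonical order.

    Each choice of auxiliary leaves whose paths meet the edge's
    endpoints gives the same value on interior points (the Fourier
    coordinates are positive there); the enumeration order puts
    all-observed choices first and hidden-root-leaf variants last, so
    recovery degrades gracefully on boundary points where some Fourier
    coordinates vanish.
    """
    n = tree.n_leaves
    mh = group.neg(h)
    out = []

    def assign(spec):
        return _assign_pattern(n, group, {a: g for a, g in spec.items() if a != HIDDEN})

    if edge.is_leaf_edge or edge.is_root_edge:
        i = HIDDEN if edge.is_root_edge else edge.leaf
        vertex = "child" if edge.is_root_edge else "parent"
        branches = [b for b in _vertex_branches(tree, edge, vertex)
                    if i not in b]
        for j, k in _ordered_cross_pairs(branches):
            out.append(
                EdgeSquareExpression(
                    edge.name,
                    h,
                    [assign({i: h, j: mh}), assign({i: mh, k: h})],
                    [assign({j: mh, k: h})],
                )
            )
        if not out:
            raise ValueError("tree has too few leaves for the square formulas")
        return out
    # internal edge: i, j meet at the child endpoint; i2, j2 at the parent
    child_pairs = _ordered_cross_pairs(_vertex_branches(tree, edge, "child"))
    parent_pairs = _ordered_cross_pairs(
        [b for b in _vertex_branches(tree, edge, "parent")]
    )
    for i, j in child_pairs:
        for i2, j2 in parent_pairs:
            out.append(
                EdgeSquareExpression(
                    edge.name,
                    h,
                    [assign({i: h, i2: mh}), assign({j: mh, j2: h})],
                    [assign({i: h, j: mh}), assign({i2: mh, j2: h})],
                )
            )
    if not out:
        raise ValueError("internal-edge square formula needs leaves on both sides")
    return out


def leaf_edge_square(tree: RootedTree, edge, h, group: FiniteAbelianGroup) -> EdgeSquareExpression:
    """Canonical square formula for a leaf edge (lowest valid leaf indices)."""
    edge = tree.edge(edge) if isinstance(edge, str) else edge
    if not (edge.is_leaf_edge or edge.is_root_edge):
        raise ValueError("not a leaf or hidden-root edge: %r" % edge.name)
    return _square_candidates(tree, edge, h, group)[0]


def internal_edge_square(tree: RootedTree, edge, h, group: FiniteAbelianGroup) -> EdgeSquareExpression:
    edge = tree.edge(edge) if isinstance(edge, str) else edge
    if edge.is_leaf_edge or edge.is_root_edge:
        raise ValueError("not an internal edge: %r" % edge.name)
    return _square_candidates(tree, edge, h, group)[0]


def edge_square_candidates(tree: RootedTree, edge, h, group: FiniteAbelianGroup):
    """Candidate (numerator-indices, denominator-indices) pairs for recovery."""
    edge = tree.edge(edge) if isinstance(edge, str) else edge
    return [c.indices(group) for c in _square_candidates(tree, edge, h, group)]


def toric_invariants(tree: RootedTree, group: FiniteAbelianGroup,
                     root_case: str = "biased0", cap: int = 4096):
    """Generators of the kernel of the Fourier monomial parametrization.

    Computed by eliminating the per-edge Fourier parameters from the
    graph ideal ``< q_g - prod_e f_e(*g_e) >``; since the map is a
    monomial ring map, the elimination ideal is exactly the kernel.
    The uniform root case uses the generic (rerooted) map and appends
    the parity-forced linear forms ``q_g = 0``.
    """
    if root_case == "uniform" or root_case in ("biased0", "biased1"):
        tree = tree.rerooted()
    n = tree.n_leaves
    if group.order**n > cap:
        raise ValueError("pattern space too large for elimination (cap %d)" % cap)
    qs = q_symbols(group, n)
    fvars = {}
    for e in tree.edges:
        for g in group.elements:
            fvars[(e.name, g)] = sp.Symbol("f_%s_%s" % (e.name, "".join(map(str, g))))
    gens = []
    from .model_param import star_argument

    for pat in patterns(group, n):
        mono = sp.Integer(1)
        for e in tree.edges:
            mono *= fvars[(e.name, star_argument(group, e, pat))]
        gens.append(qs[pattern_index(group, pat)] - mono)
    elim_order = list(fvars.values()) + qs
    gb = sp.groebner(gens, *elim_order, order="lex")
    fset = set(fvars.values())
    invariants = [
        sp.expand(g) for g in gb.exprs if not (g.free_symbols & fset)
    ]
    invariants = [normalize_poly(g, qs) for g in invariants]
    if root_case == "uniform":
        for pat in patterns(group, n):
            if group.sum(pat) != group.identity:
                lin = qs[pattern_index(group, pat)]
                if lin not in invariants:
                    invariants.append(lin)
    return invariants


@lru_cache(maxsize=None)
def _cfn_tripod_invariants_cached():
    """The three quadric binomials of the two-state model on the claw tree."""
    group = FiniteAbelianGroup([2])
    qs = q_symbols(group, 3)
    q = {pattern_label(pat): qs[i] for i, pat in enumerate(patterns(group, 3))}
    return [
        normalize_poly(q["001"] * q["110"] - q["000"] * q["111"], qs),
        normalize_poly(q["010"] * q["101"] - q["000"] * q["111"], qs),
        normalize_poly(q["100"] * q["011"] - q["000"] * q["111"], qs),
    ]


def cfn_tripod_invariants():
    return list(_cfn_tripod_invariants_cached())


def _state_swap_sign(group: FiniteAbelianGroup, n: int, pat) -> int:
    """Character sign picked up by q_pat under the global 0<->1 state swap."""
    sigma = tuple(1 for _ in group.cyclic_orders)
    sign = 1
    for g in pat:
        val = sum(gj * sj for gj, sj in zip(g, sigma)) % 2
        sign *= -1 if val else 1
    return sign


def model_constraints(tree: RootedTree, group: FiniteAbelianGroup,
                      labeling: LabelingFunction, root_case: str = "biased0",
                      invariants=None) -> PolynomialConstraintSystem:
    """Full q-coordinate description for one root case.

    ``tree`` should be the rerooted tree for the biased cases and the
    plain tree for the uniform case.  The non-strict inequalities are
    the cleared forms of the per-edge monomial conditions; clearing is
    valid because all retained Fourier coordinates are strictly
    positive and ``q_{0..0} = 1``.
    """
    if not labeling.is_symmetric(group):
        raise ValueError("labeling is not symmetric: L(g) != L(-g)")
    if group.exponent != 2:
        raise NotImplementedError(
            "inequality generation for groups of exponent > 2 is experimental: "
            "the monomial exponents are not all real"
        )
    if root_case in ("biased0", "biased1") and not tree.has_hidden_root:
        tree = tree.rerooted()
    if root_case == "uniform" and tree.has_hidden_root:
        raise ValueError("uniform-root description uses the tree without the hidden root edge")
    n = tree.n_leaves
    qs = q_symbols(group, n)
    K = character_matrix(group)

    if invariants is None:
        if group.order == 2 and n == 3 and len(tree.rerooted().edges) == 4:
            invariants = cfn_tripod_invariants()
        else:
            invariants = toric_invariants(tree, group, "biased0")
        if root_case == "uniform":
            for pat in patterns(group, n):
                if group.sum(pat) != group.identity:
                    invariants.append(qs[pattern_index(group, pat)])
    else:
        invariants = list(invariants)

    forced_zero = set()
    if root_case == "uniform":
        for pat in patterns(group, n):
            if group.sum(pat) != group.identity:
                forced_zero.add(pattern_index(group, pat))

    identity_idx = pattern_index(group, tuple(group.identity for _ in range(n)))
    equations = list(invariants) + [qs[identity_idx] - 1]

    strict = [qs[i] for i in range(len(qs)) if i not in forced_zero and i != identity_idx]
    if root_case == "biased1":
        if group.order != 2:
            raise NotImplementedError("state-swap root case is defined for the two-state model")
        strict = []
        for i, pat in enumerate(patterns(group, n)):
            if i in forced_zero or i == identity_idx:
                continue
            strict.append(_state_swap_sign(group, n, pat) * qs[i])

    nonstrict = []
    seen = set()
    for e in tree.edges:
        for gi, g in enumerate(group.elements):
            if g == group.identity:
                continue
            pos_num, pos_den, neg_num, neg_den = [], [], [], []
            for hi, h in enumerate(group.elements):
                sign = K[gi, hi]
                if sign not in (1, -1):
                    raise NotImplementedError("non-real character entries")
                if h == group.identity:
                    continue  # squared parameter is 1
                sq = leaf_edge_square(tree, e, h, group) if (
                    e.is_leaf_edge or e.is_root_edge
                ) else internal_edge_square(tree, e, h, group)
                if int(sign) == 1:
                    pos_num += sq.numerator
                    pos_den += sq.denominator
                else:
                    neg_num += sq.numerator
                    neg_den += sq.denominator
            lhs = sp.Integer(1)
            for pat in pos_num + neg_den:
                lhs *= qs[pattern_index(group, pat)]
            rhs = sp.Integer(1)
            for pat in neg_num + pos_den:
                rhs *= qs[pattern_index(group, pat)]
            # homogenize with q_{0..0} (== 1) so both sides have equal degree
            dl = sp.total_degree(lhs, *qs)
            dr = sp.total_degree(rhs, *qs)
            expr = lhs * qs[identity_idx] ** max(dr - dl, 0) - rhs * qs[identity_idx] ** max(dl - dr, 0)
            expr = normalize_poly(expr, qs, orient=True)
            key = sp.srepr(expr)
            if key not in seen and expr != 0:
                seen.add(key)
                nonstrict.append(expr)

    # label-compatibility equalities between dual elements sharing a label
    # are monomial identities among the squared edge parameters; they are
    # vacuous for injective labelings (such as the two-state model).

    return PolynomialConstraintSystem(
        qs, equations, nonstrict, strict, coords="q", root_case=root_case
    )


def to_p_coordinates(system: PolynomialConstraintSystem, group: FiniteAbelianGroup,
                     n: int) -> PolynomialConstraintSystem:
    """Exact substitution ``q = H p`` and expansion, with normalization."""
    if system.coords != "q":
        raise ValueError("expected a q-coordinate system")
    H = site_product_transform(n, group)
    ps = p_symbols(group, n)
    qs = system.variables
    subs = {}
    for i, qsym in enumerate(qs):
        subs[qsym] = sp.expand(sum(H[i, j] * ps[j] for j in range(len(ps))))
    return PolynomialConstraintSystem(
        ps,
        [normalize_poly(e.subs(subs), ps) for e in system.equations],
        [normalize_poly(e.subs(subs), ps, orient=True) for e in system.nonstrict],
        [normalize_poly(e.subs(subs), ps, orient=True) for e in system.strict],
        coords="p",
        root_case=system.root_case,
        meta=dict(system.meta),
    )
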