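"""Boundary stratification of the constrained likelihood problem.

Maximizing the likelihood over a set ``{G_i >= 0, H_j = 0}`` reduces,
through the KKT conditions, to solving Lagrange critical systems over
every active subset ``S`` of the inequalities (the solution variety of
the KKT ideal is covered by the union over strata).  Each stratum ideal
``<H, G_i : i in S>`` is replaced by sums of minimal primes of the
singleton ideals, components forcing a probability coordinate (or a
nonnegative coordinate sum) to zero are discarded, and duplicates are
merged by reduced Groebner basis.

Decomposition happens in Fourier (q-) coordinates, where all the
generators arising from group-based models are binomial and minimal
primes are obtained by recursive factor splitting plus saturation;
the resulting components are mapped back to probability coordinates by
the exact linear substitution for the Lagrange systems.

The likelihood gradient conditions are cleared of denominators by
multiplying each coordinate's equation through by that coordinate:
``u_k - p_k * sum_j lambda_j dg_j/dp_k = 0``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import sympy as sp

from .group_fourier import FiniteAbelianGroup, patterns, site_product_transform
from .semialgebraic import p_symbols, q_symbols, normalize_poly


def enumerate_active_sets(m: int):
    """All subsets of ``{0..m-1}`` in size-then-lex order, empty set first."""
    if m < 0:
        raise ValueError("m must be >= 0")
    if m > 16:
        raise ValueError("refusing to enumerate 2^%d active sets" % m)
    out = []
    for size in range(m + 1):
        for comb in itertools.combinations(range(m), size):
            out.append(tuple(comb))
    return out


@dataclass
class StratumIdeal:
    """One candidate stratum: generators + provenance + canonical key."""

    generators: tuple  # sympy exprs in the decomposition variables
    variables: tuple
    active_set: tuple = ()
    component_index: tuple = ()
    pruned: bool = False
    gb_key: tuple = field(default=None, repr=False)

    def groebner(self):
        return sp.groebner(list(self.generators), *self.variables, order="grevlex")

    def key(self):
        if self.gb_key is None:
            gb = self.groebner()
            object.__setattr__(self, "gb_key", tuple(sorted(sp.srepr(e) for e in gb.exprs)))
        return self.gb_key

    def contains(self, expr, gb=None) -> bool:
        gb = gb if gb is not None else self.groebner()
        return gb.reduce(sp.expand(expr))[1] == 0


def _reduced_gb(gens, varlist):
    return sp.groebner(list(gens), *varlist, order="grevlex")


def _split_once(gb, varlist):
    """Find a Groebner element that factors; return the branch ideals."""
    for expr in gb.exprs:
        _, factors = sp.factor_list(expr, *varlist)
        bases = [b for b, _ in factors if sp.total_degree(b, *varlist) >= 1]
        if len(bases) <= 1 and all(e == 1 for _, e in factors):
            continue
        branch_bases = list(dict.fromkeys(bases))
        if any(gb.reduce(sp.expand(b))[1] == 0 for b in branch_bases):
            continue  # a factor already lies in the ideal: no split information
        return [list(gb.exprs) + [b] for b in branch_bases]
    return None


def _saturation_branch(gb, varlist):
    """If I : v^inf strictly exceeds I for some variable v, branch into
    V(I:v^inf) and V(I + v)."""
    t = sp.Symbol("_t_sat")
    for v in varlist:
        if gb.reduce(v)[1] == 0:
            continue
        sat_gb = sp.groebner(list(gb.exprs) + [t * v - 1], t, *varlist, order="lex")
        sat = [e for e in sat_gb.exprs if t not in e.free_symbols]
        if any(gb.reduce(sp.expand(e))[1] != 0 for e in sat):
            return [sat, list(gb.exprs) + [v]]
    return None


def minimal_primes(gens, varlist, _depth: int = 0):
    """Minimal primes of a binomial-generated ideal by recursive factor
    splitting and saturation, followed by a minimality filter.

    Complete for the monomial/binomial ideals arising from group-based
    model strata; a non-splittable non-prime leaf would simply be kept
    whole (coarser but still a correct cover of the variety).
    """
    if _depth > 24:
        raise RuntimeError("decomposition recursion too deep")
    gb = _reduced_gb(gens, varlist)
    if 1 in gb.exprs or sp.Integer(1) in gb.exprs:
        return []
    branches = _split_once(gb, varlist)
    if branches is None:
        branches = _saturation_branch(gb, varlist)
    if branches is None:
        return [tuple(gb.exprs)]
    leaves = []
    for br in branches:
        leaves.extend(minimal_primes(br, varlist, _depth + 1))
    # dedup, then keep only inclusion-minimal ideals (maximal components)
    uniq = {}
    for leaf in leaves:
        k = tuple(sorted(sp.srepr(e) for e in leaf))
        uniq[k] = leaf
    leaves = list(uniq.values())
    keep = []
    for i, leaf in enumerate(leaves):
        gb_i = _reduced_gb(leaf, varlist)
        redundant = False
        for j, other in enumerate(leaves):
            if i == j:
                continue
            if all(gb_i.reduce(sp.expand(e))[1] == 0 for e in other):
                # other  <=  leaf as ideals, hence V(leaf) <= V(other)
                k_other = tuple(sorted(sp.srepr(e) for e in other))
                k_leaf = tuple(sorted(sp.srepr(e) for e in leaf))
                if k_other != k_leaf or j < i:
                    redundant = True
                    break
        if not redundant:
            keep.append(leaf)
    return keep


def probability_linear_forms(group: FiniteAbelianGroup, n: int):
    """Each probability coordinate as an exact linear form in the q-variables."""
    qs = q_symbols(group, n)
    H = site_product_transform(n, group)
    Hinv = H.conjugate().T / (group.order**n)
    forms = []
    for i in range(len(qs)):
        forms.append(sp.expand(sum(Hinv[i, j] * qs[j] for j in range(len(qs)))))
    return forms


def is_zero_component(gb, p_forms) -> bool:
    """Remark-style pruning: the component forces some probability
    coordinate, or some sum of probability coordinates, to zero (hence
    log-likelihood -infinity on the positive part of the stratum).

    Reduction modulo a fixed Groebner basis is linear and normal forms
    are closed under addition, so it suffices to reduce each coordinate
    once and test subset sums of the normal forms for cancellation.
    """
    npat = len(p_forms)
    nfs = [sp.expand(gb.reduce(sp.expand(f * npat))[1]) for f in p_forms]
    for r in range(1, npat + 1):
        for comb in itertools.combinations(range(npat), r):
            if sp.expand(sum(nfs[i] for i in comb)) == 0:
                return True
    return False


def singleton_components(H_list, G_i, varlist, p_forms=None):
    """Minimal primes of ``<H, G_i>`` with zero-component flags."""
    leaves = minimal_primes(list(H_list) + [G_i], varlist)
    out = []
    for idx, leaf in enumerate(leaves):
        st = StratumIdeal(tuple(leaf), tuple(varlist), component_index=(idx,))
        if p_forms is not None:
            st.pruned = is_zero_component(st.groebner(), p_forms)
        out.append(st)
    return out


def assemble_stratum_ideals(H_list, G_list, varlist, p_forms=None, keep_pruned=False,
                            decompose_sums=True):
    """Active-set enumeration with per-singleton decomposition (the
    modified stratification): for every subset ``S`` of the
    inequalities, every sum of one minimal-prime component per member
    of ``S``, pruned of zero components and deduplicated by reduced
    Groebner basis.  The empty active set contributes ``<H>`` itself.

    With ``decompose_sums`` (default) each component sum is itself
    decomposed into minimal primes, so the returned strata are the
    irreducible pieces of the boundary arrangement; the raw (possibly
    reducible) sums are available with ``decompose_sums=False``.
    """
    m = len(G_list)
    if not decompose_sums:
        return _assemble_by_subset_sums(H_list, G_list, varlist, p_forms, keep_pruned)
    # fixpoint refinement: the family of all decomposed active-set sums is
    # the closure of {<H>} under "add one constraint and decompose"; BFS
    # with global dedup reaches it without enumerating 2^m subsets
    root = StratumIdeal(
        tuple(_reduced_gb(H_list, varlist).exprs), tuple(varlist), active_set=()
    )
    if p_forms is not None and is_zero_component(root.groebner(), p_forms):
        root.pruned = True
    result = [root] if (keep_pruned or not root.pruned) else []
    seen = {root.key(): root}
    frontier = [root]
    while frontier:
        next_frontier = []
        for st in frontier:
            gb = st.groebner()
            for i in range(m):
                if gb.reduce(sp.expand(G_list[i]))[1] == 0:
                    continue  # constraint already active on this stratum
                S = tuple(sorted(set(st.active_set) | {i}))
                for piece in minimal_primes(list(st.generators) + [G_list[i]], varlist):
                    pgb = _reduced_gb(piece, varlist)
                    cand = StratumIdeal(
                        tuple(pgb.exprs), tuple(varlist), active_set=S
                    )
                    k = cand.key()
                    if k in seen:
                        continue
                    if p_forms is not None and is_zero_component(pgb, p_forms):
                        cand.pruned = True
                        seen[k] = cand
                        if keep_pruned:
                            result.append(cand)
                        continue  # adding constraints cannot un-prune
                    seen[k] = cand
                    result.append(cand)
                    next_frontier.append(cand)
        frontier = next_frontier
    return result


def _assemble_by_subset_sums(H_list, G_list, varlist, p_forms, keep_pruned):
    """Literal subset-sum enumeration (raw, possibly reducible sums)."""
    m = len(G_list)
    comp_lists = []
    for i in range(m):
        comps = singleton_components(H_list, G_list[i], varlist, p_forms)
        comp_lists.append([c for c in comps if keep_pruned or not c.pruned])
    result = []
    seen = {}
    for S in enumerate_active_sets(m):
        if not S:
            st = StratumIdeal(tuple(H_list), tuple(varlist), active_set=())
            seen[st.key()] = st
            result.append(st)
            continue
        for choice in itertools.product(*(comp_lists[i] for i in S)):
            gens = list(H_list)
            for comp in choice:
                gens.extend(comp.generators)
            gb = _reduced_gb(gens, varlist)
            if 1 in gb.exprs or sp.Integer(1) in gb.exprs:
                continue
            st = StratumIdeal(
                tuple(gb.exprs),
                tuple(varlist),
                active_set=S,
                component_index=tuple(c.component_index[0] for c in choice),
            )
            if p_forms is not None and is_zero_component(gb, p_forms):
                st.pruned = True
                if not keep_pruned:
                    continue
            k = st.key()
            if k in seen:
                continue
            seen[k] = st
            result.append(st)
    return result


def ideal_dimension(gb, varlist) -> int:
    """Affine dimension from the leading-term monomial ideal: the size of
    the largest variable subset meeting no leading monomial's support."""
    supports = []
    for e in gb.exprs:
        lead = sp.Poly(e, *varlist).LM(order="grevlex")
        supports.append({v for v, k in zip(varlist, lead.exponents) if k})
    best = 0
    nv = len(varlist)
    for r in range(nv, 0, -1):
        if r <= best:
            break
        for comb in itertools.combinations(varlist, r):
            cs = set(comb)
            if all(not s <= cs for s in supports):
                best = r
                break
    return best


@dataclass
class LagrangeSystem:
    """Cleared-denominator critical equations for one stratum.

    ``equations`` is square in ``unknowns`` = probability block +
    multiplier block.  When the stratum has more generators than its
    codimension, ``constraints`` holds random integer combinations
    (randomized squaring) and ``verify_polys`` the original generators
    that endpoints must additionally satisfy.
    """

    stratum: StratumIdeal
    p_vars: tuple
    lam_vars: tuple
    equations: tuple
    constraints: tuple
    verify_polys: tuple
    u: tuple

    @property
    def unknowns(self):
        return tuple(self.p_vars) + tuple(self.lam_vars)


def stratum_generators_in_p(stratum: StratumIdeal, group: FiniteAbelianGroup, n: int):
    """Map q-coordinate generators to probability coordinates, exactly."""
    qs = q_symbols(group, n)
    ps = p_symbols(group, n)
    H = site_product_transform(n, group)
    subs = {
        qsym: sp.expand(sum(H[i, j] * ps[j] for j in range(len(ps))))
        for i, qsym in enumerate(qs)
    }
    return [normalize_poly(g.subs(subs), ps) for g in stratum.generators], ps


def lagrange_from_generators(gens, variables, u, codim=None, rng=None,
                             stratum=None) -> LagrangeSystem:
    """Square Lagrange critical system for the log-likelihood
    ``sum_k u_k log x_k`` on ``V(gens)``.

    Gradient equations: ``u_k - x_k * sum_j lambda_j dg_j/dx_k = 0`` for
    every coordinate (the gradient multiplied through by ``x_k``), plus
    the constraint equations ``g_j = 0``.  If more generators than the
    codimension are supplied and an ``rng`` is given, the constraints
    are replaced by ``codim`` random integer combinations (randomized
    squaring); endpoints must then be re-verified against ``gens``.
    """
    gens = [sp.expand(g) for g in gens]
    variables = tuple(variables)
    if not gens:
        raise ValueError("stratum ideal has no generators")
    uv = tuple(int(x) for x in (u.u if hasattr(u, "u") else u))
    if len(uv) != len(variables):
        raise ValueError("count vector length mismatch")
    if codim is not None and len(gens) > codim and rng is not None:
        combos = []
        for _ in range(codim):
            coeffs = [int(rng.integers(1, 50)) * (1 if rng.integers(0, 2) else -1)
                      for _ in gens]
            combos.append(sp.expand(sum(c * g for c, g in zip(coeffs, gens))))
        constraints = combos
    else:
        constraints = gens
    lam = sp.symbols("lam0:%d" % len(constraints))
    lam = (lam,) if isinstance(lam, sp.Symbol) else tuple(lam)
    equations = []
    for k, xk in enumerate(variables):
        grad = sum(l * sp.diff(g, xk) for l, g in zip(lam, constraints))
        equations.append(sp.expand(uv[k] - xk * grad))
    equations.extend(constraints)
    return LagrangeSystem(
        stratum=stratum,
        p_vars=variables,
        lam_vars=lam,
        equations=tuple(equations),
        constraints=tuple(constraints),
        verify_polys=tuple(gens),
        u=uv,
    )


def minimal_generators(gens, varlist):
    """Greedily drop generators lying in the ideal of the remaining ones.

    A reduced Groebner basis usually over-generates (the main graph-type
    strata need 5 of their 10 basis elements); a smaller generating set
    keeps the Lagrange system a complete intersection and the homotopy
    path count low.  Higher-degree generators are dropped first.
    """
    gens = sorted(gens, key=lambda g: (-sp.total_degree(g, *varlist), sp.srepr(g)))
    keep = list(gens)
    i = 0
    while i < len(keep):
        if len(keep) == 1:
            break
        candidate = keep[:i] + keep[i + 1:]
        gb = _reduced_gb(candidate, varlist)
        if gb.reduce(sp.expand(keep[i]))[1] == 0:
            keep = candidate
        else:
            i += 1
    return keep


def lagrange_system(stratum: StratumIdeal, u, group: FiniteAbelianGroup, n: int,
                    rng=None) -> LagrangeSystem:
    """Build the square Lagrange critical system for one stratum,
    mapped to probability coordinates."""
    reduced = StratumIdeal(
        tuple(minimal_generators(stratum.generators, stratum.variables)),
        stratum.variables,
        active_set=stratum.active_set,
        component_index=stratum.component_index,
    )
    gens_p, ps = stratum_generators_in_p(reduced, group, n)
    codim = len(ps) - ideal_dimension(stratum.groebner(), stratum.variables)
    return lagrange_from_generators(gens_p, ps, u, codim=codim, rng=rng,
                                    stratum=stratum)


def leaf_automorphisms(tree):
    """Leaf permutations preserving the tree's edge structure."""
    n = tree.n_leaves
    belows = {frozenset(e.below) for e in tree.edges}
    autos = []
    for perm in itertools.permutations(range(1, n + 1)):
        mapping = dict(zip(range(1, n + 1), perm))
        if {frozenset(mapping[i] for i in b) for b in belows} == belows:
            autos.append(mapping)
    return autos


def symmetrize_strata(strata, group: FiniteAbelianGroup, tree, varlist):
    """Close a stratum list under the tree's leaf symmetries.

    The cleared boundary polynomials depend on index choices that are
    immaterial on the model itself (any valid choice of auxiliary
    leaves gives an equivalent inequality there) but change the Zariski
    components off the positive region; the canonical stratification is
    the orbit closure under the leaf automorphism group.
    """
    from .group_fourier import pattern_index, patterns

    n = tree.n_leaves
    pats = patterns(group, n)
    autos = [a for a in leaf_automorphisms(tree) if any(a[i] != i for i in a)]
    out = list(strata)
    seen = {s.key() for s in out}
    frontier = list(strata)
    while frontier:
        new_frontier = []
        for s in frontier:
            for auto in autos:
                perm_map = {}
                for i, pat in enumerate(pats):
                    image = tuple(pat[auto[k + 1] - 1] for k in range(n))
                    perm_map[varlist[i]] = varlist[pattern_index(group, image)]
                gens = [g.subs(perm_map, simultaneous=True) for g in s.generators]
                gb = _reduced_gb(gens, varlist)
                st = StratumIdeal(tuple(gb.exprs), tuple(varlist),
                                  active_set=s.active_set,
                                  component_index=s.component_index)
                k = st.key()
                if k not in seen:
                    seen.add(k)
                    out.append(st)
                    new_frontier.append(st)
        frontier = new_frontier
    return out


_STRATA_MEMO = {}


def cfn_tripod_strata(group: FiniteAbelianGroup, tree, labeling, decompose_sums=True):
    """Convenience: the full stratification of the relaxed biased-root
    description (shared by all three root cases).  Memoized, since the
    stratification depends only on the model, not on the data."""
    key = (group.cyclic_orders, tree.n_leaves,
           tuple(sorted((e.name, tuple(sorted(e.below))) for e in tree.edges)),
           labeling.labels, decompose_sums)
    if key in _STRATA_MEMO:
        return _STRATA_MEMO[key]
    from .semialgebraic import model_constraints

    p_forms = probability_linear_forms(group, tree.n_leaves)
    sysq = model_constraints(tree.rerooted(), group, labeling, "biased0")
    qs = list(sysq.variables)
    # the relaxation turns every strict positivity constraint into an
    # active-set candidate alongside the edge quadrics
    G_list = list(sysq.nonstrict) + list(sysq.strict)
    out = assemble_stratum_ideals(list(sysq.equations), G_list, qs,
                                  p_forms, decompose_sums=decompose_sums)
    # the biased-to-one case relaxes to the same polynomials; the
    # uniform-root case's strata embed in the above (its extra equations
    # are active positivity constraints), but stratify it as well as a
    # cross-check and merge, then close under the tree's leaf symmetries
    sysu = model_constraints(tree, group, labeling, "uniform")
    extra = assemble_stratum_ideals(
        list(sysu.equations), list(sysu.nonstrict) + list(sysu.strict), qs,
        p_forms, decompose_sums=decompose_sums)
    seen = {s.key() for s in out}
    for s in extra:
        if s.key() not in seen:
            seen.add(s.key())
            out.append(s)
    out = symmetrize_strata(out, group, tree, qs)
    _STRATA_MEMO[key] = out
    return out
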