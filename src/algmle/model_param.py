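"""Trees, rate parameters, and the parametrization of leaf distributions.

The forward map of a continuous-time group-based model factors through
Fourier space:

    psi (per-edge rate vectors)
      -> psi_check = K psi
      -> f_check   = exp(psi_check)        (componentwise)
      -> q         (monomial products over edges)
      -> p         = H^{-1} q.

A non-uniform root distribution ``pi`` is handled by rerooting: a new
hidden leaf is attached at the root, the new root mass sits at the
identity, and the extra edge carries ``pi`` as its transition vector.

This module also provides the synthetic-data generator (multinomial
count sampling from a parametrized distribution) and the inverse map:
recovering per-edge rate vectors from Fourier coordinates, including
the detection of zero-rate (identity transition) and infinite-rate
(vanishing Fourier parameter) boundary edges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import sympy as sp

from .group_fourier import (
    FiniteAbelianGroup,
    LabelingFunction,
    character_matrix,
    inverse_character_matrix,
    pattern_index,
    pattern_label,
    patterns,
    site_product_transform,
)

INF_RATE = float("inf")  # sentinel for an infinite recovered rate


@dataclass(frozen=True)
class Edge:
    """A directed tree edge with the set of observed leaves below it."""

    name: str
    below: frozenset
    leaf: int | None = None  # observed leaf index for leaf edges
    is_root_edge: bool = False  # hidden-root-leaf edge created by rerooting

    @property
    def is_leaf_edge(self) -> bool:
        return self.leaf is not None


class RootedTree:
    """Rooted tree with ordered leaf labels ``1..n``.

    ``edges`` excludes the root vertex's nonexistent parent edge; after
    :meth:`rerooted`, an extra hidden-root edge (below-set = all
    observed leaves) is prepended.
    """

    def __init__(self, n_leaves: int, leaf_names, edges, has_hidden_root: bool = False):
        self.n_leaves = n_leaves
        self.leaf_names = list(leaf_names)
        self.edges = list(edges)
        self.has_hidden_root = has_hidden_root
        self._by_name = {e.name: e for e in self.edges}

    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        leaves = [lf for lf in tree.leaf_node_iter()]
        names = [lf.taxon.label if lf.taxon else str(i + 1) for i, lf in enumerate(leaves)]
        leaf_idx = {id(lf): i + 1 for i, lf in enumerate(leaves)}
        edges = []
        internal_count = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            below = frozenset(leaf_idx[id(lf)] for lf in node.leaf_iter())
            if node.is_leaf():
                i = leaf_idx[id(node)]
                edges.append(Edge(name="e%d" % i, below=below, leaf=i))
            else:
                internal_count += 1
                edges.append(Edge(name="i%d" % internal_count, below=below))
        # canonical order: leaf edges by leaf index, then internal edges by below-set
        leaf_edges = sorted((e for e in edges if e.is_leaf_edge), key=lambda e: e.leaf)
        internal = sorted((e for e in edges if not e.is_leaf_edge), key=lambda e: sorted(e.below))
        return cls(len(leaves), names, leaf_edges + internal)

    @classmethod
    def tripod(cls) -> "RootedTree":
        return cls.from_newick("(1,2,3);")

    def rerooted(self) -> "RootedTree":
        """Attach a hidden leaf at the root; its edge carries the root distribution."""
        if self.has_hidden_root:
            return self
        root_edge = Edge(
            name="root", below=frozenset(range(1, self.n_leaves + 1)), is_root_edge=True
        )
        return RootedTree(
            self.n_leaves, self.leaf_names, [root_edge] + self.edges, has_hidden_root=True
        )

    def edge(self, name: str) -> Edge:
        return self._by_name[name]

    def leaf_edge(self, i: int) -> Edge:
        return self._by_name["e%d" % i]

    def __repr__(self):
        return "RootedTree(n=%d, edges=%s)" % (self.n_leaves, [e.name for e in self.edges])


@dataclass
class EdgeRateVector:
    """Rate vector ``psi`` over G defining ``Q[g,h] = psi(h-g)``."""

    psi: tuple

    @classmethod
    def cfn(cls, a) -> "EdgeRateVector":
        """Two-state rate vector ``(-a, a)`` with off-diagonal rate ``a``."""
        return cls((-a, a))

    def validate(self, group: FiniteAbelianGroup, labeling: LabelingFunction | None = None):
        if len(self.psi) != group.order:
            raise ValueError("psi must have length |G|")
        total = sum(self.psi)
        if abs(float(total)) > 1e-12:
            raise ValueError("psi must sum to zero")
        if labeling is not None:
            for cls_elems in labeling.classes(group):
                vals = {self.psi[group.index[g]] for g in cls_elems}
                if len(vals) > 1:
                    raise ValueError("psi must be constant on labeling classes")


@dataclass
class LeafDistribution:
    """Paired probability (``p``) and Fourier (``q``) coordinates over G^n."""

    group: FiniteAbelianGroup
    n_leaves: int
    p: list
    q: list
    provenance: dict = field(default_factory=dict)

    def p_float(self) -> np.ndarray:
        return np.array([float(x) for x in self.p])

    def q_float(self) -> np.ndarray:
        return np.array([float(x) for x in self.q])

    def to_json(self) -> str:
        labels = [pattern_label(pat) for pat in patterns(self.group, self.n_leaves)]
        return json.dumps(
            {
                "group": list(self.group.cyclic_orders),
                "p": {lab: float(x) for lab, x in zip(labels, self.p)},
                "q": {lab: float(x) for lab, x in zip(labels, self.q)},
                "provenance": {k: str(v) for k, v in self.provenance.items()},
            },
            indent=1,
        )


@dataclass
class CountVector:
    """Nonnegative integer pattern counts with total sample size."""

    u: tuple

    @property
    def n_samples(self) -> int:
        return int(sum(self.u))

    @classmethod
    def from_mapping(cls, group: FiniteAbelianGroup, n_leaves: int, mapping) -> "CountVector":
        labels = [pattern_label(pat) for pat in patterns(group, n_leaves)]
        return cls(tuple(int(mapping.get(lab, 0)) for lab in labels))

    def to_json(self, group: FiniteAbelianGroup, n_leaves: int) -> str:
        labels = [pattern_label(pat) for pat in patterns(group, n_leaves)]
        return json.dumps(dict(zip(labels, map(int, self.u))))


#: a realized 100-sample multinomial draw from the near-boundary CFN
#: tripod rates used throughout the worked example (root edge -0.25/0.25,
#: leaf edges 0.75, 50, 0.25); shipped as a fixed fixture because a
#: single multinomial realization is not reproducible from the rates.
DEMO_COUNTS = CountVector((17, 5, 27, 5, 16, 5, 19, 6))

#: the rate parameters that generated :data:`DEMO_COUNTS`
DEMO_RATES = {
    "root": EdgeRateVector.cfn(0.25),
    "e1": EdgeRateVector.cfn(0.75),
    "e2": EdgeRateVector.cfn(50.0),
    "e3": EdgeRateVector.cfn(0.25),
}


def rate_matrix(psi: EdgeRateVector, group: FiniteAbelianGroup):
    """Q with ``Q[g,h] = psi(h-g)``; rows sum to zero by construction."""
    n = group.order
    Q = sp.zeros(n, n)
    for i, g in enumerate(group.elements):
        for j, h in enumerate(group.elements):
            Q[i, j] = psi.psi[group.index[group.sub(h, g)]]
    return Q


def psi_to_fcheck(psi: EdgeRateVector, group: FiniteAbelianGroup):
    """Fourier edge parameters ``f_check = exp(K psi)`` (componentwise).

    ``f_check(0) = 1`` automatically because ``sum(psi) = 0``.
    """
    K = character_matrix(group)
    psicheck = K * sp.Matrix(list(psi.psi))
    return [sp.exp(x) if isinstance(x, sp.Basic) and not x.is_Number else sp.exp(sp.nsimplify(x)) for x in psicheck]


def psi_to_fcheck_numeric(psi: EdgeRateVector, group: FiniteAbelianGroup) -> np.ndarray:
    K = character_matrix(group)
    Kn = np.array(K.tolist(), dtype=float) if group.exponent == 2 else np.array(
        sp.Matrix(K).evalf().tolist(), dtype=complex
    )
    return np.exp(Kn @ np.array([float(x) for x in psi.psi]))


def transition_matrix(psi: EdgeRateVector, group: FiniteAbelianGroup):
    """Matrix exponential of the rate matrix, via character diagonalization.

    ``K`` diagonalizes every group-based rate matrix, so
    ``P = K^{-1} diag(exp(K psi)) K`` exactly.
    """
    K = character_matrix(group)
    Kinv = inverse_character_matrix(group)
    fcheck = psi_to_fcheck(psi, group)
    P = Kinv * sp.diag(*fcheck) * K
    return P.applyfunc(sp.expand)


def reroot_nonuniform(tree: RootedTree, pi, group: FiniteAbelianGroup,
                      labeling: LabelingFunction | None = None):
    """Replace a non-uniform root distribution by a hidden root leaf.

    Returns ``(rerooted_tree, f_check_root)`` where the root edge's
    Fourier parameter is the Fourier transform of ``pi``.  Rejects
    distributions incompatible with the labeling, and (for two-state
    groups) distributions whose convolution matrix has nonpositive
    determinant -- those belong to the swapped or uniform case.
    """
    pi = list(pi)
    if len(pi) != group.order:
        raise ValueError("pi must have length |G|")
    if labeling is not None:
        for cls_elems in labeling.classes(group):
            vals = {sp.nsimplify(pi[group.index[g]]) for g in cls_elems}
            if len(vals) > 1:
                raise ValueError("pi must be constant on labeling classes")
    K = character_matrix(group)
    froot = list(K * sp.Matrix(pi))
    for val in froot[1:]:
        v = float(sp.re(sp.N(val)))
        if v < 0:
            raise ValueError(
                "root distribution lies in the swapped (state-relabeled) case; "
                "apply the state relabeling and re-run"
            )
    return tree.rerooted(), [sp.nsimplify(x) for x in froot]


def star_argument(group: FiniteAbelianGroup, edge: Edge, pattern):
    """``*g_e``: the sum over observed leaves below the edge of their states."""
    return group.sum(pattern[i - 1] for i in sorted(edge.below))


def leaf_fourier_distribution(tree: RootedTree, fchecks: dict, group: FiniteAbelianGroup,
                              root_case: str = "biased0") -> LeafDistribution:
    """Fill ``q`` by the per-edge monomial products and pull back to ``p``.

    ``fchecks`` maps edge name -> length-|G| vector (the Fourier edge
    parameter, indexed like the group elements).  For the uniform root
    case the tree must not carry a hidden root edge and every pattern
    whose states do not sum to the identity gets ``q = 0``.
    """
    n = tree.n_leaves
    for e in tree.edges:
        if e.name not in fchecks:
            raise ValueError("missing Fourier parameter for edge %r" % e.name)
    q = []
    for pat in patterns(group, n):
        if root_case == "uniform" and group.sum(pat) != group.identity:
            q.append(sp.Integer(0))
            continue
        val = sp.Integer(1)
        for e in tree.edges:
            val *= fchecks[e.name][group.index[star_argument(group, e, pat)]]
        q.append(val)
    H = site_product_transform(n, group)
    Hinv = H.conjugate().T / (group.order**n)
    p = [sp.expand(x) for x in (Hinv * sp.Matrix(q))]
    return LeafDistribution(group, n, p, list(q), provenance={"root_case": root_case})


def parametrize_leaf_distribution(tree: RootedTree, psis: dict, group: FiniteAbelianGroup,
                                  root=("uniform",)) -> LeafDistribution:
    """Full chain psi -> f_check -> q -> p for a given root specification.

    ``root`` is ``("uniform",)`` or ``("biased", pi)``; in the biased
    case the tree is rerooted and the root edge carries the Fourier
    transform of ``pi``.  Alternatively, if ``psis`` contains a "root"
    entry and the tree already has a hidden root edge, it is used
    directly.
    """
    fchecks = {}
    if root[0] == "biased":
        tree, froot = reroot_nonuniform(tree, root[1], group)
        fchecks["root"] = froot
        root_case = "biased0"
    elif tree.has_hidden_root or "root" in psis:
        tree = tree.rerooted()
        root_case = "biased0"
    else:
        root_case = "uniform"
    for e in tree.edges:
        if e.name in fchecks:
            continue
        fchecks[e.name] = psi_to_fcheck(psis[e.name], group)
    dist = leaf_fourier_distribution(tree, fchecks, group, root_case)
    dist.provenance["psis"] = {k: tuple(map(float, v.psi)) for k, v in psis.items()}
    return dist


def sample_counts(dist: LeafDistribution, n: int, seed: int) -> CountVector:
    """Multinomial pattern counts; reproducible for a given ``seed``."""
    p = dist.p_float()
    if (p < -1e-12).any():
        raise ValueError("negative probabilities; distribution is outside the model")
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    u = rng.multinomial(int(n), p)
    return CountVector(tuple(int(x) for x in u))


class RecoveryError(ValueError):
    pass


def recover_parameters(q, tree: RootedTree, group: FiniteAbelianGroup,
                       eps_inf: float = 1e-6, eps_den: float = 1e-8) -> dict:
    """Invert the parametrization: ``q -> f_check -> psi`` per edge.

    For each edge and nonzero dual element the squared Fourier
    parameter is a monomial quotient in ``q`` (with several equivalent
    index choices); the first choice whose denominator entries are
    bounded away from zero is used, so recovery degrades gracefully on
    boundary points where some Fourier coordinates vanish.  Vanishing
    parameters are reported as infinite rates via the ``INF_RATE``
    sentinel.
    """
    from .semialgebraic import edge_square_candidates

    qf = np.array([float(x) for x in q])
    out = {}
    for e in tree.edges:
        fcheck = [1.0]
        for h in group.elements[1:]:
            cands = edge_square_candidates(tree, e, h, group)
            sq = None
            for num_idx, den_idx in cands:
                den = np.prod(qf[den_idx]) if den_idx else 1.0
                if abs(den) <= eps_den:
                    continue
                sq = float(np.prod(qf[num_idx]) / den)
                break
            if sq is None:
                raise RecoveryError(
                    "all square-formula denominators vanish for edge %r" % e.name
                )
            if sq < -(eps_inf**2):
                raise RecoveryError(
                    "negative squared Fourier parameter for edge %r: outside "
                    "positive orthant" % e.name
                )
            fcheck.append(math.sqrt(max(sq, 0.0)))
        psi_check = []
        for f in fcheck:
            psi_check.append(-INF_RATE if f <= eps_inf else math.log(f))
        if any(x == -INF_RATE for x in psi_check):
            psi = tuple(
                INF_RATE if g != group.identity else -INF_RATE for g in group.elements
            )
        else:
            Kinv = inverse_character_matrix(group)
            Kn = np.array(sp.Matrix(Kinv).evalf().tolist(), dtype=complex)
            vals = (Kn @ np.array(psi_check)).real
            psi = tuple(float(v) for v in vals)
        out[e.name] = {"fcheck": tuple(fcheck), "psi": psi}
    return out


def classify_boundary(recovered: dict, eps_one: float = 1e-6, eps_inf: float = 1e-6) -> dict:
    """Per-edge status: interior / zero-rate (identity transition) / infinite-rate."""
    status = {}
    for name, rec in recovered.items():
        f = rec["fcheck"][1:]
        if any(x <= eps_inf for x in f):
            status[name] = "infinite-rate"
        elif all(abs(x - 1.0) <= eps_one for x in f):
            status[name] = "zero-rate"
        else:
            status[name] = "interior"
    return status


def loglikelihood(u: CountVector, p) -> float:
    """``sum u_i log p_i`` with the convention ``0 log 0 = 0``.

    Returns ``-inf`` if any counted pattern has nonpositive probability.
    """
    uv = u.u if isinstance(u, CountVector) else tuple(u)
    pv = [float(x) for x in p]
    if len(uv) != len(pv):
        raise ValueError("count and probability vectors differ in length")
    total = 0.0
    for ui, pi in zip(uv, pv):
        if ui == 0:
            continue
        if pi <= 0:
            return -math.inf
        total += ui * math.log(pi)
    return total
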