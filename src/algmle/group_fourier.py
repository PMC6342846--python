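"""Finite abelian groups, characters, and discrete Fourier transforms.

Group-based substitution models are indexed by a finite abelian group
``G`` (``Z2`` for the two-state symmetric model, ``Z2 x Z2`` for
Kimura-type models).  Everything downstream -- the parametrization of
joint leaf distributions, the binomial phylogenetic invariants and the
boundary inequalities -- lives either in probability coordinates ``p``
over ``G^n`` or in Fourier coordinates ``q`` obtained by applying the
n-fold Kronecker power of the single-site character matrix ``K``.

All character/transform algebra here is exact: for groups of exponent
two the matrices are integer matrices, otherwise entries are sympy
roots of unity.  Floating point enters only in the numerical solver.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from math import lcm, prod

import numpy as np
import sympy as sp


class FiniteAbelianGroup:
    """Direct product of cyclic groups ``Z_{m_1} x ... x Z_{m_k}``.

    Elements are tuples of residues, ordered lexicographically; the
    identity is the all-zero tuple.  The element order doubles as the
    index order of rows/columns of the character matrix.
    """

    def __init__(self, cyclic_orders):
        orders = tuple(int(m) for m in cyclic_orders)
        if not orders or any(m < 2 for m in orders):
            raise ValueError("cyclic orders must be integers >= 2")
        self.cyclic_orders = orders
        self.elements = [tuple(t) for t in itertools.product(*(range(m) for m in orders))]
        self.index = {g: i for i, g in enumerate(self.elements)}

    @property
    def order(self) -> int:
        return prod(self.cyclic_orders)

    @property
    def exponent(self) -> int:
        return lcm(*self.cyclic_orders)

    @property
    def identity(self):
        return self.elements[0]

    def add(self, g, h):
        return tuple((a + b) % m for a, b, m in zip(g, h, self.cyclic_orders))

    def neg(self, g):
        return tuple((-a) % m for a, m in zip(g, self.cyclic_orders))

    def sub(self, g, h):
        return self.add(g, self.neg(h))

    def sum(self, elems):
        total = self.identity
        for g in elems:
            total = self.add(total, g)
        return total

    def __len__(self):
        return self.order

    def __eq__(self, other):
        return isinstance(other, FiniteAbelianGroup) and self.cyclic_orders == other.cyclic_orders

    def __hash__(self):
        return hash(self.cyclic_orders)

    def __repr__(self):
        return "FiniteAbelianGroup(%s)" % (list(self.cyclic_orders),)

    def to_json(self) -> str:
        return json.dumps({"cyclic_orders": list(self.cyclic_orders)})

    @classmethod
    def from_json(cls, text: str) -> "FiniteAbelianGroup":
        return cls(json.loads(text)["cyclic_orders"])


#: the two-state group underlying the CFN model
Z2 = FiniteAbelianGroup([2])


@dataclass(frozen=True)
class LabelingFunction:
    """Map ``L`` from group elements to a finite label set.

    Two group elements with equal labels are forced to share rate
    entries; the model is symmetric iff ``L(g) == L(-g)`` for all g.
    """

    labels: tuple

    @classmethod
    def from_mapping(cls, group: FiniteAbelianGroup, mapping) -> "LabelingFunction":
        return cls(tuple(mapping[g] for g in group.elements))

    @classmethod
    def identity_labeling(cls, group: FiniteAbelianGroup) -> "LabelingFunction":
        return cls(tuple(range(group.order)))

    def label(self, group: FiniteAbelianGroup, g):
        return self.labels[group.index[g]]

    def is_symmetric(self, group: FiniteAbelianGroup) -> bool:
        return all(
            self.labels[group.index[g]] == self.labels[group.index[group.neg(g)]]
            for g in group.elements
        )

    def classes(self, group: FiniteAbelianGroup):
        """Partition of group elements into equal-label classes."""
        out: dict = {}
        for g in group.elements:
            out.setdefault(self.labels[group.index[g]], []).append(g)
        return list(out.values())


def character_matrix(group: FiniteAbelianGroup) -> sp.Matrix:
    """Exact character matrix ``K`` with ``K[g_hat, h] = g_hat(h)``.

    Dual elements are indexed by the same residue tuples as the group
    elements; the character value is the product over cyclic factors of
    ``exp(2*pi*I*g_j*h_j/m_j)``.  For exponent-two groups the result is
    an integer (+/-1) matrix.
    """
    n = group.order
    K = sp.zeros(n, n)
    for i, g in enumerate(group.elements):
        for j, h in enumerate(group.elements):
            e = sp.Rational(0)
            for gj, hj, m in zip(g, h, group.cyclic_orders):
                e += sp.Rational((gj * hj) % m, m)
            if e % 1 == 0:
                K[i, j] = sp.Integer(1)
            elif 2 * e % 2 == 1:
                K[i, j] = sp.Integer(-1)
            else:
                K[i, j] = sp.exp(2 * sp.pi * sp.I * (e % 1))
    return K


def character_matrix_numeric(group: FiniteAbelianGroup) -> np.ndarray:
    n = group.order
    K = np.empty((n, n), dtype=complex)
    for i, g in enumerate(group.elements):
        for j, h in enumerate(group.elements):
            phase = sum((gj * hj % m) / m for gj, hj, m in zip(g, h, group.cyclic_orders))
            K[i, j] = np.exp(2j * np.pi * phase)
    if group.exponent == 2:
        K = K.real.round().astype(float)
    return K


def inverse_character_matrix(group: FiniteAbelianGroup) -> sp.Matrix:
    K = character_matrix(group)
    return K.conjugate().T / group.order


def fourier_transform(a, group: FiniteAbelianGroup):
    """Discrete Fourier transform ``a_check(g_hat) = sum_h g_hat(h) a(h)``.

    Accepts any length-|G| sequence; returns a sympy column-vector-like
    list (exact when the input is exact).
    """
    a = list(a)
    if len(a) != group.order:
        raise ValueError("expected a vector of length %d, got %d" % (group.order, len(a)))
    K = character_matrix(group)
    vec = K * sp.Matrix(a)
    return [sp.nsimplify(x) if not isinstance(x, sp.Basic) else x for x in vec]


def inverse_fourier(a_check, group: FiniteAbelianGroup):
    a_check = list(a_check)
    if len(a_check) != group.order:
        raise ValueError("expected a vector of length %d, got %d" % (group.order, len(a_check)))
    Kinv = inverse_character_matrix(group)
    vec = Kinv * sp.Matrix(a_check)
    return [sp.expand(x) for x in vec]


def patterns(group: FiniteAbelianGroup, n: int):
    """All leaf-state patterns in ``G^n``, lexicographic, leaf 1 most significant."""
    return list(itertools.product(group.elements, repeat=n))


def pattern_label(pattern) -> str:
    """Render a pattern as a subscript string, e.g. ``((0,),(1,),(1,)) -> '011'``."""
    return "".join("".join(str(c) for c in g) for g in pattern)


def pattern_index(group: FiniteAbelianGroup, pattern) -> int:
    idx = 0
    for g in pattern:
        idx = idx * group.order + group.index[tuple(g)]
    return idx


def site_product_transform(n: int, group: FiniteAbelianGroup, cap: int = 4096):
    """The joint transform ``H = K^(x n)`` on ``G^n``, as an exact sympy matrix.

    Row/column order is the lexicographic pattern order of :func:`patterns`,
    which matches the subscript order of the printed ``q`` expressions.
    Guarded by ``cap`` on the number of rows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    size = group.order**n
    if size > cap:
        raise ValueError("|G|^n = %d exceeds the size cap %d" % (size, cap))
    K = character_matrix(group)
    H = K
    for _ in range(n - 1):
        H = sp.Matrix(sp.kronecker_product(H, K))
    return H


def site_product_transform_numeric(n: int, group: FiniteAbelianGroup, cap: int = 4096) -> np.ndarray:
    if n < 1:
        raise ValueError("n must be >= 1")
    size = group.order**n
    if size > cap:
        raise ValueError("|G|^n = %d exceeds the size cap %d" % (size, cap))
    K = character_matrix_numeric(group)
    H = K
    for _ in range(n - 1):
        H = np.kron(H, K)
    return H
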