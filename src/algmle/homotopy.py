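"""Polynomial homotopy continuation: start systems, path tracking,
endpoint refinement and classification.

Solves square polynomial systems ``F(z) = 0`` by deforming a start
system ``G`` with known solutions along ``H(z, t) = gamma (1-t) G(z) +
t F(z)`` (the random complex ``gamma`` avoids singular encounters with
probability one) and following every solution path with an adaptive
Euler predictor / Newton corrector in double precision.  Finite
endpoints are polished to high precision with mpmath, deduplicated,
and classified (real / strictly positive probability block / regular).

Start systems: total degree (roots of unity), or a two-block
multihomogeneous start exploiting the bilinear structure of Lagrange
systems (probability block | multiplier block), which cuts the path
count roughly sixfold on the main stratum of the worked example.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import mpmath as mp
import numpy as np
import sympy as sp


@dataclass
class TrackerConfig:
    dt_init: float = 0.1
    dt_min: float = 1e-8
    dt_max: float = 0.25
    corrector_tol: float = 1e-9
    corrector_iters: int = 3
    norm_cap: float = 1e8
    max_sweeps: int = 3000
    refine_digits: int = 50
    refine_iters: int = 60
    dedup_tol: float = 1e-6
    real_tol: float = 1e-6
    positivity_tol: float = 1e-9
    zero_tol: float = 1e-9
    endpoint_tol: float = 1e-8
    batch_size: int = 1500


@dataclass
class CriticalPoint:
    """A refined solution of one stratum's critical system."""

    coords: tuple  # complex, full unknown vector (p-block then multipliers)
    n_p: int  # size of the probability block
    residual: float
    is_real: bool
    is_positive: bool
    is_regular: bool
    refined: bool
    stratum: object = None
    multiplicity: int = 1

    @property
    def p_block(self):
        return self.coords[: self.n_p]

    def p_real(self):
        return tuple(float(c.real) for c in self.p_block)


class CompiledSystem:
    """Coefficient/exponent arrays for fast batched evaluation."""

    def __init__(self, equations, variables):
        self.variables = list(variables)
        self.n_eqs = len(equations)
        self.n_vars = len(self.variables)
        coeffs, exps, eq_idx = [], [], []
        for i, eq in enumerate(equations):
            poly = sp.Poly(sp.expand(eq), *self.variables)
            for mono, c in zip(poly.monoms(), poly.coeffs()):
                coeffs.append(complex(c))
                exps.append(mono)
                eq_idx.append(i)
        self.coeffs = np.array(coeffs, dtype=complex)
        self.exps = np.array(exps, dtype=np.int64).reshape(len(coeffs), self.n_vars)
        self.eq_idx = np.array(eq_idx, dtype=np.int64)
        self.max_exp = self.exps.max(axis=0) if len(coeffs) else np.zeros(self.n_vars, int)
        # Jacobian terms: d(term)/d(var) for every term with exp[var] > 0
        jc, je, jrow = [], [], []
        for c, mono, i in zip(self.coeffs, self.exps, self.eq_idx):
            for v in range(self.n_vars):
                k = mono[v]
                if k == 0:
                    continue
                dm = mono.copy()
                dm[v] -= 1
                jc.append(c * k)
                je.append(dm)
                jrow.append(i * self.n_vars + v)
        self.jac_coeffs = np.array(jc, dtype=complex)
        self.jac_exps = np.array(je, dtype=np.int64).reshape(len(jc), self.n_vars)
        self.jac_rows = np.array(jrow, dtype=np.int64)
        self.jac_max_exp = (
            self.jac_exps.max(axis=0) if len(jc) else np.zeros(self.n_vars, int)
        )

    def _powers(self, z, max_exp):
        # pow_tab[v][k] = z[:, v] ** k
        tabs = []
        for v in range(self.n_vars):
            col = [np.ones(z.shape[0], dtype=complex)]
            for _ in range(int(max_exp[v])):
                col.append(col[-1] * z[:, v])
            tabs.append(col)
        return tabs

    def eval(self, z: np.ndarray) -> np.ndarray:
        """Evaluate at a batch of points; returns (N, n_eqs)."""
        z = np.atleast_2d(z)
        tabs = self._powers(z, self.max_exp)
        out = np.zeros((z.shape[0], self.n_eqs), dtype=complex)
        for c, mono, i in zip(self.coeffs, self.exps, self.eq_idx):
            term = np.full(z.shape[0], c, dtype=complex)
            for v in range(self.n_vars):
                k = mono[v]
                if k:
                    term = term * tabs[v][k]
            out[:, i] += term
        return out

    def jacobian(self, z: np.ndarray) -> np.ndarray:
        """Batched Jacobian; returns (N, n_eqs, n_vars)."""
        z = np.atleast_2d(z)
        tabs = self._powers(z, self.jac_max_exp)
        flat = np.zeros((z.shape[0], self.n_eqs * self.n_vars), dtype=complex)
        for c, mono, r in zip(self.jac_coeffs, self.jac_exps, self.jac_rows):
            term = np.full(z.shape[0], c, dtype=complex)
            for v in range(self.n_vars):
                k = mono[v]
                if k:
                    term = term * tabs[v][k]
            flat[:, r] += term
        return flat.reshape(z.shape[0], self.n_eqs, self.n_vars)

    def eval_mp(self, z):
        """Exact-structure evaluation at an mpmath point (tuple of mpc)."""
        vals = []
        for i in range(self.n_eqs):
            vals.append(mp.mpc(0))
        for c, mono, i in zip(self.coeffs, self.exps, self.eq_idx):
            term = mp.mpc(c)
            for v in range(self.n_vars):
                k = int(mono[v])
                if k:
                    term *= z[v] ** k
            vals[i] += term
        return vals

    def jacobian_mp(self, z):
        J = mp.zeros(self.n_eqs, self.n_vars)
        for c, mono, r in zip(self.jac_coeffs, self.jac_exps, self.jac_rows):
            term = mp.mpc(c)
            for v in range(self.n_vars):
                k = int(mono[v])
                if k:
                    term *= z[v] ** k
            J[r // self.n_vars, r % self.n_vars] += term
        return J


def block_bidegrees(equations, variables, partition):
    """Componentwise degrees of each equation w.r.t. a variable partition."""
    out = []
    for eq in equations:
        poly = sp.Poly(sp.expand(eq), *variables)
        degs = []
        for block in partition:
            idx = [variables.index(v) for v in block]
            d = 0
            for mono in poly.monoms():
                d = max(d, sum(mono[i] for i in idx))
            degs.append(d)
        out.append(tuple(degs))
    return out


def multihomogeneous_count(bidegrees, block_sizes) -> int:
    """Two-block multihomogeneous Bezout number: the number of ways to
    pick one linear factor per equation with exactly ``n_k`` factors
    taken from block ``k`` (counted with block degrees as factor
    multiplicities)."""
    if len(block_sizes) != 2:
        raise ValueError("two blocks supported")
    n1, n2 = block_sizes
    total = 0
    m = len(bidegrees)
    if m != n1 + n2:
        raise ValueError("system must be square w.r.t. the partition")
    for subset in itertools.combinations(range(m), n2):
        prod = 1
        for i in range(m):
            d1, d2 = bidegrees[i]
            prod *= d2 if i in subset else d1
            if prod == 0:
                break
        total += prod
    return total


def total_degree_start(compiled: CompiledSystem, rng):
    """Start system ``z_i^{d_i} - r_i`` with all root-of-unity solutions."""
    degs = []
    for i in range(compiled.n_eqs):
        sel = compiled.eq_idx == i
        degs.append(int(compiled.exps[sel].sum(axis=1).max()))
    n = compiled.n_vars
    if compiled.n_eqs != n:
        raise ValueError("start system requires a square target")
    radii = np.exp(1j * 2 * np.pi * rng.random(n))
    eqs_coeffs, eqs_exps, eq_idx = [], [], []
    for i, d in enumerate(degs):
        e1 = np.zeros(n, dtype=np.int64)
        e1[i] = d
        eqs_coeffs += [1.0, -radii[i]]
        eqs_exps += [e1, np.zeros(n, dtype=np.int64)]
        eq_idx += [i, i]
    start = CompiledSystem.__new__(CompiledSystem)
    start.variables = compiled.variables
    start.n_eqs = n
    start.n_vars = n
    start.coeffs = np.array(eqs_coeffs, dtype=complex)
    start.exps = np.array(eqs_exps, dtype=np.int64)
    start.eq_idx = np.array(eq_idx, dtype=np.int64)
    start.max_exp = start.exps.max(axis=0)
    jc, je, jrow = [], [], []
    for c, mono, i in zip(start.coeffs, start.exps, start.eq_idx):
        for v in range(n):
            k = mono[v]
            if k:
                dm = mono.copy()
                dm[v] -= 1
                jc.append(c * k)
                je.append(dm)
                jrow.append(i * n + v)
    start.jac_coeffs = np.array(jc, dtype=complex)
    start.jac_exps = np.array(je, dtype=np.int64).reshape(len(jc), n)
    start.jac_rows = np.array(jrow, dtype=np.int64)
    start.jac_max_exp = start.jac_exps.max(axis=0)
    roots = [
        radii[i] ** (1.0 / d) * np.exp(2j * np.pi * np.arange(d) / d)
        for i, d in enumerate(degs)
    ]
    sols = np.array([list(tup) for tup in itertools.product(*roots)], dtype=complex)
    return start, sols


class LinearProductStart:
    """Multihomogeneous start: each equation is a product of random
    affine-linear forms, ``d_i`` of them in block 1 and ``e_i`` in
    block 2; solutions are enumerated combinatorially."""

    def __init__(self, bidegrees, block_idx, rng):
        self.bidegrees = bidegrees
        self.block_idx = block_idx  # (indices of block-1 vars, block-2 vars)
        n = sum(len(b) for b in block_idx)
        self.n_vars = n
        self.n_eqs = len(bidegrees)
        # factors[i] = (list of block-1 forms, list of block-2 forms);
        # each form is (coeff vector over all vars, constant)
        self.factors = []
        for d1, d2 in bidegrees:
            f1, f2 = [], []
            for _ in range(d1):
                c = np.zeros(n, dtype=complex)
                c[block_idx[0]] = rng.standard_normal(len(block_idx[0])) + 1j * rng.standard_normal(len(block_idx[0]))
                f1.append((c, rng.standard_normal() + 1j * rng.standard_normal()))
            for _ in range(d2):
                c = np.zeros(n, dtype=complex)
                c[block_idx[1]] = rng.standard_normal(len(block_idx[1])) + 1j * rng.standard_normal(len(block_idx[1]))
                f2.append((c, rng.standard_normal() + 1j * rng.standard_normal()))
            self.factors.append((f1, f2))

    def eval(self, z):
        z = np.atleast_2d(z)
        out = np.empty((z.shape[0], self.n_eqs), dtype=complex)
        for i, (f1, f2) in enumerate(self.factors):
            val = np.ones(z.shape[0], dtype=complex)
            for c, c0 in f1 + f2:
                val = val * (z @ c + c0)
            out[:, i] = val
        return out

    def jacobian(self, z):
        z = np.atleast_2d(z)
        J = np.zeros((z.shape[0], self.n_eqs, self.n_vars), dtype=complex)
        for i, (f1, f2) in enumerate(self.factors):
            forms = f1 + f2
            vals = [z @ c + c0 for c, c0 in forms]
            for a, (c, _) in enumerate(forms):
                rest = np.ones(z.shape[0], dtype=complex)
                for b, vb in enumerate(vals):
                    if b != a:
                        rest = rest * vb
                J[:, i, :] += rest[:, None] * c[None, :]
        return J

    def solutions(self):
        """One start point per admissible factor assignment."""
        n1, n2 = len(self.block_idx[0]), len(self.block_idx[1])
        sols = []
        eqs = range(self.n_eqs)
        for subset in itertools.combinations(eqs, n2):
            sub = set(subset)
            ok = all(
                (self.bidegrees[i][1] > 0 if i in sub else self.bidegrees[i][0] > 0)
                for i in eqs
            )
            if not ok:
                continue
            choices = [
                range(self.bidegrees[i][1] if i in sub else self.bidegrees[i][0])
                for i in eqs
            ]
            for pick in itertools.product(*choices):
                A1 = np.zeros((n1, n1), dtype=complex)
                b1 = np.zeros(n1, dtype=complex)
                A2 = np.zeros((n2, n2), dtype=complex)
                b2 = np.zeros(n2, dtype=complex)
                r1 = r2 = 0
                for i in eqs:
                    f1, f2 = self.factors[i]
                    if i in sub:
                        c, c0 = f2[pick[i]]
                        A2[r2] = c[self.block_idx[1]]
                        b2[r2] = -c0
                        r2 += 1
                    else:
                        c, c0 = f1[pick[i]]
                        A1[r1] = c[self.block_idx[0]]
                        b1[r1] = -c0
                        r1 += 1
                z = np.zeros(self.n_vars, dtype=complex)
                z[self.block_idx[0]] = np.linalg.solve(A1, b1)
                z[self.block_idx[1]] = np.linalg.solve(A2, b2)
                sols.append(z)
        return np.array(sols, dtype=complex)


def start_system(equations, variables, strategy="total_degree", partition=None,
                 rng=None):
    """Build ``(start, start_solutions)`` for a square target system."""
    rng = rng if rng is not None else np.random.default_rng(0)
    if len(equations) != len(variables):
        raise ValueError("start systems require a square target")
    compiled = CompiledSystem(equations, variables)
    if strategy == "total_degree":
        return total_degree_start(compiled, rng)
    if strategy == "multihomogeneous":
        if partition is None:
            raise ValueError("multihomogeneous start needs a variable partition")
        bidegs = block_bidegrees(equations, list(variables), partition)
        block_idx = tuple(
            np.array([list(variables).index(v) for v in block], dtype=int)
            for block in partition
        )
        start = LinearProductStart(bidegs, block_idx, rng)
        return start, start.solutions()
    raise ValueError("unknown strategy %r" % strategy)


def track_paths(start, target: CompiledSystem, sols: np.ndarray, gamma: complex,
                config: TrackerConfig):
    """Follow all start solutions from t=0 to t=1.

    Returns ``(endpoints, status)`` where status is one of
    'converged', 'diverged', 'failed' per path (conservation holds:
    every start solution is accounted for).
    """
    results_z = np.zeros((len(sols), target.n_vars), dtype=complex)
    results_status = np.empty(len(sols), dtype=object)
    for lo in range(0, len(sols), config.batch_size):
        hi = min(lo + config.batch_size, len(sols))
        z = sols[lo:hi].copy()
        N = z.shape[0]
        t = np.zeros(N)
        dt = np.full(N, config.dt_init)
        status = np.zeros(N, dtype=np.int8)  # 0 active, 1 conv, 2 div, 3 fail
        streak = np.zeros(N, dtype=np.int64)

        def homotopy_eval(zz, tt):
            return (gamma * (1 - tt)[:, None] * start.eval(zz)
                    + tt[:, None] * target.eval(zz))

        def homotopy_jac(zz, tt):
            return (gamma * (1 - tt)[:, None, None] * start.jacobian(zz)
                    + tt[:, None, None] * target.jacobian(zz))

        for _ in range(config.max_sweeps):
            act = status == 0
            if not act.any():
                break
            za, ta, dta = z[act], t[act], dt[act]
            t_next = np.minimum(ta + dta, 1.0)
            step = t_next - ta
            # Euler predictor: J dz = -dH/dt * step
            J = homotopy_jac(za, ta)
            dHdt = -gamma * start.eval(za) + target.eval(za)
            ok = np.ones(len(za), dtype=bool)
            with np.errstate(all="ignore"):
                try:
                    dz = np.linalg.solve(J, -dHdt[..., None])[..., 0]
                except np.linalg.LinAlgError:
                    dz = np.zeros_like(za)
                    for i in range(len(za)):
                        try:
                            dz[i] = np.linalg.solve(J[i], -dHdt[i])
                        except np.linalg.LinAlgError:
                            ok[i] = False
            zp = za + dz * step[:, None]
            # Newton corrector at t_next
            for _it in range(config.corrector_iters):
                Jc = homotopy_jac(zp, t_next)
                Hc = homotopy_eval(zp, t_next)
                with np.errstate(all="ignore"):
                    try:
                        upd = np.linalg.solve(Jc, Hc[..., None])[..., 0]
                    except np.linalg.LinAlgError:
                        upd = np.zeros_like(zp)
                        for i in range(len(zp)):
                            try:
                                upd[i] = np.linalg.solve(Jc[i], Hc[i])
                            except np.linalg.LinAlgError:
                                ok[i] = False
                zp = zp - upd
            res = np.abs(homotopy_eval(zp, t_next)).max(axis=1)
            scale = 1.0 + np.abs(zp).max(axis=1)
            good = ok & np.isfinite(res) & (res < config.corrector_tol * scale)
            # apply
            idx = np.where(act)[0]
            gi = idx[good]
            z[gi] = zp[good]
            t[gi] = t_next[good]
            streak[gi] += 1
            grow = streak[gi] >= 3
            dt[gi[grow]] = np.minimum(dt[gi[grow]] * 2.0, config.dt_max)
            bi = idx[~good]
            dt[bi] *= 0.4
            streak[bi] = 0
            # terminal conditions
            znorm = np.abs(z[idx]).max(axis=1)
            diverged = znorm > config.norm_cap
            status[idx[diverged]] = 2
            failed = (dt[idx] < config.dt_min) & (status[idx] == 0)
            status[idx[failed]] = 3
            done = (t[idx] >= 1.0 - 1e-14) & (status[idx] == 0)
            status[idx[done]] = 1
        status[status == 0] = 3  # sweep budget exhausted
        results_z[lo:hi] = z
        st = np.empty(N, dtype=object)
        st[status == 1] = "converged"
        st[status == 2] = "diverged"
        st[status == 3] = "failed"
        results_status[lo:hi] = st
    return results_z, results_status


def refine_endpoint(target: CompiledSystem, z0, config: TrackerConfig):
    """Arbitrary-precision Newton polish; returns (point, residual, ok)."""
    with mp.workdps(config.refine_digits):
        z = [mp.mpc(complex(c)) for c in z0]
        for _ in range(config.refine_iters):
            F = target.eval_mp(z)
            resid = max(abs(f) for f in F)
            if resid < mp.mpf(10) ** (-config.refine_digits + 8):
                break
            J = target.jacobian_mp(z)
            try:
                dz = mp.lu_solve(J, mp.matrix(F))
            except Exception:
                return tuple(z), float(resid), False
            z = [zi - dz[i] for i, zi in enumerate(z)]
            if max(abs(d) for d in dz) < mp.mpf(10) ** (-config.refine_digits + 5):
                F = target.eval_mp(z)
                resid = max(abs(f) for f in F)
                break
        else:
            F = target.eval_mp(z)
            resid = max(abs(f) for f in F)
        ok = resid < mp.mpf(10) ** (-config.refine_digits // 2)
        return tuple(z), float(resid), bool(ok)


def refine_and_classify(endpoints, statuses, target: CompiledSystem, n_p: int,
                        config: TrackerConfig, stratum=None):
    """Polish converged endpoints, deduplicate, set flags."""
    points = []
    for z0, st in zip(endpoints, statuses):
        if st != "converged":
            continue
        zr, resid, ok = refine_endpoint(target, z0, config)
        zc = tuple(complex(c) for c in zr)
        if not all(math.isfinite(c.real) and math.isfinite(c.imag) for c in zc):
            continue
        if not ok and resid > config.endpoint_tol:
            continue  # spurious endpoint (left over from a failed polish)
        is_real = max(abs(c.imag) for c in zc[:n_p]) < config.real_tol
        is_pos = is_real and all(c.real > config.positivity_tol for c in zc[:n_p])
        Jf = target.jacobian(np.array([zc]))[0]
        try:
            cond = np.linalg.cond(Jf)
        except np.linalg.LinAlgError:
            cond = np.inf
        points.append(
            CriticalPoint(
                coords=zc,
                n_p=n_p,
                residual=resid,
                is_real=is_real,
                is_positive=is_pos,
                is_regular=bool(np.isfinite(cond) and cond < 1e10),
                refined=ok,
                stratum=stratum,
            )
        )
    return dedup_points(points, config.dedup_tol)


def dedup_points(points, tol):
    """Merge points whose probability-block coordinates coincide."""
    kept = []
    for pt in points:
        merged = False
        for other in kept:
            if len(pt.coords) == len(other.coords):
                d = max(
                    abs(a - b) for a, b in zip(pt.p_block, other.p_block)
                )
                if d < tol:
                    other.multiplicity += pt.multiplicity
                    merged = True
                    break
        if not merged:
            kept.append(pt)
    return kept


def solve_square_system(equations, variables, config: TrackerConfig = None,
                        seed: int = 0, strategy: str = "total_degree",
                        partition=None, n_p: int = None, stratum=None):
    """End-to-end solve of a square polynomial system.

    Returns all isolated finite solutions found along the homotopy,
    refined and deduplicated.  ``n_p`` marks the probability block for
    classification (defaults to all variables).
    """
    config = config or TrackerConfig()
    rng = np.random.default_rng(seed)
    n_p = n_p if n_p is not None else len(variables)
    target = CompiledSystem(equations, variables)
    start, sols = start_system(equations, variables, strategy, partition, rng)
    theta = rng.random() * 2 * np.pi
    gamma = complex(np.cos(theta), np.sin(theta))
    endpoints, statuses = track_paths(start, target, sols, gamma, config)
    pts = refine_and_classify(endpoints, statuses, target, n_p, config, stratum)
    counts = {
        "paths": len(sols),
        "converged": int((statuses == "converged").sum()),
        "diverged": int((statuses == "diverged").sum()),
        "failed": int((statuses == "failed").sum()),
        "gamma": gamma,
    }
    return pts, counts


def solve_stratum(system, config: TrackerConfig = None, seed: int = 0,
                  strategy: str = "multihomogeneous", check_seeds=()):
    """Solve one stratum's Lagrange system; keep solutions with every
    probability coordinate away from zero, verified against the full
    generator list of the stratum (relevant under randomized squaring).
    """
    config = config or TrackerConfig()
    variables = list(system.unknowns)
    n_p = len(system.p_vars)
    partition = (list(system.p_vars), list(system.lam_vars))
    if not system.lam_vars:
        strategy = "total_degree"
    pts, counts = solve_square_system(
        list(system.equations), variables, config, seed, strategy,
        partition if strategy == "multihomogeneous" else None, n_p,
        stratum=system.stratum,
    )
    verify = CompiledSystem(list(system.verify_polys), list(system.p_vars))
    out = []
    for pt in pts:
        if any(abs(c) < config.zero_tol for c in pt.p_block):
            continue  # zero coordinate: log-likelihood is -inf there
        resid = np.abs(verify.eval(np.array([pt.p_block]))).max()
        if resid > 1e-6:
            continue  # artifact of randomized squaring
        out.append(pt)
    for extra_seed in check_seeds:
        pts2, _ = solve_square_system(
            list(system.equations), variables, config, extra_seed, strategy,
            partition if strategy == "multihomogeneous" else None, n_p,
            stratum=system.stratum,
        )
        n2 = sum(
            1
            for pt in pts2
            if all(abs(c) >= config.zero_tol for c in pt.p_block)
            and np.abs(verify.eval(np.array([pt.p_block]))).max() <= 1e-6
        )
        if n2 != len(out):
            counts.setdefault("seed_mismatch", []).append((extra_seed, n2))
    counts["kept"] = len(out)
    return out, counts
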