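# Methods

## Model

A group-based substitution model fixes a finite abelian group `G`
(states = group elements) and a labeling `L : G → 𝓛`; rate matrices
satisfy `Q[g,h] = ψ(h−g)` with `ψ` constant on labeling classes,
`Σ_g ψ(g) = 0`, and `ψ(g) ≥ 0` off the identity.  Symmetry
(`Q[g,h] = Q[h,g]`) is equivalent to `L(g) = L(−g)` and makes all
Fourier quantities real.  Branch lengths are absorbed into `ψ` (there
is no separate time parameter).  The two-state model (`G = Z2`,
identity labeling) is the built-in, fully supported case; the group
and transform machinery accepts any finite abelian group, but the
inequality pipeline requires exponent two (otherwise the monomial
exponents of the squared-parameter conditions are not real and the
construction is rejected as unsupported).

The forward map factors as `ψ → ψ̌ = Kψ → f̌ = exp(ψ̌) → q → p`:
`K` is the character matrix, `q_g = ∏_e f̌_e(*g_e)` with `*g_e` the sum
of the leaf states below edge `e`, and `p = H⁻¹q` with `H = K^{⊗n}`.
Non-uniform root distributions are handled by rerooting: a hidden leaf
is attached at the root and its edge carries the Fourier transform of
the root distribution; uniform roots instead force `q_g = 0` on
patterns whose states do not sum to the identity.  Matrix exponentials
are computed exactly by character diagonalization
(`P = K⁻¹ diag(exp(Kψ)) K`), never by series.

All of this is exact arithmetic (sympy rationals and roots of unity);
floating point enters only in the numerical solver.

## Implicit description

Equations: the toric phylogenetic invariants, computed as the kernel of
the monomial parametrization by eliminating the per-edge Fourier
variables from the graph ideal (a polynomial ring map, so elimination
is exactly the kernel; no saturation is needed), plus the normalization
`q_{0…0} = 1`, plus (uniform case) the parity-forced linear forms.
The claw-tree two-state invariants also ship as a precomputed constant.

Inequalities: for each edge and each nonzero dual element, the
condition that the recovered rates be nonnegative becomes, after
squaring, a monomial inequality in the squared Fourier edge parameters;
each `[f̌_e(h)]²` is a quotient of Fourier coordinates (products over
well-chosen auxiliary leaves).  Because the retained coordinates are
strictly positive and `q_{0…0} = 1`, denominators can be cleared and
the two sides homogenized with powers of `q_{0…0}`, giving polynomial
inequalities with integer coprime coefficients and a fixed sign
convention (lex-leading coefficient positive for equations; positive
scaling only for inequalities, preserving orientation).  Strict
positivity of the non-forced Fourier coordinates completes the
description.  The biased-to-one case is produced from the biased-to-
zero case by the global state swap (odd-parity coordinates change
sign); a distribution is in the model iff it satisfies at least one of
the three root cases.

The auxiliary-leaf choices in the quotient formulas are immaterial on
the model itself, where all Fourier coordinates are positive.  They do
matter in two places, which the implementation handles explicitly:

- *Recovery at boundary points.*  `recover_parameters` enumerates all
  valid auxiliary-leaf choices (observed leaves meeting the edge's
  endpoints from distinct branches, hidden-root-leaf variants last) and
  uses the first whose denominator entries exceed `1e-8`; a squared
  parameter below `(1e-6)²` is reported as an infinite rate via a
  dedicated sentinel, never as a floating overflow.
- *Stratification symmetry.*  The cleared polynomials of different
  choices differ off the positive region, so the boundary arrangement
  generated from any one choice need not be invariant under the tree's
  leaf symmetries; the stratum family is therefore closed under the
  leaf automorphism group (below).

## Stratification

The likelihood is maximized over each root case with strict
inequalities relaxed.  By the KKT active-set argument, every critical
point lies, for some subset `S` of the relaxed constraints, on the
variety of `⟨H, G_i : i ∈ S⟩`; the relaxed constraint list contains
**both** the cleared edge inequalities **and** the relaxed strict
positivity forms.  Stratum ideals are decomposed into minimal primes.
For the binomial-generated ideals arising here the decomposition is
recursive factor splitting (branch on the distinct irreducible factors
of any reducible Gröbner basis element) plus saturation branching
(`V(I) = V(I : v^∞) ∪ V(I + v)` when a variable saturates
nontrivially), followed by an inclusion-minimality filter.  A
non-splittable non-prime leaf would simply be kept whole — a coarser
but still correct cover.

Components on which some probability coordinate, or some sum of
probability coordinates, vanishes identically are pruned: the
log-likelihood is `−∞` there.  Membership of all 2^n−2 subset sums is
tested via normal forms — reduction modulo a fixed Gröbner basis is
linear and normal forms are closed under addition, so each coordinate
is reduced once and subset sums of the normal forms are inspected for
cancellation.

Rather than enumerating all `2^m` subsets, the family of decomposed
active-set ideals is generated as a closure: starting from `⟨H⟩`,
repeatedly add one not-yet-contained constraint to a current stratum,
decompose, prune, and deduplicate by reduced Gröbner basis (fixed
order: grevlex with variables in pattern-lexicographic order, so the
dedup keys are stable).  Finally the family is closed under the tree's
leaf automorphisms.  The stratification depends only on the model, not
the data, and is computed once and cached; the biased root cases share
it, and the uniform case's strata embed in it (its extra equations are
active positivity constraints) — the uniform case is nevertheless
stratified independently and merged as a cross-check.

For the two-state claw tree this produces 44 strata: the model closure
(dimension 4 in the affine `q_{000}=1` slice), four zero-rate-edge
independence strata and eight coordinate subspaces at dimension 3,
24 surfaces, 6 lines, and the uniform point.

## Critical systems and solver

On a stratum with generators `g_j` the critical equations are the
denominator-cleared Lagrange conditions

    u_k − p_k Σ_j λ_j ∂g_j/∂p_k = 0   (one per pattern k),
    g_j = 0,

square in the probability and multiplier blocks.  Generating sets are
first minimized greedily (reduced Gröbner bases over-generate; the
independence strata need 5 of their 10 basis elements), keeping the
systems complete intersections; if a stratum still has more generators
than its codimension, the constraints are replaced by random integer
combinations (randomized squaring) and endpoints are re-verified
against the full generator list.

The solver is a standard homotopy continuation tracker:

- **Start systems.**  Total degree (roots of unity), or the default
  two-block multihomogeneous linear-product start on the partition
  (probability block | multiplier block), exploiting that multipliers
  enter the gradient equations linearly.  On the closure stratum this
  means 8960 paths instead of the 52488 of a total-degree start.  Start
  solutions are enumerated combinatorially (one vanishing linear factor
  per equation, block counts matching block sizes) and solved as small
  linear systems.
- **Tracking.**  `H(z,t) = γ(1−t)G(z) + tF(z)` with a random unit
  `γ` (recorded), Euler predictor, three-iteration Newton corrector,
  adaptive steps (initial 0.1, growth ×2 after 3 accepted steps,
  shrink ×0.4 on rejection, floor 1e-8), divergence cap `|z| > 1e8`,
  batch-vectorized over paths.  Every path ends `converged`,
  `diverged`, or `failed` (conservation is asserted in tests).
- **Refinement and classification.**  Converged endpoints are polished
  by Newton iteration at 50 decimal digits (mpmath); endpoints that
  fail to polish below 1e-8 residual are discarded as spurious.
  Deduplication merges points whose probability blocks agree within
  1e-6 (multiplicity recorded).  A point is *real* if every
  probability-block imaginary part is below 1e-6, *positive* if real
  with all probability coordinates above 1e-9, *regular* if the
  Jacobian condition number is below 1e10.  Solutions with a
  probability coordinate inside 1e-9 of zero are dropped (the
  log-likelihood is −∞ there).  All thresholds are configurable on
  `TrackerConfig`.

Per-stratum randomness (gamma, start coefficients, squaring
coefficients) derives deterministically from the run seed, so reports
are reproducible byte for byte.

## Ranking, membership, verdict

Pooled real positive critical points are ranked by exact-summation
log-likelihood at refined (unrounded) coordinates.  Membership of a
candidate in a root case is sign evaluation at tolerance 1e-7:
`relaxed` = equations + non-strict inequalities (the case's closure),
`strict` additionally the strict inequalities (the open model).  The
supremum of the likelihood over the compact closure is attained at the
best relaxed member; if that point is also a strict member the MLE
exists there (tight non-strict inequalities correspond to zero-rate
edges, which are in the model), otherwise the supremum is approached
only as an edge rate diverges and the verdict is nonexistence.  Ties
within 1e-9 log-likelihood yield an `inconclusive-tie` verdict listing
all tied points.  Multiplier signs are recorded as diagnostics, not
used as a filter: ranking among feasible points already identifies the
global optimum, and discarding sign-violating points would hide
informative saddle structure from the report.

## Synthetic data

`sample_counts` draws multinomial pattern counts from a parametrized
distribution with an explicit seed (numpy `default_rng`), emulating
i.i.d. site patterns from the model — the only sampling mechanism the
likelihood analysis assumes.  It does not emulate alignment error,
across-site rate heterogeneity, or model misspecification, so passing
tests certify the estimator's algebra and optimization, not robustness
to violations of the substitution model.  The packaged demonstration
count vector is a single realized 100-sample draw from rates
(root 0.25, leaf edges 0.75 / 50 / 0.25) — a regime with one
effectively saturated edge and a nearly uniform root, chosen to sit
close to the model boundary; being one multinomial realization, it is
shipped as a fixture rather than regenerated.

## Problem sizes and limitations

The end-to-end analysis solves 44 strata: 8960 paths on the closure
stratum, about 7000 on each of the four independence strata, and a few
hundred or fewer elsewhere — roughly ten minutes on one CPU, with the
tracker in double precision and only endpoint polishing in high
precision.  Known limitations:

- No endgame for singular endpoints: points that fail high-precision
  polishing are kept only if their double-precision residual is small;
  genuinely singular critical points would be flagged `unpolished`
  rather than certified.
- The inequality pipeline covers symmetric models on groups of
  exponent two; larger exponents would need branch choices for complex
  monomial exponents that are deliberately not guessed.
- Constraint qualification (constant rank) is not verified globally;
  a Jacobian-conditioning flag is reported per candidate, and the
  verdict inherits the usual probability-one caveat for generic data.
- Stratification cost grows with the boundary arrangement; trees
  beyond a handful of leaves would need the elimination and
  decomposition steps replaced by dedicated toric machinery.
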