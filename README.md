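# algmle

Global maximum-likelihood estimation for symmetric group-based
phylogenetic models by numerical algebraic geometry.

## The problem

For a continuous-time group-based substitution model on a fixed rooted
tree (the two-state Cavender–Farris–Neyman model on the three-leaf claw
tree is the built-in worked case), the joint leaf-pattern probabilities
`p` form a *semialgebraic* set: polynomial equations (phylogenetic
invariants) plus polynomial inequalities cut out exactly the
distributions that arise from nonnegative rate parameters.  Hill-climbing
maximum-likelihood estimation (EM, quasi-Newton) can stall in local
optima and — worse — cannot tell when the likelihood supremum is only
approached as an edge rate diverges, i.e. when **no MLE exists** in the
model.  This package finds *all* critical points of the likelihood on
the model and on every boundary stratum, so the global optimum and its
existence status are certified up to the standard probability-one
guarantees of homotopy continuation.

## The method

Given pattern counts `u` with log-likelihood `l_u(p) = Σ u_i log p_i`:

1. **Implicit description.**  In Fourier coordinates `q = H p` (with `H`
   the n-fold Kronecker power of the group's character matrix) the model
   is `{toric binomials = 0, q_0 = 1, q > 0, cleared edge inequalities ≥ 0}`,
   one cleared monomial inequality per edge from the squared-parameter
   quotient formulas; one such system per root-distribution case
   (biased-to-0, biased-to-1 via state swap, uniform).
2. **Stratification.**  Strict inequalities are relaxed; every subset of
   active constraints defines a stratum.  Stratum ideals are split into
   minimal primes (binomial factor-splitting plus saturation in Fourier
   coordinates), components forcing a probability coordinate (or a
   nonnegative coordinate sum) to zero are pruned, duplicates are merged
   by reduced Gröbner basis, and the family is closed under the tree's
   leaf symmetries.  For the worked example this yields 44 strata.
3. **Critical points.**  On each stratum the cleared Lagrange system
   `u_k − p_k Σ_j λ_j ∂g_j/∂p_k = 0`, `g_j = 0` is solved completely by
   polynomial homotopy continuation (multihomogeneous start on the
   probability/multiplier split, gamma-trick path tracking,
   arbitrary-precision endpoint polishing).
4. **Verdict.**  Pooled real positive critical points are ranked by
   `l_u`; each is tested for membership in every root case.  If the best
   point on the model closure fails a strict positivity constraint, the
   supremum is attained only at infinite rates and the MLE does not
   exist.

## Worked example

The packaged count vector `u = (17, 5, 27, 5, 16, 5, 19, 6)` is a
realized 100-sample draw from near-boundary rates (one long edge, root
nearly uniform).  Running

```
algmle mle --seed 1 --out mle_out
```

prints (abridged):

```
data vector u = [17, 5, 27, 5, 16, 5, 19, 6] (n = 100)
strata solved: 44
critical points: 167 complex, 99 real, 51 strictly positive
  l = -188.4510  in-model=False  closure=False  p = (0.183, 0.051, 0.256, 0.055, 0.147, 0.053, 0.204, 0.052)
  l = -188.7215  in-model=False  closure=False  p = (0.183, 0.049, 0.243, 0.065, 0.156, 0.042, 0.207, 0.055)
  ...
  l = -189.4875  in-model=False  closure=True   p = (0.220, 0.050, 0.220, 0.050, 0.175, 0.055, 0.175, 0.055)
verdict: MLE-nonexistent
```

The single Zariski-closure stratum alone carries 92 complex critical
points (the model's ML degree).  The best candidate overall
(`-l = 188.451`) violates the sign constraints of every root case, so it
is not a distribution in the model; the best candidate *on the model
closure* (`-l = 189.488`) recovers rates `0.192` (root edge), `1.071`
(leaf edge 1), `0.080` (leaf edge 3) — and an **infinite** rate on leaf
edge 2, i.e. its Fourier edge parameter vanishes.  The likelihood
supremum is therefore approached only as that rate diverges: the MLE
does not exist for this data, something a hill-climber would report as
an innocuous interior optimum.

## Layout

- `algmle.group_fourier` — finite abelian groups, characters, exact
  discrete Fourier transforms.
- `algmle.model_param` — trees, rate vectors, the parametrization chain,
  rerooting, multinomial sampling, inverse parameter recovery.
- `algmle.semialgebraic` — toric invariants, squared-parameter
  quotients, the per-root-case constraint systems, p↔q conversion.
- `algmle.strata` — active-set stratification, minimal-prime splitting,
  pruning, Lagrange systems.
- `algmle.homotopy` — start systems, path tracker, endpoint refinement.
- `algmle.mle_pipeline` — orchestration, membership, ranking, verdict,
  reports; `algmle.cli` exposes `algmle sample|describe|strata|solve|mle`.
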