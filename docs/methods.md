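# Methods

This note records the models implemented in `residuehd`, the numerical
choices behind them, and what the synthetic test conditions do and do
not show about real data.

## Phasor encodings and exact phase arithmetic

A phasor vector stores D unit-magnitude complex components.  Fractional
power encoding modulo m draws one integer index k_j per component
(uniform on {0,…,m−1}, or {1,…,m−1} when an anti-base will be needed)
and encodes x as exp(2πi·k_j·x/m).  Internally every encoding built
from integers or exact rationals is carried as a pair (num, den) with
phases 2π·num_j/den, canonicalized (num mod den, common gcd divided
out) so that equal phase patterns always produce bit-identical complex
arrays.  Consequences:

- congruence (`z(x+m) == z(x)`), the additive homomorphism, the
  multiplicative homomorphism, and hexagonal path-independence are
  *bit-exact*, tested with array equality rather than tolerances;
- complex materialization happens in one shared routine, so no
  float-path drift can split two logically equal encodings.

Tolerances: unit magnitude is enforced to 1e-9; a kernel within 1e-6 of
1 is treated as identity (used when measuring the hexagonal period);
angle extraction for foreign (metadata-free) vectors snaps to the
2π/m grid only within 1e-6 rad and raises otherwise — a corrupted or
rational input is rejected rather than silently rounded.

Sampling includes index 0 by default, giving the δ-like kernel with
mean 0 at nonzero offsets.  `nonzero_only` sampling (required for
anti-bases, since 0 has no multiplicative inverse) shifts the mean
off-peak kernel to −1/(m−1); both means are tested against the analytic
value over 200 fresh bases.

## Binding operators

Addition is the Hadamard product (phases add).  Multiplication works on
per-modulus factors: with base index u, the component indices of the two
arguments are r = u·x₁ and s = u·x₂; forming r·s·v mod m with v = u⁻¹
(anti-base) yields u·x₁·x₂, i.e. the encoding of the product.  Prime
moduli guarantee the inverses exist.  When handed composed vectors, a
wrapper first recovers the factors with the resonator.  Division and
multiplication of rational encodings are deliberately unsupported.

## Resonator network

Update rule: asynchronous round-robin; factor j's estimate becomes
g(Z_j Z_j†(z ⊙ ∏_{i≠j} conj(ẑ_i))), where g divides every component by
its magnitude (exact zeros become 1).  Initialization is the
phase-normalized codebook superposition by default (deterministic;
note that for root-of-unity codebooks the superposition cancels almost
exactly on most components, so its normalized residual acts as a
pseudo-random but reproducible start), or i.i.d. random phasors —
used for restarts.

Two implementation details matter and are easy to get wrong:

1. **Global phase.**  g is componentwise, so a factor estimate can
   settle on e^{iγ}·(codebook entry); for two factors a joint phase
   offset is marginally stable.  Cleanup therefore ranks codebook
   entries by the *magnitude* of the inner product, which is invariant
   to γ.  (Direct codebook decoding of raw encodings keeps the
   real-part rule; raw encodings carry no global phase.)
2. **Stopping rule.**  Cosine similarity ≥ α between successive
   concatenated states (α = 0.95 everywhere) is necessary but not
   sufficient: near capacity the dynamics drift slowly, and successive
   states are nearly parallel long before the labels are right.
   Convergence additionally requires every factor estimate to be
   *committed*: its similarity with the nearest phase-normalized
   codebook entry must also reach the threshold (`commit_alpha`,
   default α).  A true fixed point satisfies both immediately; the
   early transient satisfies only the first.  Under von Mises phase
   noise the achievable ceiling drops by the Bessel ratio I₁(κ)/I₀(κ)
   (the expected kernel attenuation, ≈0.968 at κ=16, ≈0.446 at κ=1),
   so the noisy path scales `commit_alpha` by it.  Sub-integer decoding
   disables the commit requirement entirely, because a rational
   encoding is never an integer codebook entry; there, convergence
   means only that the state stopped moving.

`evals` counts every codebook row touched — updates, convergence
checks, and final cleanup — so it is bounded below by
iterations × Σ|codebook_k| and above by roughly twice that.
Non-convergent runs still return the cleanup of their final state,
flagged, so accuracy accounting and restart policies can use them.

Capacity experiments follow the definition C(D) = largest M with
empirical accuracy ≥ 0.95: windows of K consecutive primes are scored
on uniformly random targets until accuracy drops below the floor.
Trials advance in lock-step through the same update rule (a data-
parallel formulation over trials) so the per-sweep work is dense
matrix products; 50 trials at D=4096 with M ≈ 2.0×10⁶ certify in about
45 s on one core.  The Landau function g(b) — the maximum lcm over
partitions of a codebook budget b — is computed by a prime-power
dynamic program (exact; cross-checked against explicit partition
enumeration for b ≤ 12) and quantifies the best achievable range for a
budget: g(15) = 105 = 3·5·7.

## Hexagonal coordinates

2-D positions are projected onto the 'Mercedes-Benz' frame
Ψ = [(−√3/2, −1/2), (√3/2, −1/2), (0, 1)] (unit rows at mutual 120°,
rows summing to zero).  Each of the three coordinates is phase-encoded
modulo m with the per-component constraint k₁+k₂+k₃ ≡ 0 (mod m), which
makes the all-ones translation invisible — moving equally along all
three axes cancels — and hence gives every negative coordinate a
non-negative equivalent and makes paths commute.  Triples are sampled
uniformly on the constraint set via free (k₁, k₂).

State counting: the decodable states of one period are the zero-sum
integer triples in the max-norm hexagon of radius m−1, the centered
hexagonal number 3m²−3m+1 (61 at m=5, vs m²=25 for a square lattice),
at a codebook cost of 3m vs 2m.  This is a *spatial-resolution* count:
single-modulus encodings themselves depend only on (a−c, b−c) mod m, so
vector-level distinctness cannot exceed m²; the hexagonal advantage is
realized by the finer tiling of the plane, and the entropy comparison
measures exactly that.  Entropies are Shannon entropies of the state
occupancy induced by uniform samples over one period (rejection-sampled
hexagon for the hex code, m×m square for the square code), assigned to
the nearest state position in 2-D (Voronoi; ties to the first state in
canonical order).  At m=5 with 20,000 samples: ≈5.93 bits (hex) vs
≈4.64 bits (square).  The sampling region and density are this
package's choice; only the ordering (hex > square) is asserted, not any
particular entropy value.

## Sub-integer decoding

Rational q is encoded by exact phase scaling (phases 2π·k_j·q/m held as
exact fractions; decimal strings and floats are interpreted through
their shortest decimal form, so 40.4 means 202/5).  Decoding:
(1) resonate with integer codebooks until the state settles;
(2) clean each factor to its nearest integer residue and CRT-reconstruct
x̂; (3) build r candidates x̂ + (i − ⌊r/2⌋)/r spanning a unit window and
pick the best by codebook decoding against the input.  The symmetric
window makes the decoded value the nearest grid rational; candidates
are built on the composed vector (the per-modulus alternative would
also work but multiplies candidate sets).  The expected similarity at
real offset δ is the real part of the product over moduli of normalized
Dirichlet kernels — 1 at δ ≡ 0 (mod M), ≈0 at other integers,
oscillating between — and the empirical kernel matches it within
5/√D (tested at 50 random offsets).

Information is scored as
I(a, P) = a·log₂(Pa) + (1−a)·log₂(P(1−a)/(P−1)) bits per vector
(continuity at a ∈ {0,1}): zero at chance a = 1/P, log₂P at perfect
accuracy.  This closed form is fixed by the zero-at-chance property;
I(0.9, 100) = 5.512 bits.

## Subset sum

Instance encoding uses moduli {m−1, m, m+1} with even m (so the outer
pair, differing by 2, stays co-prime; the smallest feasible even m ≥ 4
with (m−1)m(m+1) > ΣS is chosen automatically).  Each item contributes
a two-entry factor {z(0), z(S_k)}; a zero-valued item is a degenerate
single-entry factor (include and exclude encode identically).  Every
decoded mask is verified by integer arithmetic — the vectors are never
trusted — so a reported success is always correct and the algorithm is
Las Vegas: restarts from fresh random initializations compound as
1−(1−p)ⁿ, which the tests verify against single-trial estimates within
binomial error on an instance tuned to sit in an informative success
band.  The exact dynamic-programming baseline is the oracle for all
stochastic tests.  The random generator caps the representable sum at
M/2 and draws items uniformly on [0, (M/2)/n]; targets are sums of
uniformly random subsets, so instances are always feasible.

## Scene factorization and the synthetic generator

A scene is a sparse set of feature activations A_j(x, y); its vector is
s = Σ h(x)⊙v(y)⊙d_j·A_j(x,y) with h, v residue position encodings and
d_j random phasor identities.  Encoding is linear in amplitudes and
translation-equivariant: a template translated by (x′, y′) encodes to
h(x′)⊙v(y′)⊙O(i), so recognition is resonator factorization with either
3 factors (objects, H, V: 10+105·2 = 220 stored vectors on the
10-object, 105×105 reference geometry) or 1+2K factors (objects plus
per-modulus position factors: 10+(3+5+7)·2 = 40 vectors), against a
brute-force search space of 110,250.  A converged run whose
reconstruction similarity with the input falls below a threshold
(default 0.5) is treated as a spurious fixed point and restarted from
random initialization.

The synthetic generator stands in for a learned convolutional
sparse-coding front end: templates are a handful of random feature
activations with uniform [0.5, 1.5] amplitudes, and the scene is one
template translated on a torus (positions mod the grid), which makes
the shift theorem exact.  What it does not emulate: correlated feature
dictionaries, amplitude statistics of real images, boundary effects of
non-toroidal shifts, or multiple overlapping objects with occlusion —
so passing tests demonstrate the algebra and the factorization
machinery, not performance on natural images.  Externally computed
feature maps can be supplied through the `FeatureMap` CSV container.
Evaluation-count averages that depend on sparse codes learned from
real images, and all wall-clock comparisons, are intentionally not
reproduced.

## Problem sizes used by tests and the acceptance script

Worked examples run at the reference sizes (D = 1024 for binding and
subset sum, D = 512 for sub-integer decoding).  The capacity
certification runs K = 2, D = 4096 at the smallest consecutive-prime
product above 2×10⁶ with 50 Monte-Carlo trials.  Scene accuracy is
exercised at D = 2000 with 10 objects on the 105×105 grid, and at
smaller grids for the equivariance and explaining-away property tests.
Noise experiments use κ ∈ {1, 16}.  These sizes were chosen so the full
suite exercises every regime at single-core scale.

## Known limitations

- The committed-convergence rule is this package's resolution of an
  ambiguity in the stopping criterion; with it, α controls both state
  stability and commitment.  Setting `require_commit=False` restores
  the bare successive-state rule.
- Anti-bases (and hence multiplication) require prime moduli and
  nonzero index sampling; the subset-sum moduli {m−1, m, m+1} are fine
  because the solver only ever adds.
- Exact phase arithmetic bounds the representable denominator
  (M·s ≤ 2⁴⁰) — ample for the ranges studied here, but not unbounded.
- `exact_dp` is pseudo-polynomial (O(|S|·T) table); it is a test oracle,
  not a competitive solver.
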