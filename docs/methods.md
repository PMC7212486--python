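# Methods

## Model

`coalafs` computes the expected allele frequency spectrum (AFS) of a
sample of *n* haplotypes drawn from a single panmictic population whose
haploid size *N(t)* varies arbitrarily in backward time (*t* = 0 is the
present). The framework is the time-rescaled coalescent: defining the
time-scaling function

    g(t) = ∫₀ᵗ 1/N(u) du,

the rescaled coalescence times τₘ = g(Tₘ) follow the standard Kingman
*n*-coalescent, so E[τₘ] = μₘ = 2(1/m − 1/n) and
σₘ² = Var(τₘ) = Σ_{k=m+1}^{n} 4/(k²(k−1)²) (sum of the independent
exponential epoch variances). A first-order Taylor expansion of g⁻¹
around μₘ gives the working approximations

    E[Tₘ] ≈ g⁻¹(μₘ),        Var[Tₘ] ≈ σₘ² · N(E[Tₘ])²,

the variance using g′(t) = 1/N(t) evaluated at the first-order mean.
With the intercoalescence times E[W_k] = E[T_{k−1}] − E[T_k] (T_n ≡ 0)
the expected spectrum under the infinitely-many-sites model is

    E[S_j] = Σ_{k=2}^{n} [C(n−j−1, k−2)/C(n−1, k−1)] · μ · k · E[W_k],

where μ is the per-locus per-generation mutation rate.

### Assumptions

- Single population, no migration, splits, selection or recombination.
- Infinitely-many-sites mutation; E[S_j] are Poisson means (no sampling
  noise is added).
- Sizes are haploid (sequence counts). The CLI's `--diploid` flag doubles
  user-supplied sizes on input.

## Demographic families

| family | backward form N(t) | parameters (defaults in study settings) |
|---|---|---|
| constant | N₀ | N₀ |
| exponential | N₀·e^(−γt) | N₀, γ per generation |
| logistic | Nk·e^(γT)/(e^(γT)+(Nk−1)·e^(γt)) | Nk, γ, onset T; founding size 1 |
| gompertz | N₀·exp((γ/α)(1−e^(−α(T−t)))) | N₀, γ, α, T |
| piecewise | right-continuous step function | breakpoints (tᵢ, Nᵢ), t₀=0 |

The logistic and Gompertz backward forms follow from substituting
forward time = T − t into the forward solutions of their growth ODEs.
Both are evaluated for *all* t ≥ 0: past the onset the size decays below
one, which guarantees coalescence; this deliberate extrapolation can be
overridden with `size_floor`, which clamps N(t) from below (a departure
from the pure growth-curve treatment, for users who want a constant
ancestral size).

## Inversion schemes

Three interchangeable ways to compute E[Tₘ] = g⁻¹(μₘ):

1. **Finite-sum scan** (`invert_scale_finite_sum`). Approximate g by the
   left-endpoint Riemann sum G(t) = Σ_{u=0}^{t} step·(1/N(u)) and advance
   t once, harvesting every target μ in ascending order. When G first
   reaches μ the returned time is t if G − μ < step/N(t) and t − step
   otherwise; with a strict G < μ loop guard the else-branch is
   mathematically unreachable (the final increment is exactly step/N(t))
   and is retained purely as floating-point rounding protection. The
   alternative `overshoot_rule="nearest"` returns whichever neighbour has
   G closest to μ. Because the scan never rewinds, the number of N(t)
   evaluations is set by the oldest target alone — cost is O(depth), not
   O(n·depth). Default step: 1 generation; a warning recommends a
   sub-generation step when N(0) < 100, where the per-step mass 1/N is
   coarse. Internally N is evaluated in blocks of 8192 steps for speed;
   this changes neither results nor the algorithmic evaluation count
   reported by `return_eval_count`.
2. **Root-finding** (`invert_scale_root`). Solve g(t) − μ = 0 with a
   bracket grown geometrically from N(0)·μ (exact for constant size, an
   upper bound whenever N is non-increasing backward), Brent's method,
   and a Newton polish using the exact derivative g′ = 1/N. Default
   tolerance 1e−10 relative on g.
3. **Closed forms** (`invert_scale_analytic`). Constant: N₀μ.
   Exponential: g⁻¹(μ) = ln(N₀γμ + 1)/γ. Logistic: with
   A = (Nk−1)e^(−γT) and C = Nkγμ + A,
   g⁻¹(μ) = (C − W₀(A·e^C))/γ, W₀ the principal Lambert W branch
   (A > 0, so the argument is always inside the branch domain; it is
   evaluated from its logarithm, with an asymptotic Newton solve of
   w + ln w = ln A + C when e^C would overflow).

The root-finder needs a pointwise g for every family. Constant,
exponential and logistic use the closed forms above (the logistic g was
derived by integrating 1/N(t) = 1/Nk + (Nk−1)e^{γ(t−T)}/Nk, giving
g(t) = [(Nk−1)e^(−γT)(e^(γt)−1) + γt]/(Nkγ), verified against adaptive
quadrature to 1e−9 relative in the tests). The Gompertz integral has the
exact expression

    g(t) = e^(−γ/α)/(N₀α) · [Ei((γ/α)e^(−α(T−t))) − Ei((γ/α)e^(−αT))]

through the exponential integral Ei, and piecewise histories integrate
exactly epoch by epoch; both are likewise quadrature-verified. Closed
forms saturate once their exponents exceed ~600–700 (values there are
~10³⁰⁰, hundreds of orders of magnitude past any reachable target), so
deep bracket probes stay finite.

## Spectrum assembly

All binomial coefficients are evaluated as log-gamma differences and
exponentiated per (j, k) term; structurally zero terms (j > n−k+1)
short-circuit before exponentiation. The factorial front-factor form of
E[S_j] is never used at run time — its coefficients overflow doubles for
n ≳ 170 — but serves as the exact-rational brute-force oracle (stdlib
`fractions`) in the tests at n ≤ 12. The n = 2000 constant-size spectrum
reproduces θ/j to ~3e−12 relative, confirming the log-space path.

## Monte-Carlo oracle

`estimate_afs_mc` draws scaled epochs Exp(k(k−1)/2), accumulates them
into τₘ, and maps each draw through the numeric inverse of g
(root-finding at 1e−8 tolerance, warm-started in sorted order). Spectrum
estimates are Rao-Blackwellized: each replicate contributes the expected
spectrum given its sampled W_k, so no mutation-placement noise enters
and standard errors reflect genealogical noise only. The RNG is numpy's
default (PCG64) with the seed recorded in the `McEstimate`; identical
seeds reproduce results bit-for-bit.

The oracle deliberately separates two questions. (1) *Engine
validation*: the MC mean of mapped times must equal E[g⁻¹(τₘ)], which
the tests also compute deterministically by quadrature against the exact
hypoexponential density of τₘ — agreement within 3 SE on all families.
(2) *Approximation audit*: the first-order point value g⁻¹(μₘ) is a
smooth-curve approximation to that mean, biased upward by the Jensen gap
of the concave g⁻¹. The audit shows the bias is small at the spectrum's
dominant levels but reaches ~8–9% at intermediate m for the logistic
study setting at n = 10 (and up to ~20% for the exponential model's
oldest levels), so consumers comparing against simulation means should
expect the gap; it is a property of the first-order method, not of this
implementation. Because the AFS weights every level by k·E[W_k] and the
two AFS construction routes (finite-sum vs analytic) share the
first-order step, the cross-route AFS agreement is far tighter (per-entry
|log ratio| < 0.007 at the logistic settings).

## Problem sizes and numerical choices

Tests and the acceptance script use n = 51 for the logistic AFS
comparison (spectrum entries 1..50), n ∈ {10, 50, 100, 500} for the
exponential closed-form check, n = 2000 for the overflow check, and
10,000 MC replicates at n = 10 — matching the study conditions
throughout. Ties in finite-sum expected times (two adjacent μ targets
landing on the same generation, possible at n ≳ 500) yield W_k = 0,
which the spectrum accepts. Degenerate inputs: zero mutation rate gives
an all-zero spectrum whose normalization raises; reps = 1 gives NaN
standard errors; a history whose ancient size makes the target
unreachable within `max_time` raises a non-coalescing error.

## Known limitations

- First-order moments only; no higher-order Taylor corrections, no
  marginal densities or cross-level covariances of Tₘ.
- Expected (noise-free) spectra; no Poisson sampling, folding, or
  likelihood machinery.
- Single population; no migration or multi-population joint AFS.
- The synthetic histories are idealized growth curves; real data add
  sampling noise, linked selection and population structure that the
  generator does not emulate, so passing tests demonstrate correctness
  of the computation, not fit to any real population.
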