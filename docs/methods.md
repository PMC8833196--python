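# Methods

## Scope and model

The package treats evolution at equilibrium as a maximum-entropy problem.
Three layers are implemented, each exact at its own level of description:

1. **Microscopic/exact** (`gibbs`, `landscape`, `origin_fixation`): finite
   state spaces, exact Gibbs calculus, and a weak-mutation Markov chain with
   a provably correct stationary law.
2. **Phenomenological** (`phenomenology`): the closed-form population loss
   U(S, K) = a·Sⁿ·exp(bK/S) and its thermodynamic-potential calculus.
3. **Phase-transition** (`transitions`): coexistence of a molecular and an
   organismal grand-potential family under dual variable mappings.

All entropies are in nats and all logarithms natural, matching the physics
convention. Continuous environment-state integrals are realized as finite
sums — a discretization choice; none of the implemented identities depend on
it, and tolerances below refer to the finite realization.

## Gibbs layer

For a loss table H over states, `partition_function` computes
log Z = log Σ exp(−βH) via max-shifted log-sum-exp, so β up to 10³ cannot
overflow. `gibbs_ensemble` returns p ∝ exp(−βH), U = Σ pH, S = −Σ p log p
and F = −log Z/β; the identity F = U − S/β holds to < 1e−9 relative by
construction and is asserted in tests. β < 0 (negative evolutionary
temperature) is rejected: nothing in the formalism uses it.

`solve_beta_for_loss` inverts the strictly decreasing map β ↦ U(β) by
bracketed Brent root-finding (tolerance 1e−10 on β; the bracket is grown by
doubling from [0, 1]). Degenerate tables (all H equal) return β = 0 by
convention, since every β satisfies the constraint. Targets at or below
min(H), or above mean(H) (the negative-β branch), raise.

`maxent_verify` is the package's internal oracle for the variational origin
of the Gibbs law: it maximizes entropy directly over the probability simplex
subject to the two equality constraints (normalization, fixed U) with SLSQP
(ftol 1e−16, up to 3 restarts from Dirichlet draws), never using the
exponential-family solution, and reports the max-norm distance to the
analytic probabilities. Distances are typically ~1e−9; the contract is 1e−6.
Non-convergence is flagged in the report, never silent.

## Landscapes and the mutation graph

Genotypes are strings over digits 0..A−1 (unambiguous TSV serialization);
the mutation graph connects Hamming-distance-1 pairs and is regular with
degree L(A−1). Enumeration is capped at A^L ≤ 10⁵. Three landscape kinds:

- **additive** — per-site contributions, F(q) = Σᵢ fᵢ(qᵢ); this is the
  epistasis-free regime in which the temperature-ratio statistic is exact.
  Site effects are stored so additivity is directly checkable.
- **random_field** — additive plus i.i.d. Normal(0, σ_epi) epistatic noise
  per genotype (σ_epi = 0.5 by default).
- **house_of_cards** — i.i.d. Normal(0, σ) per genotype, maximal ruggedness.

Random effects default to Normal(0, σ = 1), the standard scale for synthetic
landscape studies; all draws come from a dedicated generator seeded per
landscape, so identical (kind, params, seed) give byte-identical TSV output.
The three variable classes are operationalized as site annotations: constant
(core) sites are masked from mutation, neutral sites carry zero effect,
remaining sites are the adaptable variables.

These synthetic landscapes emulate the *structure* assumed by the theory
(finite genotype space, additivity or controlled departures from it, fixed
environment); they do not emulate codon structure, realistic fitness-effect
distributions, linkage, or changing environments, so passing tests show the
formalism and its estimators are internally correct, not that real data
satisfy their assumptions.

## Origin-fixation chain

One event = propose a uniformly random Hamming-1 neighbor (symmetric
proposal, so mutational bias does not enter the stationary law), accept with
the fixation probability of a single mutant of relative fitness
w = exp(−β ΔF):

- **moran**: (1 − 1/w)/(1 − w^−Ne), the haploid Moran closed form, evaluated
  via expm1 of log w for stability near w = 1 and at extreme w; neutral
  limit 1/Ne.
- **metropolis**: min(1, w^ν)/Ne with ν = Ne − 1 by default (configurable),
  which has the same stationary law and neutral fixation rate.

Both satisfy detailed balance with π ∝ exp(−β ν F), ν = Ne − 1 for moran —
the kernel-derived exponent. The exponent in the equilibrium law is a known
ploidy/bookkeeping convention (Ne vs Ne − 1 and factors 1, 2, 4); the package
resolves it by *self-consistency*: `exact_stationary` always uses the
simulating kernel's true ν, and a ν override is exposed on the Metropolis
kernel rather than hidden. Detailed balance is verified edge-by-edge in the
tests (residual < 1e−12).

Defaults: burn-in = steps/10, no thinning (the full visit record is kept),
seed 0. The visit record stores the resident genotype after every proposal
event, so consecutive visits differ by at most one site.

### Temperature-ratio estimator

For two equilibria on a shared landscape, r(q) = log Z⁽¹⁾(q)/log Z⁽²⁾(q)
equals β₁/β₂ for every q. The estimator takes per-genotype log Z maps,
excludes |log Z⁽²⁾| ≤ 1e−6 (near-zero denominators), and returns the median
of r(q) (robust default; weighted least squares through the origin is an
option) plus the max absolute deviation from the median as the
q-independence diagnostic. When log Z is estimated from visit frequencies,
log Ẑ(q) = (log p̂(q) − log p̂(q_ref))/ν with q_ref a shared reference
genotype (default: the most frequent), which fixes the additive gauge that
raw frequencies cannot determine; using the same reference in both runs
makes the ratio exact in expectation. At Ne = 20 and 10⁵ events per chain on
a 4-genotype additive landscape the ratio is recovered within 5%.

## Ideal gas of organisms

Parameters: a > 0 (loss scale, sets units of U), b > 0 (stochasticity
coefficient in Ne = exp(bK/S)), n > 1 (environment-entropy exponent;
diverse environments mean higher per-organism loss). Analytic intensives:

    μ = (b/S)·U,      𝒯 = (μ/b)(n − bK/S),

verified against central finite differences (step 1e−5 × variable scale)
and against the equivalent closed form
𝒯 = (μ/b)(n + log(ab/μ) + (n−1) log S). The grand potential satisfies
Ω = U − 𝒯S − μK = (1−n)Sμ/b = (1−n)U identically. The intensive route
inverts the temperature relation for S (possible only for n ≠ 1, which is
why n = 1 is rejected) and agrees with the extensive route to 1e−8 relative.
The widely quoted explicit form −a(n−1)(μ/eb)^{n/(n−1)} exp(b𝒯/((n−1)μ))
carries the prefactor a instead of a^{−1/(n−1)}; the package's canonical Ω
is defined by the Legendre construction, which is internally exact, and the
explicit form is checked (and holds) at a = 1.

Because U is homogeneous of degree n, Euler's theorem gives 𝒯S + μK = nU;
the degree-1 relation U = 𝒯S + μK holds only at n = 1. The package therefore
*reports* the Euler ratio (𝒯S + μK)/U rather than asserting the degree-1
form, leaving the interpretation to the caller. The first-law check
evaluates dU symmetrically about (S, K) so the quadratic Taylor term
cancels and the residual against 𝒯dS + μdK is O(d³).

### Cumulant reconstruction

`cumulants_from_samples` uses exact unbiased k-statistics for κ₁..κ₄ and
plug-in raw-moment recursion for orders 5..m (biased at O(1/n), documented);
default truncation m = 6, hard cap m = 10, and a minimum sample size of
10·m. `reconstruct_grand_potential` evaluates
Ω = −𝒯 Σ κⱼ(μ/𝒯)ʲ/j!; since the series' convergence radius is not known in
general, a heuristic warning fires when the last retained term exceeds 1% of
the partial sum (note this necessarily fires for very short series such as
the exact Gaussian m = 2 case). Against closed-form CGFs: Gaussian is exact
at m = 2; Poisson converges geometrically, reaching < 1e−6 absolute error at
m = 10, μ/𝒯 = 0.5.

## Phase transition

Proportionality constants C_p, C_b are explicit parameters defaulting to 1
(the coexistence condition is underdetermined without them). Grand
potentials are evaluated in log space; the favored phase is the one with
the smaller value. The temperature dual 𝒯₀ = (αμ₀/b) log T₀ and chemical
dual M₀ = (c/γ) T₀ log μ₀ make Ω_p = Ω_b an identity at C_p = C_b; the
solver's critical point additionally imposes 𝒯₀ = T₀, i.e. the fixed point
T = k log T on T > 1 (log T must be positive, hence the domain restriction).
Root classification is analytic (k ⋚ e, since max_T [k log T − T] =
k(log k − 1)); roots are bracketed on (1, e) and (e, ∞) and bisected to
1e−12. Both roots are returned, labeled low-T/high-T; neither is declared
"the" physical one — the formalism does not determine the order of the
transition or the physical branch.

`phase_scan` classifies the favored phase over an ascending 𝒯 grid. The
default mapping is a *common-temperature probe*: T_phys = 𝒯 with M from the
chemical dual and μ fixed at μ₀. (Applying both dual mappings would make
Ω_p − Ω_b vanish identically at C_p = C_b, leaving nothing to scan.) Under
this probe the sign changes of Ω_p − Ω_b occur exactly at the fixed-point
roots, which the scan's bisection reproduces to 1e−10; an alternative
mapping can be injected as a callable. A grid with no sign change reports
"no transition in range" rather than erroring.

## Reproducibility and problem sizes

Every stochastic component takes an explicit integer seed feeding a
dedicated `numpy.random.Generator`; no global RNG state is used, and CLI
artifacts are byte-identical across repeat runs (JSON keys sorted, floats
at 12 significant digits, no timestamps in payloads). The standard
verification runs use 10⁶ origin-fixation events for stationary-law
comparisons (TV < 0.02 against the exact law on 8-genotype landscapes, a
desk-scale size at which the whole suite completes in well under a minute)
and 10⁵ events per chain for the temperature-ratio recovery.

## Known limitations

- Monomorphic (weak-mutation) dynamics only: no segregating polymorphism,
  no Wright–Fisher diploid machinery, no clonal interference.
- The temperature-ratio statistic assumes a shared, epistasis-free
  landscape; on rugged landscapes the per-genotype ratios genuinely depend
  on q and the dispersion diagnostic will say so.
- The phenomenological model is illustrative: fitting (a, b, n) to
  comparative-genomics data is out of scope.
- Finite state spaces throughout; A^L ≤ 10⁵.
- Plug-in cumulant estimates above order 4 are biased at O(1/n), and the
  reconstruction series is truncated with only a heuristic convergence
  check.
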