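# Methods

## Model

`specdrift` treats a species family carrying a binary trait as a
two-type linear branching process on the generation time scale: species
of trait i ∈ {0, 1} speciate at rate λᵢ, go extinct at rate μᵢ, and
switch trait along a lineage at rate δᵢⱼ (anagenetic transition).
Cladogenetic transitions — trait change at a speciation event, with the
parent type surviving — enter with probabilities a₀, a₁ and modify the
jump table to

    (k+1, l): λ₀k + a₁δ₁₀l      (k, l+1): λ₁l + a₀δ₀₁k
    (k−1, l): μ₀k               (k, l−1): μ₁l
    (k−1, l+1): (1−a₀)δ₀₁k      (k+1, l−1): (1−a₁)δ₁₀l

In all deterministic mean dynamics the cladogenetic probabilities fold
into effective net diversification rates d̃ᵢ = dᵢ + aᵢδᵢⱼ, which is how
`mean_matrix`, `growth_eigenvalues` and `lln_ode` consume them; the raw
jump table is used only by the exact simulator.

The evolutionary-time limit takes n generations per time unit with
dᵢ ≈ βᵢ/n, δ ≈ ρ/n and τᵢ fixed, yielding the coupled
frequency/richness diffusion documented in the README and implemented in
`diffusion`. Diversity dependence multiplies βᵢ by a logistic factor
(1 − R/c) (common capacity) or (1 − R/cᵢ) (trait-specific).

Key assumptions worth keeping in mind:

- rates are linear in the counts (no interaction beyond the capacity
  factor on net diversification; Lotka–Volterra-type cross-capacities
  are not implemented);
- turnover stays order one on the evolutionary scale while net
  diversification and transitions are O(1/n) — trait change is *not*
  assumed rare relative to speciation/extinction on the generation
  scale;
- the trait is binary and the family is well mixed (no spatial or
  phylogenetic structure; no genealogy is recorded).

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| λᵢ, μᵢ | speciation/extinction rate per lineage | per generation-time unit | — |
| δ₀₁, δ₁₀ | anagenetic transition rate per lineage | per generation-time unit | — |
| a₀, a₁ | cladogenetic transition probability | — | 0 |
| βᵢ | macroevolutionary net diversification | per evolutionary time unit | — |
| τᵢ | turnover (offspring variance proxy) | per evolutionary time unit | — |
| ρ₀₁, ρ₁₀ | macroevolutionary transition rate | per evolutionary time unit | 0 |
| c, c₀, c₁ | carrying capacity on richness | scaled species count | unset |
| n | generations per evolutionary time unit | — | 1 |
| θ | trait injection rate (spectrum only) | per time step | — |

Validation is eager: containers reject invalid values at construction
with the offending field named. `micro_from_macro` refuses parameter
sets whose implied λ or μ would be negative; the *simulator*, whose
diversity-dependent rates can transiently push λ below zero when
richness far exceeds capacity, instead clamps λ at 0 and adds the
deficit to μ — this preserves the net rate d exactly and keeps turnover
≥ |d|, and every clamp is counted on the returned path (`n_clamped`).

## Numerical scheme

**Jump chain.** The simulator is the exact exponential-clock algorithm;
rates are constant between events (they depend only on the current
state), so no discretization error is introduced, including under
diversity dependence where the six rates are recomputed from the current
scaled richness before every event.

**Diffusions.** Euler–Maruyama with a uniform step, default
dt = 10⁻³ evolutionary time units. Square-root arguments are floored at
0, the frequency is clipped to [0, 1] after each step and the richness
floored at 0. The two driving noises are built per step from two
independent standard normals via the mixing weights

    dB⁺ = √(τ₀P/(τ₀P+τ₁(1−P))) dB⁰ + √(τ₁(1−P)/(τ₀P+τ₁(1−P))) dB¹
    dB⁻ = √(τ₀(1−P)/(τ₀(1−P)+τ₁P)) dB⁰ − √(τ₁P/(τ₀(1−P)+τ₁P)) dB¹

which realizes the per-step covariance of (ΔP, ΔR) exactly in law: both
increments have unit variance and correlation
(τ₀−τ₁)√(P(1−P)) / √(ψ(P)ψ(1−P)), so ⟨P,R⟩ accumulates at rate
(τ₀−τ₁)P(1−P), and the noises are independent when τ₀ = τ₁.

**Absorption thresholds.** Trait fixation is declared when P leaves
[p_tol, 1−p_tol] with p_tol = 10⁻⁶ (only when the boundaries are truly
absorbing, i.e. ρ₀₁ = ρ₁₀ = 0); richness extinction when R falls below
r_tol = 10⁻⁴·max(1, r₀). An Euler step that overshoots a boundary is
treated as absorption there. Fixation estimates are insensitive to
halving these thresholds at the default dt. When a trait boundary and
the extinction threshold are crossed within the same step, trait
absorption wins the tie (the event is accepted); at dt = 10⁻³ such ties
are vanishingly rare and the choice does not move any estimate beyond
Monte-Carlo noise.

**Conditioning on nonextinction.** The conditioned process has no
closed-form Doob h-transform for the logistic richness diffusion, so
`simulate_conditioned` uses rejection: paths whose richness hits the
extinction threshold before trait absorption are discarded and counted.
This is an approximation to exact conditioning over an infinite horizon;
its adequacy is checked empirically by agreement of the fixation
fraction with the closed form q(x) (it does, within 3 standard errors at
2.5×10⁴ paths). A floor (default 10⁻³) on the acceptance rate aborts
runs whose estimates would be dominated by rejections. Paths neither
absorbed nor extinct by the horizon are excluded and reported
separately (`n_unresolved`); the default horizons (400 time units, or
40·c with a common capacity) make this a null event in practice.

**ODEs.** `scipy.integrate.solve_ivp` with DOP853, rtol 10⁻⁸,
atol 10⁻¹⁰. Equilibria of the large-capacity frequency equation are
taken as the root of the stationarity quadratic in [0, 1]; with both
transition rates positive that root is unique and interior, and without
transitions the stable fixation state is selected by the sign of
β₀ − β₁ (linear stability of the logistic-type frequency equation).

**Quadrature.** Adaptive (`scipy.integrate.quad`) with absolute
tolerance 10⁻¹⁰. Spectrum integrals require f(0) = 0 so the 1/y
endpoint singularity is integrable; the Green's-function and simplified
forms of the weighted absorption functional agree to 10⁻⁸ on the tested
grid.

**Seeding.** No global RNG state. The branching ensemble helpers spawn
one `SeedSequence` child per replicate, so ensembles are reproducible
and individual replicates re-derivable. The vectorized diffusion batch
engines draw from a single seeded PCG64 stream across the active lane
set; reproducibility holds at the level of (seed, n_paths, dt).

## Effective population size

The effective-size process N = R/ψ(P) is computed as a deterministic
functional of simulated (P, R) paths rather than integrated as its own
SDE system: its dynamics follow from the (P, R) system by Itô's formula,
so nothing is lost, and the (P, R) coefficients are simpler. The
closed-form check that survives trait fixation — the extinction
probability exp(−2rβ/τ₀) being invariant under rescaling richness into
effective size, (r, τ₀) → (r/τ₁, τ₀/τ₁) — is asserted exactly in the
tests; it is the resolution of the apparent paradox that an absent
trait's turnover would govern the surviving family.

## What the built-in studies do and do not show

The study conditions are fixed defaults, not tuned per run:

- fixation concordance: time-changed frequency process at
  τ₀ = 2, τ₁ = 1, x = 0.5 with ≥ 2×10⁴ accepted paths (binomial SE
  ≈ 0.0033), plus the neutral identity q(x) = x at x ∈ {0.1, 0.5, 0.9};
- logistic equivalence: symmetric logistic system with β₀ = β₁ = 1,
  common c = 10, started at capacity (r₀ = c), against the time-changed
  estimate, joint 3 SE;
- Feller extinction: β = 0.5, τ = 1, r₀ = 1 simulated to T = 20, where
  the 'extinct by T' frequency differs from the ultimate probability
  e⁻¹ by ≈ 2×10⁻⁵, far below the Monte-Carlo resolution at 10⁴ paths;
- law of large numbers: 10⁴ replicates over t ∈ [0.1, 1] for an
  anagenetic and a cladogenetic parameter set;
- covariation: 10⁴ general-variant paths to T = 1 at τ₀ = 3, τ₁ = 1;
- large-capacity limit: 100 logistic paths per c ∈ {10², 10³, 10⁴}
  against the deterministic system over T = 5.

These demonstrate internal consistency of the simulators with the limit
theory and closed forms. They do **not** validate the model against real
phylogenies: there is no inference machinery, no tree topology, and the
generator produces idealized constant-rate (or logistic-rate) histories
without environmental covariates, rate heterogeneity within traits, or
sampling fraction effects — all of which dominate real diversification
data. Passing tests show the mathematics is implemented faithfully, not
that a given clade obeys it.

## Known limitations

- Euler–Maruyama is weak order 1; near-boundary behaviour of
  square-root diffusions is handled by clipping rather than a
  boundary-preserving scheme, so very coarse steps (dt ≫ 10⁻³ at
  turnover O(1)) will bias absorption statistics.
- Rejection conditioning is horizon-limited and approximates the
  h-transform; for parameter regimes with heavy quasi-stationary tails
  (large c, small τ) runtimes grow linearly with the absorption time
  scale ~ c/ψ.
- The fixation formula applies only to the symmetric logistic case
  (β₀ = β₁, common c, no transitions); neighbouring cases
  (c₀ ≠ c₁, or β₀ ≠ β₁) can be *simulated* but no closed-form claims
  are made for them.
- The trait-specific large-capacity system is implemented with the
  constraint as it appears in the SDE display (β₀/c₀ = β₁/c₁ = α/c for
  the special diversity-independent-selection case); the alternative
  product form α₀β₀ = α₁β₁ that sometimes accompanies it is a
  notational mismatch we flag rather than resolve.
- The trait frequency spectrum is exposed only through its limiting
  intensity 2θ/(τ₀y) and integrals against it; no Poisson random field
  of co-segregating traits is simulated.
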