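# Methods

## Model

We track genotype frequencies `p` of an effectively infinite, haploid,
asexual population under replicator–mutator dynamics
`dp/dt = p(w − w̄) + M p`. Two completely linked locus classes matter: a SIM
locus whose allele `M` amplifies all of its carrier's outgoing mutation
rates by `σ > 1` whenever the carrier is stressed *and* susceptible, and one
resistance locus per distinct stress. Key structural assumptions:

- **No direct cost or benefit of `M`.** The SIM allele is selectively
  neutral in every environment; its only handle on selection is linkage to
  the resistance mutations it helps produce, and its only cost is that an
  active mutator degrades itself faster (rate `σ μ_M` during stress in
  susceptibles). This deliberately isolates second-order selection.
- **No back-mutation `m → M`.** The question is whether recurrent
  hitchhiking can offset one-way decay; with back-mutation the allele could
  trivially persist.
- **Resistance is easier to lose than to gain** (`μ_R ≫ ν_R`), and selection
  under stress dominates mutation (`s ≫ μ_M, μ_R`). The closed forms are
  derived in this regime; `ModelParameters.check_hierarchy` warns (does not
  fail) outside it, since the simulators remain exact there.
- **No recombination, no drift, no cross-resistance, no epistasis.**
  Fitness under simultaneous stresses is additive (`1 + s·#{active stresses
  resisted}`).

For a single stress the four-genotype flows are hand-coded
(`model_core.no_stress_derivative` / `stress_derivative`); for `χ` stresses
the `2^(χ+1)` genotypes are bit-encoded and the mutation matrix is built on
the single-bit-neighbor hypercube (`multistress`). The χ = 1 engine is
bit-compatible with the hand-coded flows (tested to 1e-14).

## Stress regimes and sampling

The environment alternates stress (`τ_S`) and no-stress (`τ_NS`) phases;
the SIM frequency `p_M` is sampled at the end of each no-stress phase,
immediately before the next stress. Regimes:

- **Recurrent (R):** the identical stress every cycle; standing resistance
  carries over.
- **Non-recurrent (NR):** every stress novel. Implemented by resetting the
  resistance marginal to mutation balance `ε = ν_R/(μ_R + ν_R)` before each
  stress (preserving the SIM marginal and making the loci independent) —
  the idealized limit of infinite stress diversity.
- **Finite diversity:** `χ` stresses applied cyclically, in random order
  (uniform with replacement, seeded), simultaneously (combined), in two
  pairs, or one at a time (sequential).

## Closed forms

Sampling once per cycle gives the recursion
`p_M' = p_M e^(−μ_M τ) (1+λ)/(1+p_M λ)` with hitchhiking factor
`λ = ((1−p_R)/p_R) · ν_R/(s/σ + μ_M + ν_R)`, where `p_R` is the resistance
frequency met at the onset of stress. With `Γ = (s/σ + μ_M + ν_R)/μ_R`:

- NR: `p_R = ε` gives `λ = 1/Γ` and fixed point
  `p̂ = max{0, e^(−μτ) − Γ(1−e^(−μτ))}`; positive iff
  `τ < τ_c = (1/μ_M) ln(1 + 1/Γ)`.
- R: `p_R` is the relaxation from (near) fixation over one full cycle,
  which multiplies the `Γ` term by
  `1 + ((μ_R+ν_R)/ν_R)/(e^((μ_R+ν_R)τ) − 1) ≥ 1`. We verified symbolically
  that this expression is exactly the recursion fixed point with that
  relaxed `p_R`, which pins down the convention used throughout: *the decay
  exponent is the full cycle `τ` and the relaxation window is everything
  outside the cognate stress*.
- Heuristic for `χ` stresses: the cognate stress recurs every `χτ`, so `λ`
  is computed from relaxation over `χτ − τ_S` starting at `p_R = 1`, and
  the same recursion fixed point is returned. At `χ = 1` (short pulses)
  this reduces to the R formula; for `χ → ∞` to the NR one. It ignores
  linkage between resistance loci and therefore *overestimates* the
  simulated prevalence; it is reported as an overlay, never asserted as
  tight.

Stress strength and SIM potency enter all of these only through `s/σ`
(tested as an invariance under `(s, σ) → (ks, kσ)`).

## Numerical choices

- **No-stress phases are linear** and are propagated exactly with
  `expm(M₀ · τ_NS)`; the propagator is computed once per run and reused
  across cycles. Agreement with adaptive integration is tested to 1e-10.
- **Stress phases** use `solve_ivp` (LSODA, `rtol 1e-10`, `atol 1e-12`);
  the rates span four orders of magnitude, so tight tolerances are cheap
  insurance at these dimensions (4–32 states).
- **Renormalization:** after each phase, frequencies are clipped at 0 and
  renormalized if `|Σp − 1| > 1e-12`, bounding floating-point drift over
  up to 10⁴ cycles.
- **Convergence:** sampled `p_M` (for cyclic multi-stress schedules, the
  vector of per-phase samples of a whole super-cycle) changing by less
  than 1e-9 for 3 consecutive cycles.
- **Extinction:** infinite-population frequencies never reach 0, so
  asymptotic loss is declared when `p_M < 1e-10` while declining, and
  `p̂_M` is reported as exactly 0. A geometrically declining trajectory has
  per-cycle differences below the convergence tolerance long before the
  frequency itself is that small; to keep the two stopping rules from
  colliding, convergence is not declared while samples are still strictly
  declining below 1e-6 (`decline_floor`). Without this guard a decaying
  run can be misread as a ~1e-8 "equilibrium".
- **Iteration cap:** 10⁴ cycles; hitting it flags the result
  `iteration-cap` with the last sample as `p̂_M`.
- **Initial condition** (equilibria are initial-condition independent,
  which is tested): `p_M(0) = 0.5`, every resistance locus at mutation
  balance, loci independent.

## Schedule conventions

- In `tau_sweep`, `τ` is the length of one stress/no-stress phase
  (`τ_NS = τ − τ_S`, grid points with `τ ≤ τ_S` are skipped with a
  warning); a full rotation of `χ` stresses takes `χτ`.
- In `treatment_comparison`, one pass through *all* stresses takes `τ` in
  every strategy: all four at once every `τ`; two fixed pairs
  ({1,2}, {3,4}) alternating every `τ/2`; each stress alone every `τ/4`.
  Each stress application lasts `τ_S` (default 10) followed by the
  remainder of its slot without stress, so sequential grids need
  `τ > 4 τ_S`.
- Randomized schedules draw each phase's stress uniformly with replacement
  from the `χ` available, from a seeded generator; a schedule is a pure
  function of `(seed, n_iterations, χ)`. A randomized run executes exactly
  `n_iterations` phases (default 10 000) and summarizes the mean and
  standard deviation of `p_M` over the last `n_last` samples
  (default 1 000).
- **SIM activation under combined stresses** is not determined by the
  single-stress rule alone; we activate the mutator whenever the genotype
  carries `M` and is susceptible to *at least one* currently applied
  stress, the direct generalization of "stress does not activate SIM in
  resistant individuals". Amplification applies to all of the genotype's
  outgoing rates, at every locus. The combined-treatment conclusion (no
  SIM maintenance) should be read conditional on this rule.

## Problem sizes in the shipped tests

The test suite and the reproduction script run at desk scale: 10-point `τ`
grids for the regime comparison, two `τ` values for the stress-diversity
ordering (χ = 2, 3, 4), a four-point grid for the treatment comparison, and
randomized runs of 2 000 iterations (tail of 200) at χ = 2. These sizes
already separate all the qualitative regimes; the library defaults
(20-point grids, 10⁴ iterations) match the full-scale experiments.

## What the configuration fixtures emulate

`single_stress.yaml` is the benchmark parameter set for the single-stress /
stress-diversity analyses (`s=1, σ=100, μ_M=10⁻³, μ_R=10⁻², ν_R=10⁻⁴`,
`τ_S=10`); `treatment.yaml` the four-drug comparison set
(`s=0.5, μ_R=5×10⁻³`, other rates equal) with an explicit `τ` grid spanning
the window where the strategies separate. They are idealized study
conditions, not fits to data: real populations are finite (drift can lose a
rare SIM allele permanently), resistance typically carries a cost (which
would *help* SIM maintenance by eroding standing resistance faster),
deleterious load on mutators is ignored (which would hurt it), and real
drugs differ in `s` and pharmacokinetics. Passing tests therefore validate
the model's internal logic and its closed forms, not quantitative predictions
for any particular organism.

## Known limitations

- Deterministic, infinite-population dynamics only; no genetic drift, so
  `p̂_M` below ~1/N should be read as effective loss for a population of
  size N.
- The multi-stress heuristic is a deliberate overestimate (see above).
- Cost of resistance and lethal-mutation load are out of scope.
- The sequential-treatment maintenance window for the shipped treatment
  parameter set is finite and relatively narrow (τ roughly 10³ for
  `τ_S = 10`); its exact location shifts with `τ_S`, which the model keeps
  as an explicit knob.
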