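# Methods

## Model

The package implements a deterministic model of ethological reproductive
isolation (RI) in a two-type plant community: a focal species at relative
frequency *f* ∈ (0, 1) and a pooled heterospecific class at 1 − *f*. Each
pollinator *i* carries two dimensionless behavioral indices on [−1, 1]:

- **Preference ρᵢ** rescales how visits split between the types relative to
  frequency: ψᵢ = f(1 + ρᵢ)/(1 + ρᵢ(2f − 1)). ρ = 0 gives ψ = f; ρ = ±1 give
  exclusive visitation of one type. The form is a frequency-preference
  function rescaled so that preference and constancy live on a common scale.
- **Constancy κᵢ** captures visit *order*: the tendency to follow a visit to
  one type with another visit to the same type, beyond what ψ alone predicts.
  It is defined through the observed pair (H, ψ) as
  κ = (1 − H − ψ)/(1 − H + ψ − 2ψ(1 − H)). Writing a = (1 − H)(1 − ψ) and
  b = ψH this is (a − b)/(a + b), which shows κ ∈ [−1, 1] for *any*
  (H, ψ) ∈ [0, 1]² — observational noise cannot push the estimator out of
  range, only into undefined corners (see below).

**H semantics.** H conditions on movements whose *destination* is the focal
plant: among arrivals at the focal plant, the fraction whose previous plant
was heterospecific. This is the pollen-contaminating fraction, and it is the
only conditioning under which the model's random-movement null H = 1 − f
holds; it is used consistently in the closed forms, the estimators and the
simulator.

Solving the constancy relation for H and substituting ψ(f, ρ) yields the
central closed form

    H(f, ρ, κ) = −(f − 1)(ρ − 1)(κ − 1) / [1 + ρ(2f − 1) + κ(2f − 1) + κρ]

and RI is the standard assortment index against the random-movement
expectation 1 − f:

    RI = 1 − 2H / (H + (1 − f)) ∈ [−1, 1].

Composing the two and simplifying gives
RI = f(ρ + κ)/[1 + (ρ + κ)(f − 1) + ρκ]; the test suite verifies the
simplification against the composition across the domain at 1e−10. The sign
convention is fixed by the model's own anchors: RI = 0 at ρ = κ = 0 and
RI → 1 as heterospecific movement vanishes. RI is symmetric in ρ and κ —
preference and constancy are exchangeable contributions to isolation.

**Curvature.** At κ = 0, ρ > 0, H(f) = (1 − f)(1 − ρ)/((1 − ρ) + 2ρf) is a
decreasing Möbius function with strictly *positive* second derivative: H
falls steeply while the focal plant is rare and flattens as it becomes
common. The mirrored case ρ < 0 has negative curvature (H stays near 1 until
the plant is common, then plunges). Informal descriptions of these shapes
sometimes use "concave"/"convex" for the visual bowl rather than the sign of
the second derivative; the tests pin the second-difference signs, which is
unambiguous.

**Endpoints.** ρ, κ = ±1 are admitted where the formulas have finite limits
(e.g. H = 0 at κ = 1 unless ρ = −1). The two corners (ρ, κ) = (1, −1) and
(−1, 1) make both numerator and denominator of H vanish and are genuinely
indeterminate; they raise a `DomainError`, as do f ∉ (0, 1) and indices
outside [−1, 1].

## Multi-pollinator communities

Each guild member has a community visit share φᵢ ∈ [0, 1] (Σφᵢ = 1), which
conflates abundance and per-capita visit rate. Members combine through their
shares of the *focal plant's* visits, vᵢ = φᵢψᵢ/Σⱼφⱼψⱼ, giving
H_tot = Σᵢ vᵢHᵢ and RI_tot = 1 − 2H_tot/(H_tot + (1 − f)). The sums reduce
exactly to the printed two-pollinator special case and to the one-pollinator
model for identical guilds of any size. Because vᵢ re-weights by ψᵢ,
constancy-only differences average linearly in φ while preference differences
do not: the pollinator preferring the focal plant contributes
disproportionately many of its visits. One consequence, reproduced as an
acceptance check: with ρ₁ = 0.8 and equal shares, a second pollinator at
ρ₂ = −0.8 yields *higher* total RI than ρ₂ = 0 for all f below a crossover
located at f ≈ 0.652 (scan of 10⁴ grid points plus bisection to |Δf| ≤ 10⁻⁶;
isolated crossings only — identically-zero differences are not crossings).

Preference may be frequency-dependent: anywhere a constant ρ is accepted, a
callable ρ(f) → [−1, 1] may be supplied and is evaluated at the current f
before the closed forms apply (out-of-range returns raise at evaluation).
`linear_preference(s)` ships ρ(f) = s(2f − 1) as an illustrative example
only; no claim is made that any real pollinator follows it.

"Equal pollinator frequency" in two-pollinator scenarios means φ₁ = φ₂ = 0.5.
Communities with more than two plant species are represented only as focal
vs pooled others; pollen-transfer efficiency, pollinator–pollinator
behavioral interaction and adaptive foraging are out of scope.

## Estimation from field observations

Input is a bout-structured table (`bout_id, pollinator_id, visit_index,
plant_id`, comma-delimited, headered). Validation requires visit indices
consecutive from 1 within each bout and a single pollinator per bout; all
non-focal plant ids are pooled, so relabeling heterospecific plants never
changes an estimate. Estimators:

    psi_hat = focal visits / total visits
    H_hat   = n_OF / (n_FF + n_OF)
    rho_hat = (psi_hat − f) / (f + psi_hat − 2 f psi_hat)
    kappa_hat from (H_hat, psi_hat) as above
    phi_hat_i = visits_i / total visits (all pollinators)

Transitions are counted strictly within bouts: between-bout movements are
unobserved gaps and carry no pollen information (this artifact's convention).
*f* must come from a plant census and cannot be inferred from visits, because
ψ confounds frequency with preference. Degenerate corners (no movements into
the focal plant; ψ̂ = 1 with Ĥ = 0) return NaN with a False validity flag
rather than fabricated values; an optional `correction` argument adds a
pseudo-count (e.g. 0.5) to each transition cell and is off by default so that
degenerate data stay visible. Estimates flagged invalid are excluded (with a
warning, and share renormalization) when projecting RI curves.

## Foraging simulator

The deterministic model fixes only (ψ, H) per pollinator; the minimal
stochastic visit process consistent with both is a two-state Markov chain
over {focal, other} with

    p_FF = 1 − H        p_OF = H ψ / (1 − ψ),

forced by stationarity of (ψ, 1 − ψ) (ψ·p_FF + (1 − ψ)·p_OF = ψ) and by the
arrival-origin condition (1 − ψ)p_OF/ψ = H. Not every behavior pair is
realizable: strongly opposed preference and constancy can demand p_OF > 1
(e.g. ρ = 0.8, κ = −0.8 at f = 0.75), in which case construction raises a
`DomainError` — simulation-based checks iterate over the feasible set.

Bouts initialize from the stationary distribution so expected tallies match
the closed forms without burn-in; `expected_tally` returns those noise-free
real-valued counts, and feeding them to the estimators reproduces (ρ, κ)
exactly. Seeding is explicit (no clock seeding): one root seed, per-pollinator
streams derived via `numpy.random.SeedSequence(seed).spawn(...)` by guild
index, so adding a pollinator never perturbs the other pollinators'
sequences. The community bout budget `n_bouts` is allocated ∝ φᵢ with a
minimum of one bout each.

### What the synthetic data does and does not emulate

The generator reproduces the bout structure, visit proportions and
first-order transition statistics implied by (f, ρ, κ, φ) — exactly the
quantities the estimators consume. It does not emulate spatial foraging
structure, reward depletion, bout-length heterogeneity, observer effects, or
higher-order sequence dependence. Tests passing on synthetic data therefore
demonstrate internal consistency of model, estimators and simulator at
realistic sampling noise — not that any real pollinator follows a two-state
chain.

## Numerical choices and problem sizes

- Identity and symmetry checks at 1e−10 (relative) / 1e−12 tolerances;
  vanishing denominators raise rather than return infinities.
- Frequency sweeps default to 201 points on (0.005, 0.995), an open-interval
  guard; visit-share sweeps use 201 points on the closed [0, 1].
- Crossover detection: 10⁴-point uniform scan, Brent bisection to 1e−6,
  multiple crossings reported ascending.
- Monte-Carlo oracle checks run 10⁵ transitions per parameter combination
  (1000 bouts × 101 visits) against a 3-binomial-SE band; estimator
  round-trip checks use 10⁴ transitions. At 10⁴ transitions the sampling SD
  of κ̂ at strong-avoidance corners (ρ = −0.8, where only ~ψ·10⁴ transitions
  reach the focal plant and |∂κ/∂H| is large) reaches 0.05–0.2, so κ̂ there
  is accurate only to that order; the noise-free expected-tally round trip is
  exact, and errors shrink as n^(−1/2) (tested).

## Known limitations

Preference and constancy are assumed constant over the observation window
(unless a frequency-dependent hook is supplied); plant and pollinator
populations are assumed well mixed at the same spatial scale; every visit is
treated as an equally effective pollen-transfer opportunity. Estimates from
small observation tables are noisy and should be projected with their
validity flags and sample sizes in view.
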