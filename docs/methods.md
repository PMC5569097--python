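# Methods

## Model

The simulator is a probabilistic cellular automaton on a rectangular
lattice `S ⊂ Z²` with extents `S1` (vertical, periodic) × `S2`
(horizontal, reflecting).  Site state is the pair `(η, μ)`: `η ∈ {0, 1, 2}`
encodes empty / amoeboid cell (A) / mesenchymal cell (M), and `μ ∈ [0, 1]`
is the ECM resistance, a lumped scalar for matrix density, stiffness and
inverse porosity.  Cells are conserved (no division or death) and at most
one cell occupies a site.

One elementary time step draws a cell uniformly at random (with
replacement) and applies, in order:

- **R1, phenotypic switch** (switching populations only): A→M with
  probability `α·μ`, M→A with probability `β·(1−μ)`, using the resistance
  at the cell's current site.
- **R2, degradation**: if the cell is (now) M, the site resistance decays
  multiplicatively, `μ → (1−δ)·μ`, so degradation is partial but never
  complete.  A subtractive variant `max(0, μ−δ)` is available behind the
  same interface for sensitivity checks.
- **R3, migration**: with probability `λ_X(μ) = c_X / (1 + exp(15(μ−0.5)))`
  the cell draws a target from the von Neumann neighbourhood with weights
  `exp(κ·S2·ΔG)`, where `G(r1, r2) = r2/S2` is the static chemoattractant
  and `ΔG` the per-step gradient increment — i.e. right `∝ e^κ`, left
  `∝ e^{−κ}`, transverse `∝ 1`.  The move executes only if the target is
  on-lattice (after periodic wrap in `r1`) and empty; otherwise it is
  aborted (exclusion process).  The sigmoid's midpoint 0.5 and slope 15
  give near-free movement in open matrix, a steep drop at moderate
  resistance, and near-arrest in dense matrix.

`n` consecutive elementary steps (`n` = population size) constitute one
Monte Carlo step (MCS), the model's time unit; every cell is updated once
per MCS in expectation.

Because all rate constants lie in `[0, 1]`, rates are interpreted directly
as per-attempt probabilities.  R3 reads `μ` *after* R2's degradation in the
same update; the alternative (pre-degradation `μ`) differs only by one
factor `(1−δ)` in the occasional update and was not found to matter, but
the chosen order is fixed and documented here for reproducibility.

Two deliberate strategy switches exist on `ModelParams`:

- `bias="linear"` replaces the exponential direction weights by
  `(max(0, 1−κ), 1+κ, 1, 1)`; the exponential default is monotone in `κ`,
  reduces exactly to the uniform walk at `κ = 0` and keeps `κ`
  dimensionless (the `S2` in the exponent cancels `ΔG = ±1/S2`).
- `switch_update="equilibrium"` resamples the phenotype each update from
  the local stationary law `P(M) = αμ / (αμ + β(1−μ))` instead of applying
  kinetic flips.  This is the fast-switching limit, in which population
  behaviour depends on `(α, β)` through the ratio `α/β` *exactly*.  Under
  the default kinetic update the dependence on the absolute rate scale is
  weak but real: faster switching tracks the local environment more
  tightly and yields measurably larger `d_p` in structured ECM (≈20%
  between `(α,β) = (0.2, 0.2)` and `(1, 1)` at `θ = 0.5`).  The kinetic
  update is the default because it is the literal reading of the rule
  definitions; the equilibrium variant documents — and makes testable —
  the idealisation under which ratio sufficiency is exact.

## Environment generators

Homogeneous ECM is a constant field `μ ≡ level`.  Heterogeneous ECM is

    μ(r1, r2) = 1 − θ/2 + (θ/2)·sin(2πr1/25 + 3π/2)·sin(πr2/25 + π/2)
                − (1−θ)·ξ(r1, r2),

with `ξ` i.i.d. uniform(0, 1) per site, drawn once from the seeded stream
and frozen.  A single shared `ξ` would make the `θ = 0` field spatially
constant rather than "completely random", so the per-site reading is used.
The expression is analytically confined to `[0, 1]` (extremes at sinusoid
`±1` with `ξ ∈ {0, 1}`), so no clipping is applied; an assertion guards
the bound.  On lattices spanning whole periods (the default 100×300 spans
4 and 6 periods) the spatial mean is 0.5 for every `θ`, so scenarios
differ in matrix *organisation*, not average load.  The sinusoid periods
(25 in `r1`, 50 in `r2`) are exposed as advanced arguments for robustness
checks with other functional forms but default to the standard field.

The chemotactic gradient is functional (`G = r2/S2`), static, and
independent of the ECM; haptotaxis and durotaxis are out of scope.

## Parameters

| symbol | meaning | range | default |
|---|---|---|---|
| `α` | A→M switch rate per unit time | 0–1 | scanned |
| `β` | M→A switch rate per unit time | 0–1 | scanned |
| `c_A` | A migration rate constant | — | 1 |
| `c_M` | M migration rate constant | 0–1 | `c_A`·`c_ratio` |
| `δ` | ECM degradation rate | 0–1 | 0.1 |
| `κ` | chemotactic responsiveness | ≥0 | 1 |
| `γ` | M fraction of a non-switching population | 0–1 | scanned |
| `θ` | ECM heterogeneity | 0–1 | 0.5 |
| lattice | `S1 × S2` | — | 100 × 300 |
| population | `n` | ≤ `S1` | 50 |
| duration | MCS | — | 200 |

`S2 = 300` exceeds the maximum possible 200-MCS displacement, so the
reflecting right boundary is never reached; `S1 = 100` holds the 50-cell
seeding column (the cooperativity experiment enlarges `S1` to the
population size).  Switch-ratio grids realize `α/β = r` as `(α, β) =
(r, 1)` for `r ≤ 1` and `(1, 1/r)` otherwise, keeping both constants in
range.  Non-switching compositions use round-half-up for the M count, so
`γ ∈ {0, 0.3, 0.7, 1}` with `n = 50` gives exactly 0/15/35/50 M-cells.

## Initial conditions and seeding

Cells start on distinct random rows of the left column `r2 = 1`; switching
populations start half M (configurable via `initial_m_fraction`; the
outcome is insensitive to the split), non-switching populations with
`round(γ·n)` M-cells.  Replicate `r` of any arm uses one
`numpy.random.Generator` seeded `base_seed + r`, from which *all* draws
come in a documented order: noise field, placement rows, phenotype
assignment, then per MCS a block of `n` cell indices followed by a `3×n`
uniform block (switch, migration, direction rows).  Arms therefore share
common random numbers at matched replicate indices, and every experiment
is a pure function of its spec.  Sub-simulations inside one cooperativity
repeat are seeded with the pair `(base_seed + r, j)`.

## Observables

Per cell, the displacement `d` from the initial position; default metric
is Euclidean with minimal-image convention on the periodic axis, with the
axial projection `|r2 − r2_init|` always reported alongside (the two give
the same qualitative orderings; the axial reading is natural when the
analysis device is the vertically averaged density profile).  Per
population, mean `d_p`, maximum `d_max`, and the within-run sd over cells.
Across replicates, mean, sd and coefficient of variation of `d_p`
(between-simulation variability; the within-run spread is reported
separately and is much larger).  `Δd_p` is the best switching arm minus
the best non-switching arm in replicate-mean `d_p`, each maximised over
its own grid; its standard error combines the two best settings' standard
errors in quadrature.

## Experiments and problem sizes

Scenario scans use the full ratio grid `{0.1, …, 0.9, 1, 2, …, 10}` and
`γ ∈ {0, 0.3, 0.7, 1}` with 50 replicates; the critical-resistance scan
uses homogeneous levels 0.1–0.9 with 20 replicates per arm and reports the
midpoint of the adjacent levels where the pure-A/pure-M ranking flips (or
an explicit "no crossover").  The phase diagram evaluates `Δd_p` per
`(θ, c_M/c_A)` grid point with 20 replicates by default.  The
κ-sensitivity recipe reports `Δd_p` per κ plus a Spearman trend statistic;
the packaged test uses a reduced ratio grid `{0.2, 0.5, 1, 2, 5}`,
`γ ∈ {0, 1}` and 20 replicates, which resolves the trend cleanly.  The
cooperativity experiment compares four arms — switching population, best
of `n` solitary switching cells, non-switching population (γ = 0.5,
matching the switching arm's initial composition; the composition of the
solitary non-switching arm mirrors γ), best of `n` solitary non-switching
cells — over `repeats` repeats; the packaged test runs `n = 100` with 30
repeats, which preserves the orderings observed at the full `n = 500`.

## Verification

Beyond unit and property tests (field bounds on 10⁴ random draws,
exclusion/conservation invariants under hypothesis-driven settings,
forced-draw boundary tests, bit-exact reproducibility), the automaton is
cross-checked against an independently enumerated Markov chain: for one
cell on a small homogeneous lattice the exact one-update transition matrix
over (position, phenotype) is built directly from the rule definitions,
and empirical distributions from 10⁵ (unbiased) and 3×10⁴ (biased,
switching) replicates must agree within 3σ binomial error, resp. pass a
chi-square goodness-of-fit test.

## Known limitations

- No proliferation, death, adhesion, intermediate phenotypes, cell-shape
  mechanics or intracellular signalling; the phenotype is a binary label
  coupling only to speed and degradation.
- The gradient is static and ECM-independent; degradation is strictly
  local and irreversible (no matrix deposition or remodelling).
- The synthetic ECM emulates structured-plus-noisy resistance landscapes,
  not imaged matrix; conclusions about real tissue rest on the claim that
  only the broad organisation (structured versus random, mean 0.5)
  matters, which the generator's pluggable functional form lets one probe.
- Ratio sufficiency (`d_p` depending on `(α, β)` only through `α/β`) holds
  exactly only in the fast-switching limit (see `switch_update` above);
  with kinetic switching the absolute rate scale has a modest effect.
- The cooperativity advantage of a *non-switching* population over its
  solitary cells is consistently positive in the mean but small relative
  to repeat-to-repeat noise at feasible repeat counts; the corresponding
  rank-test assertion is the one check in the suite that does not reach
  significance.
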