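# Methods

## Model and assumptions

The trunk model rests on four assumptions:

1. **Discrete modular growth.** The tree develops in growth cycles; each
   terminal bud adds one module of constant length per cycle and forms on
   average `μ > 1` new tips. Height in "module units" `h` and physical height
   `z` are related through the module length `height / n`, with
   `n = round(age_years × cycles_per_year)` (ties rounded half up — cycles
   are discrete).
2. **Age-dependent carrying capacity.** Any branch of age `a` cycles — the
   whole tree included — holds at most `K(a) = α (a+1)^d` tips; overshoot is
   resolved by discarding whole sub-branches, simultaneously at every level
   of the hierarchy. Expected tips: `b(a) = min{μ^a, K(a)}`, `b(0) = min{1, α}`;
   expected modules at distance `l`: `g(l, n) = b(n)/b(n−l)` for `1 ≤ l ≤ n`
   (zero otherwise). The upper end `g(n, n) = b(n)/b(0)` counts the tips
   themselves, so the live-leaf sum below is well defined at its upper limit.
3. **Leaves and pipes.** Each surviving module carries one leaf unit for
   `l_g` cycles; each leaf unit is connected to the base by a pipe of fixed
   area, `c_S` while the leaf lives (sapwood) and `c_H` once it has died
   (heartwood; pipes are not reused). Any constant number of leaves per
   module is absorbed into `c_S`/`c_H`.
4. **Trunk partition.** A fraction `κ ∈ (0, 1]` of the pipes continues on the
   trunk at each ramification, and the expected number of ramifications below
   height `h` is `log₂ g(h, n)`; the trunk share of pipes at `h` is
   `κ^{log₂ g(h,n)}`.

### Leaf bookkeeping and the dead-leaf census

The live-leaf count above `h` is `F_S(h,n) = Σ_{l=max(h, n−l_g)}^n g(l,n)`.
For the dead-leaf count the package uses the per-distance form

    F_H(h, n) = Σ_{l ≥ max(h,1)} [ g(l, l) − g(l, n)·1{n−l ≤ l_g} ],

which is the cycle-by-cycle bookkeeping (thinning losses
`g(l, m−1) − g(l, m)` while the cohort's leaves are alive, i.e.
`l ≥ m−1−l_g`, plus the age-out of the remaining `g(l, m)` at cycle
`m = l + l_g + 1`) telescoped per distance. The boundary convention is that
the age-out term counts whenever the cohort's distance is **at or above**
`h`, matching the at-or-above semantics of `F_S`; with this convention
`F_S(h,n) + F_H(h,n)` equals the number of leaves ever formed at distance
`≥ h` exactly, for every `h` — a conservation law the test suite checks both
against the closed forms and against the simulator. (Excluding the cohort at
distance exactly `h` from the age-out term would break this conservation at
`h ≥ 1`; the agent-based oracle confirms the inclusive convention.)

Degenerate conventions: `g(0, ·) = 0` (the base carries no module; the model
is anyway used from breast height upward); heights are mapped to the nearest
integer cycle index, without interpolation, because all sums run over integer
cycles and measured profiles are sparse relative to `n`; a height index above
the tree top yields a warning and a zero count rather than an error, so dense
grids can be evaluated safely.

### Validity domain of the closed forms

`b(a) = min{μ^a, K(a)}` presumes the capacity stays reachable once growth
first overshoots it, i.e. `μ·b(a−1) ≥ K(a)` at every capacity-bound cycle and
`α ≥ 1`. `mean_field_consistent()` checks this; outside the regime (slow
branching against a steep capacity) the growth process cannot refill the
capacity and the closed forms overestimate the process. All sums are
accumulated in double precision; "exact" comparisons in the tests use 1e-9
relative tolerance.

## Agent-based simulator

The simulator grows an explicit module graph (ids, parents, distances, leaf
states) and is both the independent oracle for the closed forms and a
debugging tool. Two modes:

* **Deterministic = exact expectation propagation.** Every module carries a
  real-valued weight (its expected multiplicity). Tips spawn `ceil(μ)`
  children whose weights sum to `μ` times the parent's; capacity enforcement
  walks branch ages youngest-to-oldest (the whole tree last) and, where a
  branch class exceeds `K(a)`, scales its subtree weights proportionally —
  the expectation of discarding sub-branches uniformly at random. This
  forward process never evaluates `b`, `g`, `F_S` or `F_H`, yet reproduces
  them to round-off in the consistent regime, which is the package's central
  oracle-equivalence suite. Proportional scaling is the reason a
  *deterministic* oracle can realise fractional expected counts such as
  `g(1,3) = 4/3`; an integer tree cannot.
* **Stochastic = one integer realisation.** Spawning is `floor(μ)` plus a
  `Bernoulli(μ − floor(μ))` extra per tip. The integer capacity is the
  stochastic rounding `floor(K) + Bernoulli(frac(K))`, so enforcement is
  unbiased with respect to `K`. Excess tips are removed by random-descent
  discards: a child is chosen with probability proportional to its live tip
  count; it is discarded whole if its tips fit in the excess, otherwise the
  descent recurses into it. Whole sub-branches die (the mechanism that
  creates heartwood in the crown interior) while the realised count lands
  exactly on the integer capacity, with no overshoot.

Leaf conventions shared by both modes: a module discarded in the cycle it
formed never developed (excluded from the ever-formed census, matching the
bookkeeping above in which only `b(m)` modules appear at cycle `m`); a leaf
is exposed to thinning through cycle `birth + l_g + 1` and ages out at the
end of that cycle; age deaths are recorded at cycle `birth + l_g` with cause
`age`, thinning deaths at the cycle of discard.

**Stochastic mode versus the closed forms.** Any integer realisation of
"grow, then discard down to capacity" has mean `E[min(S, K)] = K − E[(K−S)⁺]`
at a binding branch, i.e. it sits systematically *below* the mean-field
`b(n)` once the capacity binds — a property of the process, not of the
implementation (measured at roughly −1 % to −3 % of `b(10)` for moderately
bound parameters; `scripts/acceptance.py` reports this as
`meanfield_bias_capacity_bound_pct`). The statistical agreement test
therefore draws its parameters from the regime where `b(n)` *is* the exact
process mean — capacity an order of magnitude out of reach through `n = 10`,
where the tip count is a martingale with mean `μⁿ`. The test retains full
power there: any spurious thinning or biased spawning shifts the mean.

The trunk path is designated after growth as the chain of surviving modules
from the base (first child in deterministic mode, uniform random in
stochastic mode); a junction with at least two surviving branches counts as
one ramification. In the unconstrained `μ = 2` regime the realised
ramification count below `h` equals `h = log₂ g(h, n)` exactly, which the
suite checks in both modes.

## Synthetic data generator

`synthesize_profile` evaluates the closed-form trunk profile on an even grid
from breast height to 95 % of tree height and applies independent
multiplicative `lognormal(0, σ)` noise per area. The reference study
conditions used throughout the tests and the acceptance script emulate a
maritime-pine-like conifer:

| quantity | value | rationale |
|---|---|---|
| age, height | 25 y, 20 m (prediction tree: 20 y, 17 m) | mature but not old stand |
| cycles per year | 2 | two flushes per year, as in maritime pine |
| `l_g` | 5 cycles | needles retained ≈ 2.5 years |
| `α, d` | 2.0, 1.6 | capacity bound by `n = 50`; `d` in the light-competition range 1–3 |
| `μ` | 1.8 | within the biologically plausible (1, 4] |
| `κ` | 0.85 | most pipes stay on the trunk at a ramification |
| `c_S, c_H` | 0.6, 0.45 cm²/pipe | sapwood area per pipe above heartwood's, as observed in conifers |
| grid, noise | 12 heights, σ = 0.05 | sparse stem-analysis profile with ~5 % area error |

What the generator does *not* emulate: butt swell below breast height (the
model's stated exclusion), within-tree parameter drift during ontogeny,
height-dependent Huber values (reusable pipes), measurement heights chosen
adaptively, or correlated digitisation error. Passing the recovery tests
therefore shows the estimation machinery is sound and identifiable under the
model's own assumptions plus multiplicative noise — not that the model
captures every feature of real stem-analysis data.

## Calibration

The objective is the literal unweighted least-squares error
`Σ_h (S − S*)² + (H − H*)²` over measurement heights from breast height
upward, after `c_S` and `c_H` are rescaled, inside every evaluation, at the
*first* usable height (`c = measured area / modelled pipe count`; a zero
predicted pipe count degrades gracefully to a zero compartment with a
warning). Only `(α, d, μ, κ)` are searched.

The optimiser is a generalised pattern search on a unit-cube rescaling of
the bounds — `α ∈ [1, 10⁵]` on a log10 scale (it spans orders of magnitude),
`d ∈ [0.5, 3.5]`, `μ ∈ (1, 4]`, `κ ∈ (0, 1]` linear. Complete polling of the
2k axis neighbours, mesh expansion ×2 on success (capped at 0.5), contraction
×0.5 on failure, termination at mesh 1e-6 or 400 iterations, best of the
default start `(10, 1.5, 2.0, 0.8)` plus 5 seeded random restarts
(multimodality hedge). Iterate values are non-increasing by construction and
the whole fit is bit-reproducible given the seed. A fit takes a couple of
seconds on one CPU.

Prediction for a conspecific tree re-derives `n` and the module length from
the new tree's age and height and carries **all** calibrated parameters —
including `c_S` and `c_H` — unchanged: prediction uses no measurement of the
target tree. Goodness of fit is reported as the standard coefficient of
determination `R² = 1 − SS_res/SS_tot` about the observed mean, and as RMSD
normalised by the observed range (NRMSD); both are undefined (reported as
n/a) when the observed series is constant, as for a heartwood-free tree.

The simple-pipe-model baseline models the trunk as sapwood pipes only:
`c · F_S(h, n)` with the single constant matched to the measured *total* area
at the first height. Because it ignores both heartwood dynamics and the
`κ`-attenuation, it systematically overestimates the area near the crown —
the comparison the baseline study quantifies.

## Problem sizes and design choices

The verification suite runs the oracle equivalence at `n ≤ 12` (8 190-node
graphs), conservation on 200 random trees in both modes at `n ≤ 10`,
stochastic agreement with 20 draws × 500 replicates, and the calibration
studies on 12-height profiles with 20 noise seeds — sizes at which every
check completes in seconds to a couple of minutes on a single CPU while the
statistical tests retain their intended power.

Other choices made where the design was open: non-integer `μ` is allowed in
the deterministic mode (children of equal fractional weight), since
expectation propagation does not require integer offspring; profile files
are plain CSV with `#` comments and pass-through units (the model is
unit-covariant through `c_S`/`c_H`); breast height defaults to 1.3 length
units and is configurable; configs are JSON with YAML accepted; every output
file embeds the parameters, seed and package version needed to regenerate
it.

## Known limitations

* Everything below breast height (butt swell, root structure) is out of the
  model's validity domain and rejected.
* The closed forms are mean-field: exact for the expectation-propagating
  process, a few percent above any integer realisation's mean in the
  capacity-bound regime (see above).
* Parameters are species- and location-constants; no dependence on stand
  density, crown ratio or other environmental drivers, and no reusable
  pipes (the sapwood pipe's life equals the leaf's, so fitted `c_S` tends to
  exceed `c_H` to compensate).
* Parameter recovery is not guaranteed unique — different `(α, d, μ, κ)` can
  fit one profile comparably well; fit quality, not parameter identity, is
  the calibration contract, and cross-tree prediction quality is checked
  separately.
* No uncertainty quantification on fitted parameters.
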