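# Methods

`stemdish` simulates a two-dimensional dish of cells whose collective
behaviour — producing the right proportions of specialized cells, arranging
them into a prescribed spatial pattern, and holding both the numbers and the
pattern at homeostasis — emerges from three coupled layers: multistable
regulatory switches inside each cell, diffusing signal fields on the
lattice, and an adaptive death rate. This note records the model, its
assumptions, the places where the design was genuinely open, and what the
scaled-down computations in the test suite do and do not establish.

## Lattice and reaction system

The dish is a disc of radius `R` meshes cut out of a `(2R+1)²` square grid;
a mesh holds at most one cell (stem `S`, progenitor `P`, or terminally
differentiated `A`/`B`), two integer determinant counts for the occupant's
internal switch, and integer molecule counts of four signal species
(territorial `S1`, `S2`, the leading signal `S_l`, and its Turing partner
`S_a`). Connectivity is 4-neighbour; the wall reflects (molecules never
leave, cells are never placed outside). Time evolution is an exact Gillespie
direct-method simulation over ~29 per-mesh reaction families: determinant
synthesis/degradation, cell division, reversible `S↔P` transitions,
movement, `A`/`B` death, and production/degradation/diffusion of all signal
species. The engine keeps one Fenwick-tree-backed weight table per reaction
family so that sampling a mesh and updating a weight are `O(log N)`; weight
tables are rebuilt from scratch every few million events to cancel
floating-point drift. Runs are exactly reproducible under a fixed seed.

Diffusion follows the rate table's convention: a constant propensity `D/h²`
per occupied mesh per in-dish neighbour direction, moving one molecule to a
uniformly chosen neighbour (zero propensity at zero count, so counts stay
non-negative and diffusion-only dynamics conserve molecules exactly). The
usual mass-action form `(D/h²)·count` is available via
`SimConfig.diffusion_kinetics="mass_action"` and is used where a check is
anchored to the PDE discretization; the constant-rate default is what the
printed propensity table specifies and is the only variant whose event
volume permits the stated dish sizes.

## Internal switches and fate decisions

Stem cells carry a bistable mutual-repression switch for determinants
`(X_s, Y_s)` (Hill coefficient 4, half-saturation 45, degradation 1;
synthesis 85/100). Progenitors carry a tristable switch with Hill
self-activation plus mutual repression (`α = ι = 30`, `β = 47.5`,
`γ = 0.38`); its three attractors correspond to the `P`, `A` and `B` fates.
At division the mother's determinants split binomially (`X₁ ~ B(#X, ½)`)
between the two offspring, one of which occupies the mother's mesh and the
other a uniformly chosen empty neighbouring mesh (a firing without an empty
neighbour is a no-op); each offspring's type is the basin of attraction its
counts land in. `A`/`B` offspring carry no determinants; a progenitor born
from a stem division or transition re-draws its determinants uniformly from
the middle (progenitor) basin restricted to the dynamically reachable box
(`x ≤ Σ synthesis/γ`) — points beyond that bound are unreachable by the
dynamics and sampling them would let binomial noise dominate the fate
decision.

Two feedbacks deform the decision boundaries, and classification must see
them because they are the patterning and homeostasis mechanisms:

* the progenitor switch's self-activations are boosted by the
  signalling-effect coefficients `ε₁/ε₂` derived from the local signal
  counts, so in high-`S_l` territory the `A` basin swallows most of the
  plane (measured: 91% of the plane at `ε = (30, 0)` versus 16% at
  `ε = 0`) — this is what converts a signal pattern into a cell pattern;
* the stem switch's `X_s` synthesis rate falls with total density `n`
  (`ι(n) = 2·85·n_ref⁴/(n_ref⁴ + n⁴)`), so self-renewal shuts off as the
  dish fills.

Since basins cannot be recomputed per event, the engine precomputes families
of fate-labelled basin maps on a quantized grid — 7×7 levels of
`(ε₁, ε₂) ∈ [0, 2a]²` and 9 levels of `ι` — at resolution 2 over
`[0, 340]²` (vectorized RK4 integration of every lattice point, ~20 e-folds
of the relaxation time; unresolved points filled from the nearest resolved
neighbour with ties to the progenitor label). A shifted map's stable states
are fate-labelled by looking their coordinates up in the unshifted reference
map, which tracks attractor identity continuously as basins merge or
vanish. Each division classifies against the map nearest to the mother
mesh's current coefficients.

### Signalling-effect coefficients

`ε_i = f_i(S_l) + g(S_i)` with `g(s) = a·s/b` saturating at `a` for
`s ≥ b` (defaults `a = 30`, `b = 100`: the leading signal can at most double
the self-activation). `f` is a Hill switch of exponent 12 normalized to
half-max at `sl_max/2` — the same half-maximum threshold that defines the
`A` territory in the scoring template and the abundance targets — and is
gated off wherever the cell's own territorial signal is already present
(`S_i > 0`), so the leading signal only acts where territory is not yet
established. `f₁` responds to `S_l` and `f₂` to its complement
`sl_max − S_l`, giving the two specialized fates opposite spatial biases;
with no leading-signal scenario at all both `f` terms vanish. For
Turing-generated fields `sl_max` is the clip ceiling `s_upper`.

## Signals

`S1`/`S2` are secreted by `A`/`B` cells at `220·β⁴/(β⁴ + s_other⁴)`
(`β = 2`), decay at `0.5` and diffuse at `110`; mutual repression of
production plus the `g` term in `ε` lets specialized cells defend their
territory. The leading signal has three scenarios: a fixed static pattern
(half, stripes, spots, reversed spots, graded gaussian, checker; binary
values {0, 250}); a diffusive field secreted by population cells
(`α = 10⁴`, `D = 2.5·10⁵`, decay 0); or a stochastic two-species Turing
system with linear reaction terms `f = 0.9·s_l − s_a + 0.2`,
`g = 1.2·s_l − s_a − 1` scaled by `γ = 10⁴`, differential diffusivities
(e.g. `(10⁴, 2·10⁵)` for stripes) and hard clipping of `S_l` to
`[s_lower, s_upper]` implemented rejection-free by zeroing the offending
propensity at the bound (a diffusing molecule aimed at a full mesh is
rejected). The Turing run starts from the homogeneous reaction balance
(`s_l = 4`, `s_a = 4` at the defaults) and stochasticity supplies the
symmetry-breaking perturbation; the maturation horizon is a configuration
choice (default a few reaction relaxation times, `γ·t ~ 10–100`).

## Phases, movement, and the stop rule

Phase 1 (signal maturation): only determinant dynamics, movement, and
leading-signal reactions run; the stem population is frozen. Phase 2 begins
after a configured horizon: divisions and transitions switch on and the
tissue forms. Phase 3 starts once both specialized types are established
(counts above a threshold): all leading-signal reactions stop and the
residual field is frozen — it still gates `ε` wherever no territorial
signal is present.

Movement relocates a cell to a uniformly chosen empty in-dish mesh. The
global target is deliberate: movement exists to keep the system from
blocking, and with neighbour-local movement a crowded tissue freezes —
measured on a patterned dish, every movement firing was blocked and the
population drained because stem/progenitor cells could never reach
vacancies. In the borderless variant movement stays neighbour-local so that
restricted migration off the matrix remains meaningful.

The division clock counts firings of the constant-rate division channels
(so "`k` divisions on average" means `t ≈ k/r`); a firing that finds no
empty neighbour is a no-op for the state but still advances the clock.

## Death control and homeostasis

`A`/`B` abundance targets come from the leading pattern: with `p` the
fraction of in-dish meshes above half the pattern maximum,
`n*_A = p·0.85·N` and `n*_B = (1−p)·0.85·N`, leaving 15% of the dish for
stem cells, progenitors and vacancies. Controllers: `step` (0.05 below
target, 0.1 above), `linear` (`(n/n*)·v_g`), `cube_root` (`(n/n*)^⅓·v_g`)
with `v_g = 0.0125`, plus a non-adaptive `fixed` mode (0.003/0.0034, the
reported time-averaged values) for runs without a pattern-defined target.
Below target the cube-root rate exceeds the linear one everywhere — the
increased small-deviation sensitivity that motivates it.

Two feedbacks jointly set the homeostatic composition: the death controller
pins `n_A`, `n_B` to their targets, and `ι(n)` pins the total density. The
reference density `n_ref` anchors the latter and must sit at the intended
occupancy: the default is `0.85·N`. Calibrating it far below (e.g.
`0.3·N`) starves the stem/progenitor pool at working density — with
self-renewal off, every vacancy capture is a terminal division, and the pool
was measured to go extinct within ~60 time units, after which the tissue
decays; anchoring at the homeostatic density sustains the pool indefinitely
(measured: `S ~ 10–25`, `P ~ 20–50` over 100 time units on a radius-15
dish, with `n_A` within a few percent of target).

## Borderless variant

With `adhesion.enabled` the wall is removed (grid 3× the seed diameter) and
a minimal cell–matrix adhesion layer substitutes for it: matrix is wherever
`S1 + S2 + S_l ≥ 1` molecule or inside the founding disc; off-matrix cells
cannot divide, move at a 0.1-damped rate, and acquire an apoptosis
propensity of 0.1 regardless of type. All adhesion constants are defaults
to be sensitivity-tested, not literature values.

## Pattern score

The template is `+1`/`−1` at in-dish meshes above/below half the pattern
maximum and 0 outside; the penalty is 1 exactly at out-of-dish meshes. A
snapshot maps to `±1` at `A`/`B` cells, zero-padded into a `2d×2d` matrix;
the raw score is the maximum over all filter placements of (template
correlation − penalty correlation), normalized by the perfectly matching
snapshot's score. Scores are reported unclamped (anti-matching snapshots go
negative); the max-over-offsets makes the score insensitive to rigid
translations. Sliding sums use direct FFT-free correlation — at `d ≤ 201`
nothing faster is needed.

## Scaled study sizes and what they show

The full-scale configuration (radius 100, 50–100 divisions, 500–1000
snapshots) is supported but the test suite and the acceptance script run
scaled versions chosen by timescale arguments, not by tuning:

* **Formation** (half/half pattern): radius 25, stop at 10 mean progenitor
  divisions. Placement fractions measured across 5 seeds: ≈85–90% of each
  specialized type in its intended half.
* **Maintenance**: radius 15 starting from an established pattern at the
  homeostatic occupancy (the pattern-scoring procedure prescribes starting
  from the patterned state), horizon 100 time units ≈ 1.25 death-turnover
  times. At this scale both traces still carry a transient toward their
  defect equilibrium — the signal halo `√(D/k) ≈ 15` meshes spans much of a
  small dish — so the wide-vs-narrow contrast appears as the striped
  pattern losing more score in total and continuing to decline through the
  final quartile while the gaussian trace flattens. Full saturation needs
  `t ~ 3/γ ≈ 240` time units and a dish large against the halo; the scaled
  runs demonstrate the mechanism, not the plateau itself.
* **Controller comparison**: gaussian maintenance at radius 15 for 30 time
  units; final-quartile `|n_A − n*|/n*` medians ≈ 0.026 (cube root) vs
  0.031 (linear).
* **No-signal control**: radius 25 to 10 mean divisions with fixed death
  rates; all four types appear and like-type adjacency of specialized cells
  exceeds a 200-fold label-permutation null by >4 null standard deviations.

The synthetic initial states emulate a uniformly seeded dish (sparse random
stem cells, default 5% of meshes) and, for maintenance runs, an idealized
established tissue (cells laid exactly on the template at 85% occupancy
with warm signal fields). Real colonies grow from clonal foci, have graded
boundaries and mechanical interactions; none of that is modelled, so
passing tests certify the reaction–diffusion/decision logic, not
quantitative agreement with any experimental tissue.

## Numerical choices

* Fixed points: residual-minimum seeding on a coarse grid, hybrid-Newton
  polish, deduplication, classification by central-difference Jacobian
  (step `10⁻⁵`) with tolerance `10⁻⁸` on the right-hand-side norm.
* Basin maps: fate of a lattice point is the nearest stable state within a
  capture radius after forward RK4 integration; ties on unresolved fills go
  to the progenitor label.
* Mean-field steady states: LSODA integration (`rtol = atol = 10⁻¹⁰`)
  followed by a Newton polish; fixed-point tolerance `10⁻⁹`.
* Degenerate inputs: an empty dish with no reactions reports a stalled
  status rather than spinning; a division or movement firing with no target
  is a logged no-op; the `S_a` death propensity `γ(s_a + 1)` fires as a
  null event at zero count.

## Known limitations

* The emergent division-channel rates (`η`, `λ`, `μ` families) are measured
  from event logs, not derived analytically from the switch parameters; the
  mean-field cross-check is therefore a consistency test, not an
  independent prediction.
* Quantized `(ε₁, ε₂, ι)` basin families introduce a classification
  granularity of half a quantization step; at the defaults this moves
  decision boundaries by at most a few determinants, small against binomial
  partitioning noise.
* Homeostatic filling from a sparse seed takes `t ~ 1/γ_{A/B}`; scaled
  formation runs stop long before that, so their endpoint composition is
  S/P-rich relative to the long-run tissue.
* Spot and reversed-spot formation inherits the known asymmetry of
  dominant-territory invasion; no claim about their maintenance is tested.
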