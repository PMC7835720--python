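# Methods

## Problem

When people pick up a novel object with a two-digit precision grip, they
choose a thumb/index contact pair from an enormous space of possibilities
(a 10-cm sphere already offers ~100 fingertip-sized surface patches, hence
~10,000 ordered digit configurations). Human grasp points are well
described as near-optimal trade-offs among a small set of costs. This
package implements that computational chain for cube-lattice (polycube)
stimulus objects and the psychophysics built on top of it: designing
grasp pairs that isolate a single optimality criterion, simulating
two-alternative forced-choice (2AFC) "which grasp is better" judgments
across vision / video / grasping sessions, and analysing the resulting
percent-correct data.

## Object model

Objects are solids of face-connected unit cubes (default side s = 2.5 cm)
with per-cube material (beech wood or brass). Mass is `Σ s³·ρ(material)`
and the center of mass (COM) is the mass-weighted mean of cube centroids.
Default densities are ρ_wood = 0.62 g/cm³, chosen so that a 10-cube wooden
object weighs 96.875 ≈ 97 g, and ρ_brass = 8.5 g/cm³; both are
configurable. The demo stimulus set uses 5-brass/5-wood mixtures for the
heavy objects (712.5 g at these defaults; matching a 716 g reference
exactly would need ρ_brass ≈ 8.55 g/cm³, so the heavier figure is treated
as a reference value, not a constraint). Poses are restricted to turntable
placements: a rotation about the vertical axis plus a translation, with
the object resting on the table plane z = 0 and the participant on the −y
side.

The exposed surface (faces not shared between two cubes) is discretized
into candidate contacts, by default one per face center (`per_face_grid =
1`), matching the coarse fingertip-patch budget above and keeping the
exhaustive pair search trivial; finer grids are available.

## Grasp scoring

A candidate grasp is an unordered pair of contacts. The hard constraint is
**force closure**: the line between the contacts must lie inside both
friction cones, i.e. the angle between each contact normal and the
connecting line toward its own side must not exceed `atan(μ)` (default μ =
0.5, cone half-angle ≈ 26.6°). Grasps failing this (e.g. both digits
pushing on the same side) cannot lift the object and are discarded before
scoring.

Four soft costs are computed per surviving grasp:

| criterion | definition | units | rationale |
|---|---|---|---|
| aperture | `max(0, aperture − a₀)`, a₀ = 2.5 cm | cm | precision grips are abandoned above ~2.5 cm |
| nga | acute angle between the (undirected) grasp axis and the natural grasp axis | rad | misalignment forces uncomfortable arm/hand postures |
| torque | \|((COM − p) × m·g·ĝ) · â\| | N·m | weight torque about the grasp axis makes the object pitch in the grip |
| visibility | fraction of surface sample points whose ray to the eye crosses the hand volume | – | the grasping hand hides the object |

The natural grasp axis defaults to a horizontal unit vector at 45° between
the lateral and frontal axes; the viewpoint defaults to 34 cm on the
participant's side of the object and 30 cm above the table. The hand is a
deliberately crude occluder — a rectangular slab spanning the two
contacts, 3 cm wide, extruded 10 cm from the contact line toward the
viewer — and only the *ordering* of grasps by occluded fraction is treated
as meaningful. All four costs are symmetric under thumb/index swap, which
is why enumeration uses unordered pairs (the ~10,000 ordered-pair figure
is reproduced only by the combinatorial-budget helper).

Because the costs live on incommensurable scales, they are min–max
normalized within each object's candidate set (best grasp per criterion →
0, worst → 1; a constant criterion → 0 for all) and combined as a weighted
sum (default uniform weights). The exact functional forms and weights of
such cost models vary in the literature; the forms above are fixed here
and exposed through `ModelConfig`.

## Stimulus design

For each object and one target criterion, the designer exhaustively
searches ordered candidate pairs (near, sub) and keeps the pair maximizing
the target optimality difference Δ (sub's normalized cost minus near's,
positive = near better) subject to |Δ| ≤ ε on the three off-target
criteria. ε = 0.2 normalized units defines "approximately constant"; the
tolerance is a design choice, configurable per run. If no pair satisfies
ε, the fallback takes the pair with the smallest worst off-target |Δ|
within the top decile of target Δs and flags it `relaxed` in every output.
Objects are assigned to criteria in fixed blocks (default 4 objects per
criterion × 4 criteria = 16 pairs), mirroring hand-assignment rather than
a global optimization; the counterbalance report sums signed off-target
Δs within each block so residual differences can be checked for
near-cancellation across objects. Sticker colors (blue/green) are a seeded
random map from the near/sub roles.

## Observer model

The response model is scaffolding for the data's *structure*, not a claim
about human mechanism. The probability of judging the near-optimal grasp
"better" is

    P(correct) = λ/2 + (1 − λ) · logistic(k·Δ)

with session-specific sensitivity k ≥ 0 and lapse rate λ ∈ [0, 0.5]. k = 0
gives exactly 50% (chance); Δ is by default the target-criterion
normalized difference (a combined-cost switch exists). Defaults are
k_vision = 0, k_video = k_grasping = 3, λ = 0, emulating the qualitative
replication pattern: at chance from vision alone, equally above chance
from watching videos or grasping. The observer is memoryless across
trials, matching the absence of within-session learning in the judgments
being emulated; an optional linear drift in k per trial exists for power
analyses only. Each participant gets an independent RNG stream
(`SeedSequence((master_seed, participant_id))`), so adding participants
never perturbs existing ones. `fit_observer` recovers k per session by
bounded 1-D maximum likelihood with λ fixed; estimates pinned at the
bounds are flagged.

What the generator does **not** emulate: object-specific difficulty beyond
Δ, response biases, sequential dependencies, presentation-order effects,
kinematics. Tests passing on these synthetic cohorts show the analysis
chain is correct and calibrated, not that human judgments follow the
logistic model.

## Statistics

Percent correct is aggregated per participant × session (chance = 50%).
Frequentist: one-sample t vs 50, paired t between sessions, and an
unpaired sibling in pooled and Welch variants (both exposed, since the
appropriate variant depends on the design). Zero-variance data raise a
degenerate-test error unless the constant equals the reference exactly,
where t = 0 by convention. Bootstrap CIs use the seeded percentile method
(10,000 resamples by default). Effect sizes are (mean − 50)/σ and
mean(a−b)/σ(a−b).

Bayesian estimation follows the robust ("BEST"-style) one-group model: a
Student-t likelihood with a broad normal prior on the mean (scale 1000·sd),
a uniform-on-log prior on the scale within [sd/1000, sd·1000], and a
shifted exponential (mean 29, offset 1) on the normality parameter ν.
Sampling is random-walk Metropolis over 4 over-dispersed chains, 10,000
iterations each with 2,000 burn-in, joint Gaussian proposals whose global
scale adapts toward ~30% acceptance during burn-in and is frozen after.
Convergence is gated at R̂ ≤ 1.1 per parameter (Gelman–Rubin across
chains); failure raises with chain diagnostics. The 95% HDI is the
shortest window over the sorted posterior draws; the ROPE on effect size
is ±0.4 by default and the reported fraction is the posterior mass inside
it. Paired contrasts reuse the one-group model on the differences. No
multiple-testing correction is applied — contrasts are reported
per-comparison.

The replication-subset rule selects objects whose vision-session bootstrap
CI contains 50 *and* whose grasping-session one-sample t is significant
(two-sided p < 0.05) with a positive mean; the learning check regresses
correctness on within-session trial index per participant and tests the
slopes against zero per session.

## Numerical and scale choices

- Torque converts cm → m and g → kg, so values are in N·m; the per-cell
  moment sum is used as an independent oracle in tests (agreement 1e-8
  relative).
- Ray/slab occlusion uses a slab test in the box frame with a 1e-9
  tolerance; grazing contact exactly at a surface sample point does not
  count as occlusion.
- Ties in combined cost and in pair selection are broken by the
  deterministic enumeration order.
- Calibration suites use 2,000 simulated cohorts for the type-I error
  check and 500 cohorts for the chance grand mean; parameter recovery uses
  200 simulated participants. These sizes give sub-percent Monte-Carlo
  error on the quantities checked while keeping the default suite quick.

## Known limitations

- Two digits only; no palm contact, grip-force planning, or dynamics.
- The hand occluder and the four cost forms are plausible but not fitted
  to human data; absolute cost values are meaningless, only orderings and
  normalized differences are used.
- The demo object shapes are stand-ins with the right cube count and
  material structure, not the original stimulus shapes.
- The Bayesian sampler is a simple Metropolis scheme adequate for these
  3-parameter posteriors; it is not a general-purpose MCMC engine.
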