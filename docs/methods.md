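# Methods

## The model

A *position* is one time-slice of a possession: the (x, y) coordinates of
five offensive agents, five defensive agents, and the ball on a half-court.
Every position is reduced to a pair of **density fields**: each agent
contributes an isotropic 2-D Gaussian (sigma = 5 ft) centered at its
location, and the group field in each 5×5 ft bin of a fixed 10×10 grid is
the Gaussian probability mass integrated over the bin rectangle (an expected
head-count, additive over agents; mass off the grid is discarded). Fields
are then discretized to integer levels 0–19 with a linear rule calibrated so
that one agent standing at the exact center of an interior bin yields level
7 in that bin; three coincident agents reach 21 before clipping at 19.
Rounding is half-away-from-zero with a 1e-9 tie guard. This makes the state
of a position a pair of integer vectors (n_o, n_d) over 100 bins, insensitive
to sub-half-foot jitter and invariant under permutations of same-group
agents.

Coordinates: x ∈ [−25, 25] sideline to sideline, y ∈ [0, 50] from the
half-court line toward the baseline, hoop at (0, 41.75). The 50 ft grid
overhangs the 47 ft physical half-court by 3 ft so the bins stay square.
The 3-point boundary is the 23.75 ft arc about the hoop truncated by |x| =
22 ft corner lines.

Two probabilistic models of the per-bin joint density distribution are
provided:

* the **direct (DP) table** P_b(n_o, n_d) — 100 × 20 × 20 = 40,000 free
  probabilities, estimated by weighted counting with a uniform pseudocount
  `alpha` per state (default 0.1) so held-out loglikelihoods stay finite;
* the **reduced exponential-family model**
  P̃_b(n_o, n_d) = Z_b⁻¹ exp(−n_o·v_o,b − n_d·v_d,b − f(n_o, n_d)),
  600 parameters: one shared interaction surface f (20 × 20) capturing the
  bin-universal coupling between the groups' densities, and one potential
  per bin per group, lower values marking preferred locations.

A position's loglikelihood surrogate is ln P̃ = Σ_b ln P_b(n_o,b, n_d,b);
it ignores inter-bin correlation, which is why all downstream uses are
comparative (differences between conditioned models) rather than absolute.

## Fitting the reduced model

The reduced model minimizes Σ_b KL(P_b ‖ P̃_b), convex up to flat gauge
directions, by alternating:

1. **Per-bin tilts.** For fixed f, each bin's (v_o,b, v_d,b) solves a 2-D
   convex dual (log-partition plus linear term) by Newton's method with
   backtracking line search, vectorized over bins, until the model means
   match the empirical bin means. Potentials are capped at |v| ≤ 30: a bin
   whose empirical mean sits exactly at a boundary level has its matching
   potential at infinity, and the cap makes such bins effectively
   point-mass without stalling.
2. **Iterative scaling of f.** The stationarity condition is
   Σ_b P̃_b(s) = Σ_b P_b(s) per state s; f moves by half the log-ratio
   (damping 0.5). States with zero empirical mass everywhere are pinned at
   f = 50 (probability effectively zero but finite — they are unconstrained
   by the objective).
3. **Re-gauging.** f ← f + a·n_o + c·n_d, v ← v − (a, c) with a, c the bin
   means of the potentials, and f(0,0) subtracted. The transform changes no
   probability (tested to 1e-10 end to end).

Initialization f = −ln(mean_b P_b), v = 0 is exact for homogeneous bins.
Convergence: objective change < 1e-8 and gauge-fixed parameter change
< 1e-6, maximum 5,000 outer iterations; non-convergence is reported in the
`FitReport`, never silently. The objective is computed in log space and is
monotone nonincreasing across iterations (asserted in tests). On a
100-bin, 20-level problem the fit takes well under a second; per-bin mean
errors and per-state mass errors at convergence are below 1e-6.

The KL sum weights bins equally, as written; an occupancy-weighted variant
was considered and rejected as the default because the equal-weight form is
the one whose stationarity conditions the alternating scheme solves
exactly.

## Localization, scoring, calibration

*Hidden-agent scan*: with 4 of 5 defenders known, every half-foot cell
center (100×100 cells by default) hosts the hypothetical fifth defender;
the fixed 9-agent density contribution is computed once and the candidate's
bin-mass vector added incrementally, which equals full recomputation
exactly (tested) and is independent of evaluation order. The top-q area is
the prediction; ties break by (row, column).

*Outcome scoring*: ln P̃ under models conditioned on play outcome R ∈
{0, 2, 3}; differences such as ln P̃_{R=2} − ln P̃_{R=0} are binned
(default width 2.0, minimum 50 samples per bin — the bin settings are this
package's choice) against realized outcomes, and a least-squares line
through the surviving bin means reports the slope in percentage points per
unit loglikelihood difference plus the Pearson correlation of the bin
means. 2-point calibration is meant for positions with the ball inside the
arc, 3-point outside.

*Defensive gain*: per shot-time frame, remove the rated defender, build the
top-10% region from the successful-defense model, skip the frame if the
defender stands outside it (filters atypical assignments while keeping most
plays), and otherwise score D(actual) − mean_region D with
D = ln P̃_{R=0} − ln P̃_{R=r}. Points saved per game converts the two
gains through the calibration slopes at 60 two-point and 30 three-point
attempts.

*Gravity*: at an anchor location, four reduced models are fitted — player
present within 5 ft vs any offensive agent present, split off/on-ball at
3 ft ball-to-occupant distance — and all are evaluated on the *same*
offensive configurations (every frame with an agent at the anchor) through
the 9-bin mean of E[n_d | n_o] around the anchor bin. Reporting is in
*ball equivalents*: the per-anchor linear map sending the typical player's
off-ball value to 0.00 and on-ball value to 1.00. Evaluating both models on
identical configurations is what deconfounds teammate positioning: a
teammate's pull on the defense enters both models through the offensive
density field. These fits use a near-zero pseudocount (1e-3): a uniform
pseudocount drags each subset toward the uniform table in inverse
proportion to its size, and with a 40-observation-equivalent pseudocount a
200-frame player subset reads about one full ball equivalent above a
1,100-frame typical subset — a pure small-sample artifact. Subsets below
`min_frames` mark the metric unavailable rather than fabricating a value.

## The synthetic world

The generator exists so every stage is testable without any external data;
its defaults are the package's study conditions and were fixed once.

* **Truth model**: f has quadratic self-terms (0.06·n²) and a positive
  offense–defense coupling (−0.035·n_o·n_d), giving mean bin levels near
  2.4 — what five agents' unit masses spread over a half-court produce —
  with defense up to ~6–7 near the rim. Offensive potentials favor the rim
  and a ring along the 3-point arc; defensive potentials favor the rim.
* **Per-bin sampler** (`sample_states`): independent draws from P̃_b per
  bin — the exact-recovery harness, since the fit treats bins
  independently. 50,000 draws recover (f, v) at r > 0.99 and held-out
  loglikelihood within 0.1%.
* **Frame sampler** (`sample_frames`): Metropolis–Hastings over the 10
  agents' continuous coordinates; the target is exp(−H) with H the truth
  bin energy evaluated through the real density pipeline plus smooth
  agent-level terms: defender attraction to the ball (depth 3.0, sigma
  3.5 ft — the on-ball defender presses tight) and any scripted player
  effects. Proposals are single-agent Gaussian steps (sigma 2 ft, adapted
  toward 30% acceptance during burn-in) mixed with 15%-probability
  court-wide relocations; the mixture is symmetric so plain Metropolis
  acceptance applies, and the relocations are what lets individual agent
  labels mix across the court on practical chain lengths. Each play fixes
  the ball — carried by a random offensive agent with probability 0.8,
  else free at a random anchor — with a short re-equilibration gap after
  each switch. Frames within and across plays are autocorrelated, which is
  deliberate: it exercises robustness to the bin correlations the reduced
  model does not represent. What this world does *not* emulate: play
  choreography (screens, cuts, drives), shot-clock dynamics, and any 3-D
  ball flight — so passing tests demonstrate statistical correctness of
  the inference, not basketball realism.
* **Outcomes** (`assign_outcomes`): per play, success probability is
  logistic in a documented configuration score — 3 × (2 − local 9-bin
  defensive density at the ball) at the shot frame — with the stated slope
  defined at the operating point (2%/unit by default); success maps to
  R = 2 inside the arc, 3 outside. A clipped linear link
  (P = 0.45 + slope·s/100) is also provided: the logistic's binned
  least-squares slope over a wide score range is necessarily shallower
  than its center slope, so exact slope-recovery checks use the linear
  form.
* **Player effects** (`inject_player_effect`): `magnet` lowers the energy
  of the *nearest* defender by a Gaussian bump following the flagged
  agent (primary-defender attention; attracting all defenders at once
  would also drag the star toward packed defense, which is neither
  realistic nor useful); `spot_up` gives the flagged agent a personal
  preference for the arc ring (a shooter's positional profile);
  `rim_protector` attracts the flagged defender to the rim while the ball
  is inside the arc (implemented as an energy term so detailed balance is
  preserved and the stationary distribution is well defined); `tether`
  binds an agent to a buddy teammate, used to script deconfounding
  scenarios; `null_twin` records a flagged agent with no deviation.
  Effects compose additively in energy; magnitude 0 equals the null twin.

Measured under these conditions (seeded, reproduced by the test suite): a
null twin's off-ball gravity is 0 within the replicate CI; a magnet of
depth 1.5 (half the ball attraction, wider) measures ≈ 1.0 ball
equivalents off-ball — the scale the field associates with an elite
shooter; and a non-magnet tethered to a magnet teammate stays well below
the raw magnet effect.

## Ball anchors

The conditioning anchors for ball location are 89 points, 36 inside the
3-point line and 53 outside, with Gaussian weighting (sigma = 2 ft) and a
2 ft hard radius for test-set restriction. A single uniform lattice cannot
produce that 36/53 split — the inside-arc region is about half the
half-court area, not 40% — so the default set is two symmetric square
lattices clipped to their regions: 5.5 ft spacing inside the arc, 4.9 ft
outside (denser where 3-point shots originate). The set is user-replaceable
via CSV.

## Numerical and design choices

* Discretization rounding: half-away-from-zero with +1e-9 tie guard; the
  level-7/level-19 anchors admit several linear maps and this package pins
  delta = c1/7 with c1 the single-agent center mass (0.146631).
* Density semantics: bin-integrated mass, not point-sampled centers —
  "average density over an area" with exact additivity.
* Filters use closed boundaries (≤/≥) everywhere; the long-axis velocity
  for the transition filter is computed once per play on the full table
  (central differences, one-sided at edges, zero for single-frame plays),
  so the frame filters are pure per-frame predicates and commute.
* Train/test splits are play-level to avoid within-play leakage.
* Models serialize to NumPy `.npz` with an embedded JSON header recording
  grid, levels, pseudocount and conditioning metadata.
* Problem sizes in the test suite (replicate counts, 1,500-play chains,
  50,000-draw recovery) are the package's chosen desk-scale study
  conditions; the statistical checks are written against the properties,
  not the sizes.

## Known limitations

* ln P̃ treats bins as independent; absolute likelihoods are not
  calibrated probabilities, only differences are used.
* The reduced model's f is unconstrained on states never observed; the
  f = 50 cap is a convention, and predictions for such states are
  extrapolations.
* Gravity requires enough frames in all four conditionings; perimeter
  anchors for low-usage players will frequently be unavailable, which is
  reported rather than imputed.
* The MCMC world's inter-bin correlations are stronger than the reduced
  model assumes; localization and calibration results on it are therefore
  conservative relative to the in-family samplers.
* The rim-protector effect conditions on ball position instantaneously;
  no anticipation or delay dynamics are modeled.
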