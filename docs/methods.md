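# Methods

`capsakinesis` quantifies how chemokinesis — a non-directional increase in
crawling speed in response to a dissolved chemical — can benefit a
unicellular predator that attaches irreversibly to its prey. The concrete
system is *Capsaspora owczarzaki* preying on schistosome sporocysts, with
serum albumin (BSA) as the model chemo-effector. The package has three
layers: generators of synthetic raw data with known ground truth, the
track/dose/trace analysis pipeline, and an agent-based predation
simulation over a diffusing chemical field.

## Cell motility model

Crawling cells are modelled as a persistent random walk in 2-D. At each
step event the heading turns by an angle drawn from a normal distribution
with SD `turn_sd` (default 0.3 rad), truncated symmetrically at
`±turn_bound` (default π); the cell then advances by an exponentially
distributed distance whose mean is speed × step interval. This encodes two
empirical features of crawling *Capsaspora*: strong directional
persistence (small adjustments dominate, reversals are rare) and
exponentially distributed travel distances per filopodial extension.

For a truncated-normal turn with effective SD σ the per-step direction
correlation is `E[cos Δθ] = exp(-σ²/2)`, so the persistence time is
`τ = 2·Δt/σ²` — about 22 min at the defaults (σ = 0.3, Δt = 60 s). The
exact ensemble mean-squared displacement after n steps is

    MSD(n) = n·E[L²] + 2·E[L]²·Σ_{k=1}^{n-1} (n-k)·α^k,   α = E[cos Δθ],

which reduces to the familiar ballistic-then-diffusive persistent-walk
form (`MSD ≈ v²t²` for t ≪ τ, `MSD ≈ 2v²τ·t·(1+CV²_L/…)` for t ≫ τ).
Both the track generator and the simulation engine are tested against this
closed form to within 10% over lags up to 5τ.

The track generator (`synth.generate_tracks`) additionally injects the
tracking artifacts real pipelines must remove: "floating cell" jumps
(uniform-direction displacements of 16.8 µm = 1.5 × the 11.2 µm step
filter, so the filter catches every one by construction) and dropped
detections at a configurable per-frame rate. Step lengths are exponential
with mean `step_mean` when that field is set; when it is `None` the
generator moves cells exactly `speed × frame_interval` per frame, which
gives clean closed-form limits (straight lines at `turn_sd = 0`). Tracks
may leave the arena — the generator does not reflect, and the analysis
tolerates it.

## Track analysis

All rules operate on tracks (time-ordered detections; missing frames are
absent rows, never interpolated — "gap filling" is deliberately not
implemented anywhere):

* **Spurious-reading filter.** A track is rejected if any adjacent-frame
  step exceeds `max_step` (11.2 µm for the co-culture assay, 2.30 µm for
  the calcium assay) or if tracking was lost for more than `max_gap` = 3
  consecutive frames; tracks shorter than 3 frames are dropped. Each
  rejected track is attributed to the first rule it violates, in the fixed
  order step → gap → length → duration → annulus, so rejection counts are
  permutation-invariant and sum to the input size.
* **Annulus selection.** When a prey reference is given, only cells whose
  *first* detection lies 70–240 µm from it are kept: closer cells may
  already touch the prey via filopodia (up to ~24 µm long), farther cells
  sit near the field-of-view edge. Membership is evaluated once, at
  selection time, not per frame.
* **Chemotaxis metric.** Net movement toward the reference =
  distance(first, ref) − distance(last, ref), positive for approach;
  restricted to tracks ≥ 120 frames (2 h) so maximal displacement is
  observable. The metric is exactly invariant under rotations about the
  reference (property-tested).
* **Chemokinesis window.** Step velocities (µm/min, adjacent-frame pairs
  only, gap-spanning pairs skipped) pooled from cells 70–90 µm from the
  prey during the first 15 minutes — the band and window with the maximal
  response. An empty selection is returned empty with a warning, never as
  a zero.
* **Plate-reader mean velocity.** The spurious-reading control in the
  plate-reader assay is a subpopulation cut: keep cells that migrated at
  most 60 µm (total path length by default; a `net` displacement toggle is
  provided because the instrument's definition is ambiguous) and were
  tracked at least 18 frames; average each cell's step velocities, then
  average across cells.
* **Distant cells.** Cells whose nearest neighbour exceeds 60 µm — twice
  the filopodial reach, hence incapable of cell-cell contact — identified
  at the first frame by default, with a stricter all-frames mode.
* **Calcium traces.** Incomplete traces are removed; each remaining trace
  has its initial intensity subtracted (normalising every cell to zero at
  frame 0); traces are averaged per frame within a well and mean ± SEM
  taken across wells.

## Dose-response model

Velocity versus inducer concentration follows a four-parameter Hill curve
`v(c) = v0 + (vmax − v0)·c^h/(EC50^h + c^h)` — the standard monotone
saturating family. Fitting is plain least squares (`scipy.curve_fit`) with
multi-start initialisation (EC50 starts at the quartiles of the positive
doses; h at 0.5/1/2 unless fixed), making the fit equivariant under
rescaling of the dose unit. Dose 0 is evaluated exactly, never replaced by
a pseudo-dose. Flat data are detected *before* fitting (dose-group span
below twice the within-group SEM) and returned flagged as
EC50-unidentifiable; non-convergence is likewise flagged, never silently
returned.

A recovery study (frozen in the tests) fits 100 seeded synthetic data sets
of 8 log-spaced doses × 3 replicates. At noise of 5% of the response
range the median |EC50 error| is ≈ 7%; at 10% noise the same design sits
near its information floor at ≈ 14% (the implementation agrees with an
independent Nelder–Mead refit of the identical objective to < 10⁻⁵, so
this is the estimator's true sampling precision, not an optimisation
artifact). Precision claims tighter than ~10% therefore require the
lower-noise design, and the tests say so explicitly.

The serum arithmetic helper multiplies the albumin content of serum
(≈ 25 mg/ml) by the serum EC50 dilution (≈ 1% v/v) to give the albumin
concentration present at that dilution, 0.25 mg/ml — the same order as
the directly measured EC50 of pure albumin (~1 mg/ml).

## Chemo-effector field

The prey exudes the chemical into a thin fluid layer; dispersal is
isotropic diffusion with constant diffusivity, treated depth-averaged in
2-D. The default diffusivity is 60 µm²/s — the literature order of
magnitude for a ~66 kDa protein in water at room temperature — and is a
configuration value, not a measured one. Concentrations carry dose units
(mg/ml), so a source rate has units concentration·µm²/s.

The solver is explicit central differences on a square grid (default
spacing ≈ 12 µm) with the usual stability bound `dt ≤ dx²/4D`, enforced
before integration and satisfied automatically by substepping. Edges are
Dirichlet-zero ("absorbing": the domain extends 3× beyond the arena, so
the edge mimics an open bath) or zero-flux ("reflecting", used by the
conservation tests). Verified properties: exact linearity/superposition;
mass conservation to < 0.5% with reflecting edges; agreement with the 2-D
Gaussian Green's function to < 2% away from the release cell; near
second-order convergence under grid refinement (error ratio ≥ 3 per
halving). A radially symmetric finite-volume solver over annuli provides
a fast path for the single-prey geometry and an independent cross-check.

Prey exudation may couple linearly to the number of attached predators
(`rate = base + coupling·n_attached`). The simulation default sets the
coupling to zero — a constant live-prey source. With any appreciable
coupling the source grows ~100-fold as attachment proceeds, saturating
the arena and inflating the predation benefit far beyond the measured
regime; the coupled source remains available in the configuration.

## Predation simulation

2000 point agents (they do not interact, so `n_cells` sets Monte-Carlo
precision, not crowding) hunt one stationary prey, a disk of radius 40 µm,
for 120 simulated minutes with one step event per minute, in a square
arena with reflecting edges. Movement segments are tested against the
prey circle by segment–circle intersection, so a fast chemokinetic step
cannot tunnel through the prey; a crossing agent is clipped to the surface
and attaches irreversibly at the interpolated sub-step time. Attachment
times below one step interval are therefore continuous. Cumulative
residence time — the headline statistic — is Σ (duration − attach time)
over attached agents, and equals the time-integral of the attached count
exactly (tested).

With chemokinesis enabled, each free agent's speed is the Hill response
evaluated at its local (bilinearly interpolated) concentration; disabled,
every agent moves at the baseline `v0`. The default speed law uses the
measured pure-BSA EC50 of 1 mg/ml with assumed `v0 = 1` and `vmax = 3`
µm/min (the underlying velocities are figure-only; the 3× span matches the
magnitude of the measured response). Random draws (one turn, one unit
exponential per free agent per step) do not depend on the field, so
chemokinesis-on over a zero field is trajectory-identical to
chemokinesis-off under a shared seed — an exact equivalence the tests
assert.

The field is warm-started: the prey has been exuding before observation
begins, so the concentration profile is spun up for one run-length
(7200 s) at the base rate before t = 0. Without the warm-up the two
conditions are indistinguishable early in the run and the chemical only
matters late, which is not the observed phenomenology.

### Parameterisation of the default condition

Two parameters have no measured anchor: the arena size and the base
exudation rate. They were chosen — once, with the physical parameters
above held fixed — to reproduce the qualitative regime of the study they
emulate, and all acceptance statistics are then computed with no further
adjustment:

* **Arena 140 µm.** The benefit of pure chemokinesis shows up in the
  *conditional* attach-time distribution only in a pool-depletion regime.
  If the attachment hazard is roughly constant in time (a large,
  continuously replenished far pool), a spatially uniform speed-up leaves
  the conditional attach-time distribution unchanged —
  `F_on(t) = F_off(a·t)/F_off(a·T)` equals the off-condition conditional
  CDF whenever `F_off` is linear — and wide scans over larger arenas
  (250–600 µm, many source strengths and Hill slopes) confirmed no robust
  earlier-attachment signal there. With the arena restricted to the
  prey's immediate neighbourhood, about half the population attaches
  within 2 h even without chemokinesis, the reachable pool saturates, and
  speeding cells up makes the same cells attach earlier — reproducing the
  expected ordering, the earlier conditional attachment, and a modest
  residence benefit simultaneously.
* **Base rate 40 concentration·µm²/s.** Sets the warm-started
  concentration at the prey surface to a sub-EC50 value (~0.3 mg/ml,
  decaying outward), i.e. a speed boost of roughly 1.2–1.3× near the prey
  rather than saturation. Stronger sources push the cumulative-residence
  ratio far above the measured ~1.25×.

At these defaults, across six disjoint seed triplets the
cumulative-residence ratio was 1.21–1.29 (target ~1.25), the on-condition
attachment fraction exceeded the off condition in every replicate, and the
one-sided Mann–Whitney test for earlier conditional attachment gave
p ≤ 0.03 in every triplet.

### Depleted-prey scenario

Four recently devoured prey, 150 µm from the live one along the
diagonals, each release a final burst at the start of the run. The default
burst mass is the devoured prey's body footprint at the half-maximal dose
(π·40²·EC50 ≈ 5×10³ concentration·µm²). With albumin-scale diffusivity a
burst of this size dissipates within minutes — fast relative to cell
movement — and the measured effect on cumulative residence (+0.5 ± 1.6%
over eight seed triplets) is statistically indistinguishable from the
plain chemokinesis condition, matching the expected null result. Note
that any perturbation of the field decorrelates individual trajectories
(the dynamics are chaotic at the agent level), so the comparison is
between condition means, not paired trajectories; with three replicates
per condition the ±2·SEM overlap check retains a residual seed-to-seed
failure probability of roughly one in ten even for a truly null burst.
The limiting behaviour is also tested: a slow-diffusing, very large burst
changes the outcome measurably.

## What the synthetic data do and do not emulate

The generators reproduce the statistical structure the analysis depends
on: persistent-walk kinematics with known speed/persistence, artifact
jumps guaranteed to trip the step filter, missing detections, Hill-shaped
dose-response with replicate noise, and baseline-plus-step calcium
transients with per-cell baseline variation. They do not emulate images or
segmentation (tracks are the input boundary), cell-cell avoidance or
contact, heterogeneous per-cell speeds, drift of the microscope stage, or
prey movement. Passing tests therefore validate the *computations* on
well-specified inputs; they do not certify tracker performance on real
microscopy.

## Numerical choices and edge cases

* Velocities use µm and minutes; time is seconds internally.
* Gap-spanning detection pairs are skipped in velocity estimates rather
  than divided by elapsed time.
* The step filter applies to frame-adjacent pairs only; the gap filter
  handles the rest.
* The exact-threshold step (= 11.2 µm) is kept; rejection is strictly
  `>`.
* Dose-response fits report residual SD with degrees-of-freedom
  correction; the flat-data pre-check uses dose-group means versus pooled
  within-group SEM.
* Field injection deposits uniformly over the grid cells covering the
  source disk; a release younger than one grid cell's diffusion time is
  deposited into the nearest cell.
* Simulation seeds map one-to-one to replicates; every run is bit
  reproducible from its configuration and seed list.
* Problem sizes in the test suite (hundreds to thousands of agents,
  30–160² grid cells, 100-fit recovery studies) were chosen so the whole
  battery, including the full-scale study conditions, completes in well
  under a minute on a single core.

## Known limitations

* The 2-D depth-averaged field ignores vertical concentration structure
  and any advection; exudation couples to attached count, not to a
  mechanistic feeding model.
* The predation benefit ratio is parameter-sensitive; the defaults
  reproduce the targeted regime but are assumptions where noted, and all
  of them are exposed in the configuration.
* `distant_cells` is O(n²) over tracks in all-frames mode.
* The Hill fit reports bootstrap-free asymptotic diagnostics only;
  profile-likelihood confidence intervals are out of scope.
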