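# Methods

## Scope and architecture

`gazesim` implements an integrated bottom-up/top-down model of overt visual
attention as a closed perception–action loop over a synthetic tabletop
world.  Six components cooperate, each behind its own module:

1. **virtual world** (`gazesim.world`) — coloured balls on the unit
   direction sphere, rendered through an analytic pinhole camera with a
   centred foveal window;
2. **early vision** (`gazesim.vision`) — foveal/peri-foveal stream split,
   R/G/B-dominance and movement filters, normalised salience, connected-
   component stimulus extraction, foveal feature classification;
3. **oculomotor mapping** (`gazesim.oculomotor`) — retinotopic→motor-delta
   and motor-delta→egocentric transforms, saccade execution;
4. **spatial memory** (`gazesim.memory`) — linearly decaying store of
   fixated gaze coordinates with bound feature vectors (the IOR source);
5. **priority map** (`gazesim.priority`) — convergence of salience, IOR
   decay and task relevance into one activation per candidate location,
   plus the saccade threshold;
6. **experiments** (`gazesim.experiments`) — the timed validation harness,
   fixation statistics, condition batteries and replication tests.

## Model assumptions

* The 2-DOF head measures only directions, so world objects live on an
  (azimuth, elevation) sphere; distances, lighting and occlusion beyond
  painter's order are out of scope.
* The pixel→motor mapping is the closed-form inverse of the renderer's
  projection.  A physical system would learn this mapping from sampled
  fixations; using the analytic inverse makes the retinotopic→egocentric
  round trip exact and removes a training phase without changing the
  architecture.
* Saccades reposition the camera instantaneously; a configurable saccade
  duration (default 0.2 s) is charged to the simulated clock and no frames
  are processed in flight (saccadic suppression).  The frame buffer used by
  the movement filter is cleared across saccades, so ego-motion is never
  mistaken for object motion.
* Colour intensity is *channel dominance* (channel minus the maximum of
  the other two, floored at zero), not the raw channel value: a grey
  background scores zero under every colour filter, which is what lets
  coloured balls pop out at all.
* Top-down modulation applies only to stimuli matched to a remembered
  fixation — classification requires the fovea, so unvisited stimuli carry
  raw salience.

## Task modulation form

The combination of IOR decay and task relevance is implemented as

    f = s (1 + E − H) − (1 − t/t_max)(1 − E + H),  floored at −1,

isolated in `gazesim.priority.modulate` so alternatives can be swapped.
The exact algebraic combination is a design choice of this package; it is
pinned down by behavioural constraints rather than by a canonical formula:
it must reduce to `f = s − (1 − t/t_max)` when `E = H = 0`, recover `f = s`
exactly at `t = t_max` in that neutral case, be monotone (increasing in E,
decreasing in H) at every age, start high with a near-zero time gradient
when `E ≫ H`, and start below zero with a steep gradient when `H > E`.
The test suite asserts exactly these constraints; the floor at −1 only
bounds values that are already behaviourally equivalent (below threshold).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `theta` | 0.1 | saccade threshold on activation (dimensionless) |
| `t_max` | 20 s | spatial-memory horizon; full IOR decay time |
| `eps_match` | 0.02 rad | spatial tolerance when matching stimuli to memory |
| `w_R, w_G, w_B, w_mov` | (1, 0, 1, 0) | bottom-up filter weights in [0, 1] |
| `E_row, H_row` | zeros | per-class task excitation/inhibition (2×4 matrix) |
| `duration` | 500 s | trial length |
| `control_rate` | 10 Hz | perception–action steps per simulated second |
| `saccade_duration` | 0.2 s | clock charge per saccade (motorised-head scale) |
| `lattice_factor` | 8 | peri-foveal block-averaging factor |
| `s_min` | 0.05 | segmentation floor for stimulus extraction |
| `d_min` | 0.2 | dominance needed for a foveal colour class |
| `min_coverage` | 0.5 | foveal coverage below which a fixation is UNDEFINED |

`theta`, `t_max` and the 500-s protocol are the standard validation
settings of the architecture.  The matching tolerance is required once gaze
coordinates are continuous; 0.02 rad is ≈ 5 px at the default focal length,
well below the inter-ball spacing and above the sub-pixel localisation
error of the centroid estimator.  Re-saccading within the tolerance
*refreshes* the existing memory entry (decay restarts) instead of
duplicating it.  Equidistant matches resolve to the older entry, keeping
inhibition maximally conservative.  The control loop's behaviour is
rate-stable: per-class saccade counts change by well under 20 % between
5 Hz and 20 Hz control rates (tested).

Top-down magnitudes for the built-in condition battery default to
`E = H = 0.2`.  With balanced two-colour weights the maximum attainable
salience is 0.5, and any `E ≥ 0.4` lifts an excited, fully salient ball
above threshold at age zero — i.e. abolishes its inhibition of return
entirely.  0.2 biases the competition strongly while keeping IOR
functional for every class.

## The synthetic world

The standard scene places four balls (two red, two blue) on a horizontal
arc: sensor 480×240, focal length 240 px, fovea 14 px, arc span 0.525 rad,
elevation −0.05 rad, per-ball angular radius drawn from U(0.027, 0.042) rad
and colour saturation from U(0.55, 1.0), positions jittered by ±0.012 rad.
The geometry is sized so that (a) every ball is fully visible whichever
ball is fixated, (b) at least one clean lattice column separates adjacent
discs, so segmentation can never merge two balls, and (c) every ball covers
more than half the fovea when centred, so fixations classify.

Radius and saturation ranges matter beyond realism.  A noise-free
threshold system whose targets all share one salience value falls into a
degenerate limit cycle: every ball recovers from IOR with an identical
period, saccades bunch into fixed clusters, and the entire dwell time of
the run lands on a single ball.  Physical systems escape this through
sensor noise; the simulator, which is deliberately deterministic within a
trial, escapes it through heterogeneity of the scene itself — balls of
different apparent size and saturation have different salience, hence
different recovery periods, and the fixation pattern disperses.  Seeded
scene jitter is the *only* source of run-to-run variation: identical
configurations reproduce identical runs bit for bit, and behavioural
comparisons therefore replicate across seeds (paired by scene) rather than
across repeated runs.

What the generator does **not** emulate: pixel noise, motion blur, depth
and vergence, lighting gradients, occlusion, textured or non-circular
objects, and the hardware colour bias of physical camera pipelines (at
equal weights the simulator is colour-neutral by construction, and a test
asserts this).  Passing behavioural tests here show the *architecture's*
signatures — IOR timing, perseveration without memory, weight and task
biases — not robustness to real sensor data.

## Numerical choices

* Rendering is aliasing-free by definition (a pixel takes the disc colour
  iff its centre is inside the projected disc), making frames and hence
  whole trials bit-reproducible.
* Stimulus positions are salience-weighted centroids of connected
  components (4-connectivity, `s > s_min`), mapped back to full-resolution
  coordinates.  Against the exact projection this localises an isolated
  ball to ≈ 1 px, i.e. ≈ 0.004 rad — comfortably inside `eps_match`.
* Stimuli are ordered by descending salience with (row, column) tie-break;
  threshold selection takes the maximum activation with earliest-record
  tie-break.  All ties are therefore deterministic.
* For static scenes the trial loop caches the rendered frame and extracted
  stimuli per pose; with an unchanged pose and scene the frame is
  bit-identical and the movement filter reads zero, so recomputation would
  be a no-op.  Timing and results are unaffected.
* Degenerate inputs: an empty scene yields an empty stimulus list and no
  saccades; an all-background fovea classifies UNDEFINED; all-zero
  saliency weights are rejected (undefined normalisation); memory entries
  older than `t_max` must be pruned before evaluation and are never
  silently clamped.

## Known limitations

* The run total of saccades is *crossing-limited*: each ball is refixated
  shortly after its activation recrosses the threshold, so the total
  saccade count is the sum of per-ball recovery rates.  Inhibiting one
  class therefore lowers the run total by that class's deficit instead of
  redirecting those saccades to other targets; redirection would require a
  saturated regime (some candidate always above threshold), which a
  desk-scale 10 Hz loop with sub-second saccades does not enter.  The
  replication tests document this as a measured property.
* Fixation-duration statistics remain lumpier than those of noisy physical
  systems, because within a trial the simulator is exactly deterministic.
* A distractor of high intrinsic salience captures an overriding saccade;
  the peri-foveal task-based dampening that biological systems appear to
  use is not modelled.
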