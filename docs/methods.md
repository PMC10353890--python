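# Methods

`flycourt` analyses the light-protocol courtship experiment: groups of eight
male *Drosophila* in 26-mm circular arenas (ROIs), filmed at 15 frames/s
under a low → high → low illuminance schedule (120 s at 0.4 klx, 120 s at
18 klx, 120 s at 0.4 klx), with courtship behaviours — chasing, wing
extension, chaining — scored as presence/absence per 10-s interval and
summed into a 0–12 *total score* per 2-min epoch.  Because no videos are
bundled, the package carries an agent-based simulator whose output every
downstream stage is validated against.

## The arena simulator

The simulator is a discrete-time (1/15 s) agent model in a disc of radius
13 mm.  It is deliberately phenomenological: its purpose is to produce
trajectories whose *interaction structure* (who chases whom, when, and for
how long) is known exactly, so the detectors can be scored against ground
truth.  The model:

* **Free walking.** A fly alternates walk bouts and pauses (two-state
  Markov process; pause rate 0.5 s⁻¹, resume rate 1.0 s⁻¹, giving roughly
  two-thirds time moving).  While walking it moves at `base_speed`
  (4 mm/s) with heading diffusion (`turn_noise` 1.5 rad/√s).  Near the rim
  it wall-follows: the heading relaxes toward the tangent with a slight
  inward bias, which is both what real flies do and the only arc geometry a
  pursuer can hold.  A walking fly veers away from a conspecific closer
  than 3.5 mm in its frontal half-plane — non-courting flies avoid
  collisions, and without this the null condition would be full of
  accidental "following" that no detector could reject.
* **Chases.** Each fly initiates a chase with per-second probability
  `chase_rate(I)`, a logistic function of log-illuminance centred near
  3.5 klx (steepest between 2 and 6 klx) rising from ~0.002 s⁻¹ at
  0.4 klx to ~0.25 s⁻¹ at 18 klx.  The nearest free fly within 10 mm
  becomes the target; the target flees (straighter heading, wider wall
  arcs) while the chaser steers toward it — toward the trailing slot
  3 mm behind it during the approach — with a capped turn rate
  (10 rad/s) and a speed controller that settles the gap at
  `follow_spacing` (3 mm) using the target's line-of-sight recession
  speed as reference, up to `chase_speed` (8 mm/s) and never below
  2.2 mm/s (a courting pursuer does not stall).  If the gap encroaches
  below the follow spacing the pursuer veers tangentially (up to 45°),
  circling rather than colliding.  Contact (gap ≤ 3.5 mm) starts the
  chase clock; the chase ends after 1 s plus an exponential tail of mean
  1 s (mean 2 s overall — the floor keeps generated events above the
  detector's 1-s resolution).  A pursuit that fails to make contact
  within 4 s is abandoned and never logged.
* **Chains.** An ongoing chase recruits a further fly with per-second
  probability `chain_rate` (0.25): the nearest free fly steers in behind
  the line's tail and, on contact, extends the single-file line; each
  recruitment extends the chase by 2 s.  Ground truth logs a chain
  segment per constant-membership period (line size ≥ 3) and a chase
  event for *every* follower→predecessor pair, since each consecutive
  pair is a genuine pursuit.
* **Solid bodies.** No two flies may approach beyond a body-core
  separation (2.2 mm; 1.8 mm within a pursuit pair).  Total overlap is
  unphysical and would also make identities unresolvable in video, so the
  renderer's output would no longer define a well-posed tracking problem.

Every stochastic decision draws from one `numpy` generator seeded from
`SimParams.seed`, so simulation is a pure function of its parameters.

The paper-facing defaults (8 flies, 13-mm radius, 15 frames/s, the
low/high/low schedule, the 2–6 klx rise of the dose-response curve) are the
experiment's stated conditions; the kinematic constants (speeds, durations,
spacings, rates) are this package's model choices — the source experiment
reports no fly kinematics — chosen once to give realistic-looking activity
at plausible *Drosophila* walking speeds.

**What the simulator does not emulate:** body articulation (wing extension
is not generated, and therefore not detectable from simulated video),
females (mixed-sex arenas exist only as parameter presets), pheromones or
internal state, lighting changes in the rendered image, camera distortion,
or occlusion by the arena wall.  Tests passing on simulated video therefore
demonstrate the *pipeline's* correctness on a known-truth world, not
performance on any particular real recording.

## Rendering and tracking

Frames are grayscale: a light background, a dark ring at the ROI wall, and
one dark anti-aliased ellipse per fly (2.5 × 1.2 mm) oriented along its
displacement, plus Gaussian sensor noise (σ = 2 grey levels).

Detection subtracts a per-pixel temporal background — the 90th percentile
of brightness over the first 150 frames.  A high percentile, not the
median, because flies are dark and a fly that pauses inside the background
window would be absorbed into a median model and become invisible.  Pixels
darker than the background by more than 3 × (1.4826·MAD) of the residual
noise are foreground; connected components inside the ROI disc above a
minimum area are blobs.  When fewer blobs than flies are found, oversized
blobs (and the largest blobs up to the deficit — two strongly overlapped
flies can stay under the area criterion) are flagged as merge candidates
and carry their pixel coordinates.

Linking maintains one state per identity (position, exponentially smoothed
velocity, missed-frame count).  Each frame: identities claim their nearest
blob within a gate (the displacement of a 50 mm/s fly in one frame,
widening with consecutive misses up to 5); a blob claimed by several
identities is split by k-means on its own pixels, seeded at the claimants'
constant-velocity predictions.  Two-fly merges are resolved
order-preservingly along the blob axis when the pair moves in tandem (a
chaser does not teleport past its leader) and by prediction when the two
motion states differ (a walker passing a paused fly); velocity memory is
frozen (not updated from split centroids) during merges, and the centroid
is blended with the prediction, so crossings resolve by motion continuity.
Remaining identities and candidates are matched by a gated Hungarian
assignment on predicted positions; unmatched identities coast at their
prediction and are marked invalid.  Positions are reported in mm relative
to the ROI centre (x right, y up), frames from 0, time = frame/rate.

Scale calibration fits the arena-wall circle with a Hough transform on the
image edges; mm/px = known diameter / fitted pixel diameter.

## Interactograms and event detection

The interactogram is the boolean tensor `(A, B, frame)` of centroid
proximity, true iff the distance is *strictly less than* 3.75 mm (the
criterion that best captures chasing between centroids at this arena
scale); frames where either track is invalid are false.  It is symmetric
with a false diagonal, and it equals a brute-force pairwise computation by
construction (tested against an independent double loop).

A per-frame **directed pursuit predicate** underlies both detectors: chaser
→ target holds when the pair is in proximity, both move at ≥ 2 mm/s
(smoothed over 3 frames), the chaser's displacement heading is within 60°
of the bearing to the target, and the target is the chaser's nearest fly
inside that heading cone (tolerance 0.5 mm) — a chaser pursues the closest
fly ahead of it, which suppresses pairings across a crowd and between
non-consecutive members of a follow-line.  Dropouts shorter than 0.3 s are
bridged (never across tracking gaps); maximal runs of at least 1 s become
chase events.

Chains are searched in the directed pursuit graph: per frame, disjoint
simple directed paths of ≥ 4 flies (follower → … → leader; the
exhaustive search is exact for ≤ 8 flies and handles "wheels").  Candidate
frames are stitched while the member set overlaps ≥ 50% frame-to-frame,
several concurrent lines are tracked independently, and an event must last
≥ 1 s and be *mobile*: every member's mean speed while part of the line
must meet the 2 mm/s criterion.  The event reports the longest observed
member list, leader first.

All thresholds live in `InteractionParams` and are tunable; the defaults
above are the package's operational definition of behaviours that the
source experiment scored by eye.

## Kinematics

Per fly: distance travelled (sum of displacements over steps with both
endpoints valid), mean speed (distance / valid-step time), and % time
moving (smoothed speed ≥ 1 mm/s over a 0.2-s boxcar; steps across tracking
gaps enter neither numerator nor denominator).  Flies with fewer than two
valid frames are excluded with a warning.  The moving threshold and
smoothing window are package choices, exposed as parameters.

## Interval scoring and statistics

`score_intervals` marks a behaviour 1 in a 10-s bin iff any event interval
overlaps the bin's scoring window, however briefly; per-epoch sums give the
0–12 total score.  The automated pipeline scores the full bin; an
*alternating* mode consults only the ROI's assigned 5-s half-window of each
interval, for parity with the two-operator live protocol in which paired
ROIs are scored alternately.

`compare_epochs` treats the ROI as the replicate.  Paired design: mean ±
SEM per epoch and two-sided paired t-tests between consecutive epochs.
Multi-group design: one-way ANOVA across epochs, then Bonferroni-corrected
pairwise t-tests; significance tiers at 0.05/0.01/0.001.  Degenerate
paired data have explicit conventions: all differences zero → t = 0,
p = 1; constant non-zero differences → t = ±∞, p = 0 (the generic
routines return NaN there, which is uninformative for saturated scores).

`dose_response` reports mean ± SEM per intensity and the adjacent-level
interval of maximal proportional increase (a rise from zero dominates any
finite ratio); constant scores yield no interval.  `normalize_spectrum`
divides an emission spectrum by its peak, E(λ)/E(peak).

## Song analysis

Synthesis: pulses are exponentially damped sinusoids (carrier 220 Hz,
5 ms decay) at a fixed inter-pulse interval; sine song is a pure tone with
5-ms cosine ramps; optional white noise at a stated SNR (noise RMS =
10^(−SNR/20)/√2 relative to a unit tone).

Segmentation band-passes 100–500 Hz for pulses and 100–200 Hz for sine,
takes a rectification + zero-phase low-pass envelope, and thresholds at the
envelope median + 6 × (1.4826·MAD) — all noise-relative, so the
segmentation is invariant to amplitude scaling.  Pulses are envelope peaks
above threshold with ≥ 5 ms spacing and a prominence requirement (ripple
riding on a sustained hum — sine song lies inside the pulse band — has
height but no prominence).  Pulses with gaps ≤ 0.1 s form bouts (kept at
≥ 3 pulses).  Sine segments are sustained sine-band envelope runs of
≥ 0.2 s whose own periodogram peaks inside the sine band; the dominant
frequency comes from that periodogram (resolution 1/duration).  A known
limitation of the median-based noise floor: recordings that are mostly hum
(sine song over half the recording) raise the floor and suppress
detection; courtship song is sparse in practice.

`compare_song_stats` reports, per parameter (IPI, pulses/bout, sine
frequency and duration), summary statistics, the Jaccard overlap of the
two value ranges, and a two-sided Mann–Whitney p-value; identical samples
report p = 1 by convention, and parameters absent from either side are
flagged not comparable.

## Problem sizes used in the validation suite

The packaged tests validate at sizes chosen to exercise every code path at
desk scale: the video round trip uses ten 60-s (900-frame) eight-fly
arenas; detector recall/precision uses full 6-min protocol runs; the
light-dependence recovery runs twenty seeded four-ROI experiments tracked
from rendered video at 0.18 mm/px; song recovery sweeps IPIs 20–60 ms and
sine frequencies 110–190 Hz at 10 dB SNR; statistical calibration uses 100
null replicates.  Identity agreement is reported in aggregate across the
ten fixtures, fixed in advance as seeds 1–10.

## Known limitations

* Wing extension cannot be detected from centroid video; it is scored only
  from external annotations (or, in simulation, from ground truth).
* The chase/chain operational definitions are heuristic thresholds on
  centroid kinematics; on real video their precision depends on tracking
  quality, and wall-following non-courtship proximity (prominent in some
  visual mutants) is only partially rejected by the motion and heading
  criteria.
* Sustained two-fly overlap longer than a few seconds (e.g. mounting) will
  eventually defeat identity maintenance; the tracker is built for the
  grazing merges of chasing, not for copulation scoring.
* The simulator's kinematic constants are not fitted to any dataset;
  quantities that depend on them (speeds, % time moving) should not be
  compared numerically against real recordings.
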