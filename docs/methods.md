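# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Ball flight

The ball is a point mass under gravity g = −9.8 m/s². The launch is
solved backward from two constraints: it leaves a port 2.0 m up the front
wall, and its vertical velocity at floor contact is −9 m/s. That gives an
upward launch speed v₀ = √(9² − 2·9.8·2) ≈ 6.47 m/s and a flight time of
≈1.58 s; the horizontal (depth) speed is then fixed (≈3.49 m/s) by
requiring the bounce to land 3.5 m in front of the start position, i.e.
5.5 m from the wall. The bounce is an instantaneous reversal of vertical
velocity scaled by the restitution coefficient (0.65 or 0.85), horizontal
velocity conserved; both ball types share the identical pre-bounce path.
These two constraints under-determine the launch in general — the solved
trajectory is one consistent solution, chosen because it is the unique
ballistic path satisfying both stated boundary conditions.

Positions are sampled from the closed-form piecewise quadratic at 90 Hz
(the motion-capture rate; the eye tracker's native 120 Hz is not used
because all channels are recorded on the 90 Hz grid). Sampling the exact
solution means finite differences of generated trajectories recover
gravity and the post-bounce speeds to discretization error, which the
tests exploit.

One consequence of the physics is that the lively (0.85) ball crosses the
player plane ≈2.9 m up. The generator lets the racquet meet it there; a
human player would more plausibly intercept it early or let it pass.
This does not affect any computed metric, but it is a respect in which
the synthetic kinematics are not human.

## Synthetic gaze, swing, and schedules

The gaze track encodes the canonical interception strategy: fixation on
the launch port, pursuit of the ball at a configurable gain (default
0.95), one predictive saccade landing a configurable lead time (default
300 ms) before the bounce on a spot a few degrees (default 4°) above the
bounce point, the bounce fixation held 250 ms past the bounce, a catch-up
saccade back onto the ball, and post-bounce pursuit. Saccades use a
triangular velocity profile (default peak 300°/s), so their duration is
2·amplitude/peak. The event magnitudes are generator choices — the
strategy's structure is what real data constrain — and were set so that
the injected saccades (≈10–35° here) are comfortably above the detector's
gates; sub-degree microsaccades would not be, and the package makes no
claim about them. Optional white jitter on the gaze angles and
missing-sample runs (validity flag) emulate tracker noise and dropouts.

The swing rests, draws back 0.15 m away from the aim point, then sweeps
along a quarter-sine speed profile that reaches the configured peak
(default 4 m/s) exactly at the contact frame and decelerates mirror-wise
through the follow-through. On intended misses the aim point is offset
0.8 m laterally, which keeps the ball outside the padded collision box on
every frame. Intended hits place the racquet centre on the ball at
contact and deflect the ball, so segmentation sees the same "abrupt
trajectory change" a real collision produces.

Feedback schedules permute round(0.58·n) (low) or round(0.42·n) (high)
'hit' calls and place one probe per sixth of the block, subject to: three
probes after 'hit' calls and three after 'miss' calls, and the running
hit proportion at every probe within one trial's rounding of the block's
nominal rate. Orders are drawn by seeded rejection sampling (cap 10,000
tries; typical acceptance needs a handful). Ball types are a seeded
permutation of round(0.67·n) normal balls. Feedback schedules are seeded
per participant; whether the original study used one fixed order for
everyone is not recoverable from its description.

## Self-report generative model

POF and COF are linear in the 0/1 pressure and feedback indicators plus a
participant random intercept and Gaussian noise; anxiety is linear in the
realized POF, COF and their product. Slope defaults are the study's
reported point estimates (0.46 feedback→POF; −0.12, 0.07, 0.43
pressure/feedback/interaction→COF; 0.18, 0.29, 0.02 POF/COF/product→
anxiety). Ratings are clipped to their scales (0–6, 0–10) as a safety
valve.

Intercepts and variance components are nowhere stated and were chosen
once with two aims: keep the variance decomposition near the reported
marginal/conditional R² pattern (random intercepts dominating), and keep
clipping below ~1% so the generative model stays effectively
linear-Gaussian — a requirement for the package's parameter-recovery
guarantees to be meaningful. The anxiety intercept (1.6, implying a mean
near 3.1 rather than the observed ≈2.5) buys the low clipping rate; with
a mean of 2.5 the floor of the anxiety scale censors enough of the low
tail to attenuate the POF slope measurably. Recovery tests establish that
the analysis code is unbiased *under this generative model*; they cannot
certify behaviour under real-data pathologies (ordinal coarseness,
floor-heavy anxiety distributions, non-Gaussian intercepts).

## Preprocessing

* Positional channels: 2nd-order Butterworth, 10 Hz, forward–backward
  (zero phase; 4th-order effective). The per-pass order is unstated in
  motion-capture convention-land only by omission; 2nd order per pass is
  the common choice. Reflection padding handles the ends; the zero-phase
  time-reversal identity holds away from the padded edges.
* Gaze angles: 3-frame median, then zero-lag 2nd-order Butterworth at
  50 Hz (saccade chain) or 15 Hz (position chain). 50 Hz exceeds the
  45 Hz Nyquist of 90 Hz data, so it is clamped to 0.99 × Nyquist with a
  logged warning — the recorded rate, not the tracker's native rate,
  bounds what the filter can pass. Missing samples split the series;
  each valid run is filtered independently (no interpolation), runs
  shorter than the filter warm-up stay median-filtered only.
* Segmentation: release = first ball displacement; bounce = the
  vertical-velocity sign change nearest the floor; contact = the first
  frame the ball leaves its ballistic prediction by more than 5× the
  running RMS deviation (absolute floor 1 mm), or, for misses, the first
  frame the ball's depth passes the racquet's. The prediction window
  starts three frames after the bounce so the bounce discontinuity
  cannot masquerade as contact.
* Exclusion (assessed over the segmented release-to-contact window):
  missing fraction strictly above 20%, or any contiguous gap strictly
  above 100 ms (at 90 Hz: 10 frames trips it, 9 does not). Excluded
  trials lose their gaze metrics; interception and swing metrics are kept
  and flagged, since they do not depend on the eye channel.
* Winsorization: per condition, values strictly beyond mean ± 3 SD
  (sample SD, computed once on the original data) move to the boundary.

## Event detection

Saccade candidates are contiguous runs with |angular acceleration| above
5× its per-trial median absolute value over non-missing frames (runs
separated by a single frame merge). A candidate is accepted only if gaze
velocity exceeds 40°/s for at least five consecutive frames that are
*also* at least 20% above the ball's angular velocity — the conjunction is
evaluated on the same frames, the stricter reading — and is discarded if
it contains or touches missing data. Boundaries come from the
acceleration extrema: for a fast saccade the acceleration maximum
(before the velocity peak) and minimum (after it) are near-plateaus, so
the onset is the first frame above half the maximum and the offset the
last frame below half the minimum, searched up to 50 ms beyond the
candidate. Zero-phase filtering spreads threshold crossings outward by a
frame or two, which is why the candidate edges themselves are not used.

Fixations use the classic I-DT sweep on the 15 Hz chain: grow a window
while (yaw range + pitch range) ≤ 3°, emit at ≥100 ms, never spanning a
missing sample; a max-pairwise-great-circle dispersion metric is
available behind the `metric` switch. An exhaustive-enumeration oracle in
the test suite certifies the sweep's output exactly. Thresholding uses
absolute acceleration; signed thresholding would drop deceleration-only
candidate fragments and is not what the 5×-median rule is meant for.

## Outcome measures

The bounce fixation is the fixation whose interval contains the bounce
frame, else the latest one ending before it; its pitch is the mean
egocentric (gaze-in-head) pitch over the event and its duration the event
length. Interception is an inclusive sphere-vs-oriented-box test against
the racquet extent inflated by the 20 cm collision pad. Peak swing
velocity is the largest frame-to-frame controller speed over the
foreswing, defined as the contiguous run of frames before contact whose
depth-velocity component (toward the oncoming ball) is positive. An
earlier formulation ("toward the predicted interception point") breaks on
miss trials, where the actual ball position at the pass-by frame lies
nearly a metre lateral of a perfectly ordinary swing; the forward-phase
definition is what the measure means and is robust to lateral aim error.

Error-dependency coding: each trial carries the count of *consecutive*
immediately-preceding 'miss' calls (not the block total), capped at 4 and
reset by any 'hit'; and the most recent probe's anxiety rating carried
forward within the block (missing before the first probe; those rows are
dropped by the error-dependency model). Counts are stored 0-based; any
1-based recode for presentation is left to the caller.

## Models

Linear mixed models are random-intercept fits by REML (statsmodels
MixedLM); inference is Wald with the normal approximation — no
small-sample df correction, a deliberate large-n choice that can make
p-values slightly anti-conservative at 43 groups. Condition factors are
0/1 indicators with low-pressure/low-feedback reference, so main effects
read as simple effects at the reference level of the other factor.

The logistic mixed model is fitted by direct maximization of the
Gauss–Hermite marginal likelihood (31 nodes) over the fixed effects and
log random-intercept SD, with Wald SEs from the inverse numerical
Hessian. This fitter exists because the installed Python ecosystem lacks
a frequentist GLMM: the available variational approximation understates
posterior SDs severalfold and the MAP variant shrinks both slopes and the
intercept variance. The test suite pins the fitter against lme4's
`glmer` on a fixture (coefficients and variance to a few percent, via
Rscript).

Standardized betas are β·SD(x)/SD(y) with full-sample SDs, interactions
standardized from their realized product column. For logistic models
SD(y) is taken on the latent scale, √(var(Xβ) + var_u + π²/3) — a
documented approximation; no standardization convention reproduces the
originally reported logistic standardized betas from their own raw
coefficients, so agreement there is not a target. Marginal and
conditional R² follow the variance-decomposition convention:
var(Xβ̂)/(var(Xβ̂)+var_u+var_e), with var_u added to the numerator for the
conditional version, and π²/3 as var_e for logistic fits. Follow-up
contrasts are paired t-tests on participant cell means with Holm's
step-down adjustment.

`simulate_power(effect, n, ...)` draws replicate studies from the
random-intercept truth with total outcome variance 1 split by the ICC
(default 0.5), observations split evenly over the 2×2 cells (default 24
per participant — six probes by four blocks), converts the standardized
effect to a raw coefficient via β = effect·SD(y)/SD(indicator) with
SD(indicator) = 0.5, refits the condition model per replicate, and
reports the rejection rate of the focal (feedback) coefficient at alpha
with its binomial Monte-Carlo SE. The minimum effect size of interest
defaults to 0.2 ("small" on the r-like scale); it is a parameter, not an
estimate.

## Problem sizes and numerical choices

Defaults used by the test suite and acceptance script: 100 synthetic
trials for event-detection fidelity; 100 replicate studies of 43
participants for parameter recovery; 200 replicates for power at n = 43.
These sizes put the Monte-Carlo error well below the margins being
tested while keeping a full run in minutes on one core. Seeds are
explicit everywhere; identical seeds give bit-identical sessions,
including written files (floats serialized with `%.17g`, parsed with
round-trip precision). Degenerate inputs fail loudly and specifically:
constant outcomes, zero-variance predictors, fewer than two participants,
complete separation, cutoffs at Nyquist, unknown config keys and
out-of-range values each raise a named error; segmentation failures and
over-missing trials flag the recording instead of raising, since a
pipeline must survive a bad trial.

## Known limitations

The head is static and level (quaternion identity), so world and head
frames coincide in generated data; `to_world_angles` handles arbitrary
head orientation and is tested against rotation composition, but the
generator does not exercise head-free geometry. Yaw is not unwrapped
(irrelevant within ±40° here). Pursuit gain, saccade profiles and
self-report noise are stylized; no blink model, no saccadic suppression,
no learning across trials, no serial correlation in self-reports beyond
the random intercept. The elastic ball's contact height is unrealistic
(above). Interception truth in the generator is decided by construction
(aim on / off the ball), so recovered interception rates validate the
geometry test, not human performance.
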