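# Methods

This note documents the models, the numeric conventions, and the design of
the synthetic-data generator — everything a user needs to interpret the
package's output or to audit a disagreement.

## Coordinate and timing conventions

* Pitch is the angle of the body's long axis relative to horizontal,
  nose-up positive, in degrees.  z increases upward; frames are stored
  image-style (`[row, col]`, row 0 on top) and all detector *outputs* use
  `x = col`, `z = (H-1) - row`.
* The `.dlm` dialect is tab-delimited, headerless, eight columns in fixed
  order (time stamp, body x/z, head x/z, pitch, epoch id, animal length).
  The format names fields but no dialect, so one is fixed and documented.
  Floats are written in shortest-round-trip form; read→write is the
  identity.
* Durations are converted to frame counts as `round(ms · rate / 1000)`:
  at 166 Hz the −500…+300 ms bout window is 83 + 1 + 50 = 134 frames, the
  100 ms IBI buffer is 17 frames, and the −250 ms "initial" time point is
  42 frames before the peak.
* Wall-clock time (needed for the zeitgeber-day filter) is reconstructed
  as metadata `start_time` + per-frame time stamp; records are kept when
  the time of day lies in `[light_on, light_off)`.

## Segmentation

Instantaneous speed is the per-frame Euclidean displacement divided by dt,
back-filled at the first frame so the series aligns with the frame count.
Epochs pass QC when longer than 2.5 s with maximum speed above 5 mm/s;
additional plausibility filters (displacement jump, pitch jump) exist but
are off by default and logged when used.  Each maximal run of
supra-threshold speed yields one candidate bout at the run's speed argmax
(earliest frame on ties); candidates whose full window does not fit in the
epoch are dropped, and overlapping windows from distinct runs are all
kept.  Consequently a bout's peak is the maximum of its *run*; a faster
neighboring bout may legitimately appear inside the 800 ms window when
inter-bout gaps are short.

The raw inter-bout gap is measured between the last supra-threshold frame
of one run and the first of the next (the frame-sampled analogue of the
threshold-crossing interval); the IBI duration subtracts a 100 ms buffer
from each end, non-positive results are discarded, and mean IBI pitch is
averaged over the buffered (shortened) interval.  Bout pairs separated by
an additional, window-clipped run yield no IBI, because the gap is not
sub-threshold throughout.

## Kinematics

Angular velocity differentiates pitch smoothed by a centered 11-frame
moving average whose window shrinks symmetrically at the edges (no data is
fabricated; linear series pass through unchanged).  Each first difference
is assigned to its interval midpoint — otherwise the peak time would carry
a +3 ms (half-frame) bias.  Bouts whose mean angular velocity over
[−250, −100] ms is negative ("nose-down start") have their adjusted series
negated; the time of peak angular velocity is the argmax of the
per-timepoint median of the adjusted series across one experimental
repeat's bouts, restricted to the pre-peak steering phase [−250, 0] ms,
and per-repeat values are averaged for reporting.

Trajectory is the tangential displacement angle over peak ± 1 frame
(central stencil — the least biased finite-difference estimate of an
"instantaneous" direction), with the forward sign taken from the bout's
net x displacement so the quantity is invariant to left/right heading.
Features are then pure arithmetic: attack = trajectory − pitch at peak;
steering = pitch at peak − pitch at −250 ms; body/residual split steering
at the time of maximal angular velocity (identity exact by construction);
righting = pitch at +100 ms − pitch at peak.  "Initial" pitch is the
−250 ms value everywhere; the righting regression can be switched to use
the preceding IBI's mean pitch via `righting_initial`.

## Models

* **Bout timing** — quadratic least squares of bout frequency on IBI
  pitch, fitted in the polynomial basis (closed form) and converted to
  (a, b, c) = (sensitivity, baseline posture, base rate); standard errors
  for b and c by the delta method.  The fit uses raw IBIs; 3°-binned
  averages are display-only.
* **Steering** — OLS of pitch at peak speed on trajectory; slope =
  steering gain.
* **Fin–body** — after two selection rules (peak speed ≥ 7 mm/s, then
  exclusion of bouts with steering above the post-speed-filter median
  *and* negative attack angle), bounded nonlinear least squares of attack
  angle on body rotation with the increasing logistic
  a + h/(1+e^(−k(x+b))), h, k > 0; initialization h₀ = data range,
  b₀ = −median(x), k₀ = 4·(range slope)/h₀.  The fin-body ratio is the
  maximal slope k·h/4.  Its variance is computed, per the documented
  convention, as `Vslope = Ek²·Vh + Eh²·Vk + Vk·Vh·(1/4)²` (default
  `as_printed`); a strict delta-method variant placing (1/4)² on all three
  terms is available via `variance_convention = "delta_method"`.  Note the
  as-printed form overstates the variance by ≈16×, which makes the
  reported fin-body CI widths conservative.
* **Righting** — OLS of righting rotation on initial posture; righting
  gain = |slope| (the relation is corrective, hence negative), set point =
  −intercept/slope, its SE by the delta method; a numerically flat slope
  flags the set point as undefined.

Linear and quadratic fits are closed-form (numpy lstsq with analytic
covariance); the test suite cross-checks coefficients, SEs and R² against
statsmodels OLS as an independent oracle.  A logistic fit that fails to
converge raises with full diagnostics (n, x range, starting values) rather
than failing silently.

## Resolution and power

The resampling dataset behind each parameter is the (x, y) point cloud of
its model, with the fin–body selection rules applied up front (the
percentile cutoff is computed once on the full filtered sample, not per
draw).  The sampling unit is the individual bout/IBI; a grouped bootstrap
over epochs exists but is off by default.  CI width is 2·z₀.₉₇₅·SE
(z = 1.959964 from the normal, not t), computed on 20 resamples per N.
Effect sizes impose a fractional offset on the coefficient of interest by
replacing y with the modified model's prediction at the original x plus
each point's original residual — so offset 0 is the identity and refitting
the fully modified dataset scales the coefficient exactly.  For the
fin–body parameter the sigmoid height h is scaled (k·h/4 scales by the
same factor), and its features are computed with the time of maximal
angular velocity fixed at −40 ms rather than estimated per repeat
(`DatasetAnalysis.features_fixed_mav`).  Cohen's d uses 200 bootstrap
draws per dataset and the SD of all 400 values; the outer loop repeats 20×
per (offset, N) cell.  All randomness flows from one master seed through
per-cell `default_rng([seed, tag, …])` streams, so results are
reproducible regardless of execution order; a failed fit inside a repeat
is redrawn at most 5 times, then aborts that repeat with a logged reason.

## Detection

The background model is a per-pixel temporal median over a frame sample
(robust to the transiently present animal).  The absolute difference is
thresholded and labeled with 8-connectivity; exactly one component within
the area bounds is required (zero → `no_animal`, several →
`multiple_animals`, only implausibly sized components →
`size_out_of_bounds`).  The blob is split into two parts by a 1-D
intensity-weighted 2-means along its principal axis: the brighter part is
the head if the mean-intensity ratio exceeds 1.15, else the smaller part
if the area ratio exceeds 1.3, else the frame is rejected as
`parts_unresolved` (a uniform disc has no resolvable parts).  Orientation
is the intensity-weighted principal axis of the whole blob with the nose
direction disambiguated by the head-part centroid; pitch =
atan2(Δz, |Δx|), heading-invariant.  Animal length is the moment-based
major-axis length (4·√λ_max, exact for a uniform ellipse).  The synthetic
renderer draws a trunk ellipse plus a brighter head disc, both centered on
the body axis, so the blob's principal axis equals the posed pitch exactly
and detector accuracy can be asserted to < 1° over ±80°.

## The synthetic generator

The generator emulates what the apparatus records — not hydrodynamics.
Defaults are the study conditions: 166 Hz; peak speeds lognormal with
mean 12.9 and SD 4.9 mm/s; pitch distribution with ≈8.5° mean and ≈15° SD;
sensitivity 0.003 Hz/deg², base rate 1.25 Hz; righting gain 0.18 with set
point 8.5°; fin-body sigmoid k = 0.4 /deg, h = 8° (ratio 0.8) centered at
body rotation −2°; angular-velocity peak 50 ms before peak speed.

Within each epoch, bout timing realizes the parabola directly: after each
bout a target frequency f is drawn from a(p−b)² + c (Gaussian noise,
clipped to [0.3, 8] Hz) at the current pitch, and the next sub-threshold
gap is set to 0.2 s + 1/f − dt, so the buffer-corrected, frame-sampled IBI
measures 1/f without bias.  Peak speeds below 6 mm/s are redrawn: a
sub-threshold "bout" would silently merge two IBIs and contaminate the
timing fit (a detectability floor, lifting the realized mean to
≈13.0 mm/s).  Pitch follows one smooth steering profile per bout (a
truncated-Gaussian-CDF ramp over [−250, 0] ms whose derivative peaks at
−50 ms), so the residual rotation is the profile's unfinished fraction of
the steering rotation rather than independent noise; a smoothstep righting
ramp of −gain·(p_init − set point) + noise follows over [0, +100] ms.
This bout-level feedback also makes the pitch distribution stationary,
with SD set by the steering spread (8.4°) against the righting gain.
Between bouts pitch performs a gentle random walk (0.5°/√s) and the animal
drifts with a slow AR(1) velocity (SD 0.25 mm/s per axis, 1 s correlation
time — slow enough that the drift cannot shift the in-bout speed argmax or
chop a threshold crossing into splinter runs).  Per-frame pitch
measurement noise (0.25°) is added on top.

Attack angle is generated from the realized body rotation through the
sigmoid plus noise (1.5°), and the bout's displacement direction is
trajectory = pitch at peak + attack + thrust noise (1.5°).  Because attack
is *defined* as trajectory − pitch at peak, the steering gain cannot be
dialed independently: it emerges (≈0.91 under defaults) and the generator
records the latent-population regression slope as `steering_gain_true` in
the manifest; a requested gain below the emergent value can be
approximated by calibrating the thrust-noise variance on the pooled latent
sample.  The attack-noise scale and sigmoid placement were chosen so that
bouts with strong steering but negative attack — the artifact class the
fin–body exclusion rule exists to remove — are as rare as they are in real
data; with heavy attack noise the rule becomes strongly selective and
biases the recovered sigmoid upward.

### What passing tests do and do not show

The generator shares the analysis pipeline's definitions of bout, IBI and
feature, so recovery tests validate segmentation, alignment, feature
arithmetic and fitting — not the biological adequacy of the models.  Real
data differ in ways the generator deliberately omits: angular velocity
dependence of bout timing (the residual variance behind the modest real
R²), residual rotations decorrelated from steering, multi-animal occupancy
and tracking artifacts, non-Gaussian noise.  Synthetic R² values are
correspondingly higher than observed ones.  Recovery accuracy at
n = 10,000 bouts is sub-percent for the linear parameters (steering gain,
righting gain, set point, sensitivity); the fin–body ratio carries a small
positive bias (≈ +4%, from the exclusion rule acting on measurement-noise
negative attacks) plus intrinsic estimator dispersion of ≈5% — it is the
most data-hungry parameter, consistent with its 4-coefficient nonlinear
fit, and the resolution module reproduces that ranking.

## Problem sizes

The test suite and acceptance script use a 10,000-bout corpus (5 repeats ×
2,000 bouts, ≈3 s to generate and ≈1 s to analyze) for parameter
recovery, 33-pose detector sweeps at ±80°, CI-width curves over
N ∈ {400 … 4000} with 20 resamples, and the full 200-draw/20-repeat
Cohen's d protocol at N = 2,000 — sizes at which every assertion is stable
yet the whole suite runs in well under a minute of compute.

## Known limitations

* The detector assumes a single dark-field animal (brighter than
  background after subtraction) with a brighter/denser head; it reports
  pitch in (−90°, 90°] and cannot represent upside-down postures.
* The exact pixel-count thresholds that define an epoch during
  acquisition, and the acquisition-side quality-control filters, are
  rig-specific; they are exposed as configuration rather than fixed.
* The fin–body exclusion rule's percentile cutoff is computed after the
  speed filter; the reverse order would give a slightly different cutoff.
* `Vslope` defaults to the documented (as-printed) formula, which is not
  a delta-method variance; switch to `delta_method` for calibrated CIs.
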