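# Methods

This note records the models, estimators, and numerical choices behind
`nemaswim`, the assumptions they rest on, and the limits of what the
synthetic benchmarks demonstrate.

## Posture representation

An animal at one frame is an ordered centerline (tail first) with per-point
half-widths.  All measures consume the **curvature kymograph**: signed,
dimensionless curvature `k_hat = kappa * L` evaluated at the midpoints of 12
equally long body segments, one column per frame.  Dimensionless curvature
makes every downstream score independent of animal size and magnification;
a body lying on a circle of radius `L/2` scores `|k_hat| = 2` everywhere.

Sign convention: image coordinates, y axis down; positive `k_hat` is
clockwise turning of the tangent (traversed tail to head) as seen on
screen.  An animal bent clockwise from tail to head scores positive
asymmetry.  Head–tail relabeling flips row order and curvature sign, which
induces the identities used in the tests (asymmetry sign flip, reverse
percentage `p -> 100 - p`).

### Curvature estimator

Curvature is the derivative of the tangent direction with respect to arc
length.  The input polyline is resampled onto a fine arc-uniform grid via a
parametric cubic spline (not-a-knot ends; linear fallback below 4 points;
consecutive duplicates within 1e-9 px collapsed first), and at each segment
midpoint the curvature is the least-squares slope of the unwrapped tangent
angle against arc length over a window of one body segment (`L/12`,
configurable as `window_fraction`).

Two deliberate choices here:

* **Window length `L/12`.**  A local fit over an arc `w·L` attenuates a
  sinusoidal curvature profile of wave number `n` by roughly
  `sinc(pi n w)`: at `w = 1/4` that is 0.78 at `n = 1.5` and 0.47 at
  `n = 2.5`, which would destroy amplitude-based measures (stretch,
  attenuation).  One segment (`w = 1/12`) keeps the factor at 0.99 / 0.93
  and matches the 12-sector discretization: each score summarizes one body
  sector.
* **Tangent-slope regression rather than an algebraic circle fit.**  The
  two agree on circles and gentle arcs (asserted in the tests), but the
  algebraic (Kasa) circle fit collapses to a spurious small circle on
  S-shaped windows at curvature inflections, producing order-10 outliers
  where the true curvature crosses zero.  The regression form is the
  definition itself and has no such failure mode.

## Short-time 2D spectral analysis

Swimming is a single-mode traveling wave `k_hat ~ A sin(2π(f_s s + f_t t))`
whose parameters drift over seconds, so a whole-trial transform is
unsuitable.  At every frame the 12 × W curvature patch (W ∈ {32, 40, 48,
56, 64} frames, Hann-tapered along time only — 12 samples are too few to
taper) is zero-padded to a fixed 64 × 256 raster and the five magnitude
spectra are averaged pointwise.  Since the map is real, the full-plane
magnitude is centro-symmetric and only the `f_s >= 0` half-plane is kept;
with `s` oriented tail→head, forward (head-initiated) waves give
`f_t* > 0`, reverse waves `f_t* < 0`.

The dominant mode is the grid argmax over `f_s > 0` (the `f_s = 0` line
carries the postural DC/asymmetry component, not the wave), refined by
per-axis parabolic interpolation.  A mode is *defined* only when the peak
bin carries at least `eps_mode` of the total non-DC spectral energy
(`peak² >= eps_mode · Σ|X|²`).  The default is 0.005: on the padded,
averaged spectrum a clean wave concentrates ≥ ~0.015 of the energy in the
peak even when fully attenuated along the body, while spatio-temporal white
noise stays near 0.001, so 0.005 separates the two with at least 3× margin
on either side.  Windows overlapping trial edges use their valid
truncation; a window with under 25% valid frames (or fewer than 8) is
undefined; invalid frames are zero-filled inside windows.

**Resolution limit.**  With 12 spatial samples the Dirichlet main lobe is
about 2 cycles/body wide.  At the joint extreme of very slow (~0.25 Hz) and
very long (~0.5 cycles/body) waves, the wave and its centro-symmetric
mirror fall inside one main lobe and interfere; the temporal-frequency bias
there (~8%) exceeds the 5% recovery target no matter the refinement.  The
frequency-recovery property test documents and excludes that corner; all
benchmark grids (f ≥ 0.5 Hz, n ≥ 0.7) are clear of it.

### Stroke clock

The stroke duration is `D(t) = fps / |f_t*(t)|` frames; the *two-stroke
window* is the half-open interval `[t - D, t + D)` clipped to the trial.
Frames without a defined mode inherit the nearest defined duration
(nearest-neighbor gap fill) so windowed measures remain computable across
brief undefined runs; such frames still never enter summaries.  A window is
usable when at least half its frames are valid.

## The ten measures

* **Wave initiation rate** `= 60·|f_t*|` waves/min (direction ignored).
* **Body wave number** `= |f_s*|` cycles/body.
* **Asymmetry**: mean of `k_hat` over all segments and valid frames of the
  two-stroke window.  Group statistics aggregate `|median|` per animal.
* **Stretch**: max over segments of that segment's curvature range within
  the window.
* **Attenuation**: `100·(1 - R_tail/R_head)` where each `R` is the largest
  per-segment range within the tail quarter (rows 1–3) or head quarter
  (rows 10–12); undefined when `R_head < 0.1` (motionless head); negative
  values (amplification) occur in reverse swimming.
* **Range estimation**: when the stroke frequency is known, per-segment
  ranges are taken on a least-squares harmonic reconstruction of the
  segment's series (constant + first + second harmonic at the stroke
  frequency).  Undulation is single-mode, so the reconstruction preserves
  the true range, while a raw max − min is maximally sensitive to per-frame
  estimation noise from pixel-level tracking (it inflates by roughly twice
  the noise amplitude).  Without a defined frequency the raw range is used;
  on noiseless input both coincide.
* **Reverse swimming**: frame is reverse iff `f_t* < 0`; summarized as the
  percentage of defined frames.
* **Curling**: postural, not spectral.  Curl score = the smaller, over the
  two extremities, of the distance from the tip to the nearest centerline
  point at arc separation ≥ `L/2`; curled iff score ≤ `L/3` (inclusive),
  which fires on "O" shapes, "6" shapes and postures in between.
* **Travel speed**: body centers (arc-length-weighted centroids) are
  averaged over one stroke on each side of the frame; speed is the distance
  between the two averaged centers divided by their actual mean-frame
  separation, in body lengths/s.  Stroke-averaging cancels the lateral
  back-and-forth of undulation (verified: undulation + drift reads the same
  as pure drift within 5%); normalizing by the realized frame separation
  removes the integer-window bias that otherwise distorts short strokes.
* **Brush stroke**: the body tube (centerline ± half-width, round caps) is
  rasterized on a normalized canvas (body length = 128 raster units,
  fractional-center disc stamping so thin tubes are covered without bias);
  value = union of pixels painted during the two-stroke window divided by
  the static body's pixels, minus one.  Postures are sub-frame interpolated
  toward the next frame while painting, so the union estimates the
  continuously swept region and is frame-rate independent.  The series is
  smoothed with a two-stroke moving average.
* **Activity index** `= brush / (2D/fps)` body areas per second.

Continuous measures are summarized by the temporal median and the 10–90
percentiles (linear interpolation between order statistics); medians are
used because dynamic within-trial changes skew means away from the typical
behavior.

## Tracking

Segmentation: local standard-deviation filter (kernel ≈ animal width,
default 5 px) as an edge/noise gate, Otsu threshold of the smoothed
intensity image with a contrast guard (foreground must separate from
background by ≥ 4 within-class SDs, and carry above-average edge energy) so
featureless noise yields zero detections; per component, the closed outline,
the inner Euclidean distance transform, and the skeleton ridge ordered
end-to-end (double BFS) give the centerline; half-widths are the transform
values on the ridge; ridge ends are extended to the intensity tips.

Frame-to-frame tracking is a deformable model.  Anchors — body points whose
local 7×7 intensity patch is unchanged between consecutive frames — are
pinned (at 18 fps at least two such stationary points essentially always
exist; fewer than two triggers a fresh segmentation match and a flag).  The
remaining control points relax for 12 iterations under (i) an image force:
ascent of the signed distance field of the thresholded body (positive ridge
inside, negative outside), projected onto the local normal because the
ridge carries no tangential information and unprojected pull drags tips
inward; (ii) curvature smoothness (pull toward neighbor midpoints, weight
0.25); (iii) arc-length-preserving chain springs (weight 0.5).  Steps scale
with body length (the distance field's gradient has unit slope regardless
of scale) and anneal over iterations so the fit first catches the motion,
then settles without oscillation; displacements are clipped to the motion
envelope (0.25 body lengths per frame at 18 fps, rescaled for other rates).
Tips are then trimmed/regrown against the signed distance with a tolerance
band toward a slowly adapting per-animal length target (EMA, rate 0.02),
which keeps the arc-length registration of the curvature rows stable.
Finally the polyline is projected onto a least-squares cubic spline with
interior knots every 0.1 body lengths: a scale-free cap on degrees of
freedom that removes pixel-grid jitter (which would otherwise alias into
the 12-segment curvature samples) while representing postures up to about
three wave cycles.

Every 20 frames a fresh segmentation is merged: candidates matched by
centroid, oriented by whole-body distance (endpoint distances alone are
ambiguous for U-shaped postures), and combined pointwise keeping whichever
candidate has deeper distance-transform support, bounding tracker drift.

Contacts: per frame, each animal's motion envelope is the union of discs of
the displacement bound around its body points; pairs with intersecting
envelopes whose fitted bodies come within touching distance (sum of local
half-widths + 2 px) are flagged on both animals, and a body approaching
itself at arc separation ≥ 0.3 L within touching distance flags
self-overlap through the same path.  Flagged frames are excluded from all
measures but can be re-validated through manual overrides.

Quality: a frame is flagged when its body length falls more than two robust
standard deviations (1.4826·MAD, floored at 0.2% of the median) below the
animal's whole-video median length.  Plain mean/SD cannot implement the
intent: a block of collapsed frames larger than ~20% inflates the SD past
its own deviation and can never be flagged, so the robust form is required
for the rule to reject heavily corrupted tracks.  An animal with more than
20% flagged frames (strictly) is rejected; manual overrides can flip
individual frames or the verdict.  If a first measures pass finds reverse
swimming above 50%, the head/tail labels are swapped and measures
recomputed (`SwimTrial.fit` does this automatically).

Tracking is deterministic: identical video and parameters give identical
output; no random state is used anywhere in the tracker.

## Synthetic swimmers

Ground truth is synthesized in curvature space — the measures are defined
on the kymograph, so generated parameter values are exact by construction;
hydrodynamic realism is explicitly out of scope.  A scenario specifies
temporal frequency `f`, wave number `n`, amplitude `A`, constant curvature
bias `c`, attenuation `alpha`, reverse and curl episodes, drift, body size,
frame rate, duration, rendering noise, and a mandatory seed.

* **Amplitude envelope** `e(s) = 1 - alpha·g(s)` with `g = 1` on the tail
  quarter, `0` on the head quarter, linear between.  The quarter plateaus
  make the tail/head quarter amplitude ratio exactly `1 - alpha`, so the
  generated attenuation ground truth is exactly `100·alpha`%, including the
  0% and 100% anchor cases (a linear-in-`s` envelope would leave the tail
  quarter with ~21% of the head amplitude at `alpha = 1` and could not
  produce the 100% anchor).
* **Reversals** negate the phase velocity inside episodes with the phase
  kept continuous across boundaries, so reversal onsets do not splatter the
  spectrum.
* **Curls** override the wave: "O" is constant `k_hat = 2π` (a closed
  circle); "6" is a straight tail half with the head half turned through
  1.8π, putting the tip well within `L/3` of the mid-body.
* **Postures** are reconstructed by integrating the tangent angle over arc
  length (midpoint curvatures interpolated with an interior spline, flat
  extension beyond the end midpoints, linear fallback for discontinuous
  curl profiles) and placed by arc-centroid plus drift.
* **Rendering**: dark tubes (gray 60) on light background (gray 200),
  supersampled 2× for anti-aliasing, ~1 px Gaussian blur, seeded additive
  Gaussian noise (default sigma 5, contrast-to-noise ≈ 28).  Identical
  scenario and seed give bit-identical video.

Defaults describe a vigorous young adult at the standard operating point:
1.5 Hz, 1.5 waves/body, amplitude 3, 30 s at 18 frames/s, 100 px body at
0.02 mm/px.

What the synthetic benchmarks do **not** show: performance on real videos —
real worms have non-sinusoidal waveforms, three-dimensional excursions out
of the focal plane, size/pigmentation variation, illumination gradients,
and debris; occluding contacts here are only flagged, never resolved
through identity-preserving reasoning.  The benchmarks pin the estimator
chain (rendering → tracking → measures) under controlled conditions, which
is the part of the system that can be validated without curated recordings.

## Benchmarks and their operating points

* Parameter-recovery grid: f ∈ {0.5, 1, 2, 3} Hz × n ∈ {0.7, 1.5, 2.5} ×
  alpha ∈ {0, 0.5, 1} × reverse ∈ {0, 20%}, 30 s at 18 fps, measures from
  ground-truth centerlines; recovery within 5% (rate, speed), 0.1 (wave
  number), 7 points (attenuation), 3 points (reverse), 10% (stretch).
* Tracking benchmark: five swimmers, 30 s, 512², contrast-to-noise ≈ 47;
  ≥ 95% of frames within 1 px mean centerline deviation, no rejections.
* Invariance: one scenario fitted after (i) 2× uniform scaling of
  ground-truth centerlines, (ii) re-rendering at 0.01 vs 0.005 mm/px
  (200 vs 400 px bodies, 15 s) with full tracking, (iii) 18 → 36 fps.
  Drift bounds: 2% relative; 2 points for percentage-valued measures;
  0.05 absolute for values of magnitude ≤ 1 (the asymmetry median, a mean
  curvature near 0.5, fluctuates by ~0.02 between independently tracked
  renders).  The re-render pair uses 200/400 px bodies because at 100 px
  the body tapers below one pixel at the tips and tip localization noise
  dominates range-based measures; the scale pair was chosen to test the
  pipeline in its intended operating regime, not at its failure floor.

## Known limitations

* The spectral mode is single-wave by design; multi-frequency motion
  (e.g. simultaneous head oscillation and body wave) reports only the
  dominant component.
* Wave numbers below ~0.5 cycles/body are at the spatial resolution floor
  of a 12-segment discretization.
* Curl detection is geometric and threshold-based (`L/3`, inclusive);
  boundary postures between "6" and an open "C" may differ from human
  judgment.
* The tracker does not preserve identity through full-body occlusions;
  contact frames are flagged and excluded instead.
* Attenuation is undefined (not zero) when the head quarter is motionless
  (`R_head < 0.1`), e.g. full quiescence.
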