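# Methods

This note documents the models, conventions and design choices behind
pawkit: what the synthetic study generator emulates, how footfalls are
recovered from pressure frames, how the kinetic and pain statistics are
defined, and where the genuinely open choices were settled.

## Study structure

The package targets a two-period crossover: four cats, each undergoing
one unilateral forelimb onychectomy per period (left/right and
treatment order counterbalanced across animals), with a washout between
periods. Per cat × period the schedule is:

* two baseline kinetic sessions at −48 h and −24 h;
* six post-operative kinetic sessions at 6, 24, 30, 48, 54 and 72 h;
* ten walking and ten landing trials per kinetic session;
* ordinal 0–5 pain scores at 3, 6, 12, 24, 30, 36, 48, 54, 60, 72 h
  plus the two baseline sessions.

Walkway hardware constants: 2.4 m × 0.5 m mat, 4 sensels/cm² (0.5 cm
pitch), 60 Hz frame rate, 50 psi calibrated range, 0.7 m jump-down
platform.

## Synthetic-data generator

The generator exists so that every downstream stage is testable against
known ground truth; it emulates the statistical structure of the study,
not musculoskeletal mechanics.

**Force curves.** Each footfall's force–time curve is a half-sine (or
triangular) pulse — both families have closed-form integrals, so the
ground-truth vertical impulse is exact (`2/π·P·T` and `½·P·T`). Curves
are sampled at frame midpoints; the worst-case peak underestimate from
sampling, `max|f′|·Δt/2`, is stored per footfall as the discretisation
tolerance used by the extraction oracle.

**Walking.** A lateral-sequence walk (limb phases LF 0.00, RH 0.25,
RF 0.50, LH 0.75, duty factor 0.6) advances along the mat at a velocity
drawn log-normally around the 0.6 m/s target (spread ≈0.18 m/s) with a
small planted acceleration (SD 0.06 m/s²) — deliberately wide enough
that a substantial fraction of trials violates the ±0.2 m/s / ±0.1 m/s²
validity bounds and exercises the QC stage. Hind paws register on the
most recently vacated ipsilateral fore print (2 cm behind), which is
also what the limb classifier exploits. A run whose instantaneous
velocity falls below 0.12 m/s stalls: no further strides are emitted
and the trial is marked invalid (cats refusing to cross the mat is an
observed behaviour post-surgery). Forelimb walking peaks default to
55 %BW (hind 40 %BW) with 10% per-footfall and 8% per-trial
multiplicative variation.

**Lameness.** The operated forelimb's peak is multiplied by a lameness
factor in [0, 1], specified per treatment arm per post-op timepoint.
Defaults were derived once from published feline onychectomy landing
data, as the ratio of post-operative to baseline operated-limb landing
PVF (control ≈0.56–0.73, treated ≈0.68–0.82). The contralateral
forelimb compensates by `1 + gain·(1 − lameness)` with gain 0.3 walking
/ 0.4 landing, matching the ≈14% rise in non-operated landing PVF seen
in the same data.

**Landing.** Both forelimbs strike at a frame-aligned instant; with a
configurable probability the strikes are staggered by 1–2 whole frames
(baseline probability 0.25, rising by 0.7·(1 − lameness), which puts
the post-operative control arm near 0.49 — the baseline ≈24% and
post-op ≈49% measurable-delay proportions observed in cats). When lame,
the operated limb strikes later in 85% of staggered landings. Hind
limbs follow the first forelimb by `0.11 + 0.08·(1 − lameness)` s
(rounded to frames). The forelimb landing peak defaults to 187 %BW so
that simulated baselines sit in the published 185–190 %BW band; all
strike times are snapped to the 60 Hz frame grid so extracted timing
equals planted timing exactly.

**Rendering.** A footfall deposits its curve through a normalised 2-D
Gaussian footprint (σ = 0.8 cm, ≈3×3 cm blob), so summed mat force
during a single-limb contact equals the limb curve exactly before
noise. Per-sensel sensor noise is zero-clipped Gaussian with SD 0.01 N
(≈0.1% of a walking forelimb's peak sensel load — commercial calibrated
mats are quiet; the value is configurable). Full recordings are
rendered lazily per trial from the trial's stored seed; a full study at
frame level would be ≈50 GB, while the ground-truth level simulation is
instant.

**Pain scores.** A latent post-surgical intensity `A·exp(−t/τ)` plus
*bounded* uniform noise (±0.3) is thresholded at fixed cutpoints
(0.5, 1.5, …, 4.5). Control defaults A = 1.9, τ = 40 h; treated
A = 0.8, τ = 10 h; a period multiplier on τ (1.4 / 0.6) gives the two
periods distinct recovery speeds, so the design's period × time
interaction is exercised. Because the noise is bounded, the default latent can never
reach the score-3 cutpoint: no simulated score exceeds 2, and the
rescue-analgesia trigger (score ≥ 4) never fires under defaults.

What the generator does **not** emulate: continuous force development
within a step (double peaks, braking/propulsion), centre-of-pressure
motion within a paw, correlated day effects, observer drift in pain
scoring, or any pharmacokinetics. Passing tests therefore demonstrate
that the pipeline recovers what it assumes about real data — discrete
limb contacts with smooth unimodal force pulses — not that it is robust
to arbitrarily pathological recordings.

## Footfall extraction

* Detection threshold: 2× the per-sensel noise SD, estimated robustly
  as the 99th percentile of (sub-sampled) sensel values — footprints
  occupy well under 1% of sensel-frames. Fallback: 0.5% of the global
  maximum for noise-free recordings.
* Connectivity: 8-neighbourhood in space with footprint overlap
  (within one sensel) across consecutive frames — a single 26-connected
  labelling of the thresholded (t, row, col) array. Components whose
  time-overlapping centroids are closer than 2 cm are merged (pads of
  one paw); components spanning fewer than 3 frames, or fewer than
  15 voxels, or peaking below 4× threshold are rejected as noise.
* Quantification: per-frame force is summed over the event's spatial
  footprint dilated by 2 sensels, with the mean background level of
  quiet sensels subtracted *without* re-clipping — quiet sensels then
  contribute zero on average, capturing the sub-threshold tails of the
  pressure blob without the positive bias of summing clipped noise.
* Timing: strike = first frame at ≥ max(threshold, 5% of event peak);
  lift = end of the last such frame. No sub-frame interpolation, so
  contact times are integer multiples of 1/60 s (the instrument's true
  granularity). The impulse integrates the curve trapezoidally with one
  silent frame appended at each end (equivalent to midpoint-rule
  accuracy for the interior).
* Limb labels: left/right from lateral position versus the path axis
  (rows increase to the cat's left when travelling along +x); walking
  fore/hind from stride registration (an event within 6 cm of an
  earlier same-side print is a hind paw); on landings the earliest two
  strikes are forelimbs. Events with lateral separation under one
  sensel pitch are flagged unclassified.

Against the generator, extraction recovers limb labels for >99% of
walking footfalls, PVF within the per-curve frame-discretisation bound,
and VI within 2% relative.

## Trial QC

Velocity is the least-squares slope of strike x-position versus strike
time; acceleration is the trend of consecutive segment velocities.
Walking trials are valid at |v − target| ≤ 0.2 m/s, |a| ≤ 0.1 m/s² and
lateral path deviation < 10 cm (the study's original straightness
criterion was visual; the 10 cm bound is this package's proxy). The
five valid trials closest to the target velocity are analysed, ties
broken by smaller |a| then original order; fewer than five returns all
with a warning. The target is per-cat configurable, with a
"comfortable-speed" mode substituting the cat's median velocity,
because cats routinely self-select faster speeds (≈0.9 m/s is typical).
Landing validity requires forelimbs first and forward travel; the
acceleration bound is applied to walking only.

## Kinetic statistics

SI is computed **per trial and then averaged** within a session (mean
of ratios). This is the convention consistent with published session
tables in this literature, whose SI columns cannot be recovered by
applying the SI formula to the tabulated mean forces; it is also the
only choice that yields a within-session SI standard deviation. `Tf1f2` is signed, positive when the operated limb strikes
later (delayed loading); "measurable" means ≥ 1 frame. Baseline
adjustment subtracts the mean of the two baseline sessions separately
per cat and period (a single missing baseline session is used alone and
flagged). Washout readiness checks whether current mean PVF lies within
the 95% t-interval of the pooled baseline trial-level PVFs, inclusive
at the edges; the variance source (trial-level spread) is this
package's choice, as is the inclusive boundary.

## Crossover statistics

**Pain AUC** is the trapezoidal area of (score − baseline) versus time,
anchored at (0 h, Δ=0); negative increments count unless explicitly
floored. Arms are compared by a paired t-test and by the exact Wilcoxon
signed-rank obtained from complete enumeration of all 2ⁿ sign
assignments (mid-ranks for ties); one-sided toward the observed
direction, since the four-subject floor 1/16 = 0.063 is attainable only
one-sided.

**Ordinal pain model.** Proportional odds with fixed effects treatment,
period, time (hours/72), time × treatment and period × time. The
default fit is marginal, subject-clustered (GEE); a random-intercept
maximum-likelihood fit (25-node Gauss–Hermite quadrature) is provided
but at four subjects the marginal fit is the stabler default. From the
fit, the probability that the score sits at its baseline level is
evaluated over a fine time grid per period × arm; the first time that
probability reaches 0.5 (linear interpolation) is the LD50-like
crossing time, reported as "< t_min" when the curve starts above 0.5.
Non-convergence or divergence (|β| blowing up under separation) raises
an explicit `EstimationError` rather than returning garbage.

**Kinetic mixed model.** Baseline-subtracted session summaries are
modelled with treatment, time (categorical) and treatment × time fixed
effects, a random intercept per cat, and a cat × period variance
component. The latter is essential: baseline subtraction shares one
baseline-estimation error across all six timepoints of a period, and
treatment varies at the cat × period level, so omitting that component
inflates the treatment-term type-I error severalfold (observed ≈27%
versus nominal 5% in null simulations). An unstructured 6×6 residual
covariance over the repeated times would be the fullest specification,
but it is not reliably estimable with four subjects; the cat and
cat × period intercepts provide the compound-symmetric approximation
the data can support.

Inference: in this balanced two-treatment crossover the mixed-model
test of the average treatment difference reduces exactly to a paired
comparison of per-cat treatment means; the overall treatment p-value is
computed in that form (t with n_cats − 1 degrees of freedom), which
null simulations show is calibrated (≈4–6% rejection at α = 0.05),
whereas Wald-normal inference is badly anticonservative and REML-based
t(3) inference overcorrects. Per-timepoint treatment contrasts use the
REML fit with containment-style subplot degrees of freedom
(n − rank(X) − (cells − 1)) and a Tukey studentized-range adjustment
over the full set of 12 treatment × time cell means — conservative for
the six reported within-time comparisons, which is the right direction
at this sample size. Dunnett time-versus-baseline comparisons are
evaluated inside the single-arm mixed model: the six t statistics'
joint null is multivariate t with the estimated contrast correlation,
integrated by seeded Monte Carlo (default 10⁵ draws), and adjusted
p-values are floored at the raw p.

**NTf1f2** uses Pearson's chi-square without continuity correction
(configurable) on the 2×2 table with the post-operative row first, so
an odds ratio above 1 means landings stagger more after surgery; a zero
cell triggers the Haldane +0.5 correction for the odds ratio only.

α = 0.05 throughout. The pain (10-point) and kinetic (6-point) time
grids are kept as separate schedules.

## Numerical and engineering conventions

* Forces are stored in newtons; %BW normalisation uses g = 9.80665.
* Coordinates: origin at the mat corner, x along travel, cm units,
  frames 0-based; lift time is the end of the last contact frame, so
  contact time = lift − strike is a frame multiple.
* All randomness flows from integer seeds through
  `numpy.random.default_rng`; a study spawns per-trial seeds via
  `SeedSequence`, so any single trial re-renders byte-identically.
* The pipeline report rounds floats to 6 significant decimals and
  serialises with sorted keys: identical config + seed ⇒ identical
  bytes.
* Simulation sizes used in the validation suite: 100 rendered trials
  for the extraction oracle, 50 landings for parameter recovery, 200
  null replicates for calibration — sizes chosen to keep the whole
  suite comfortably reproducible on a laptop while leaving Monte-Carlo
  margins well clear of the tolerances tested.

## Known limitations

* With four subjects the ordinal model's Wald tests are approximate;
  treat its p-values as descriptive. The exact enumeration test and
  the paired reduction of the kinetic model are the defensible
  inferential anchors at this n.
* The limb classifier's stride-registration rule assumes near-registered
  walking (true of cats); gaits without hind-on-fore registration would
  need the window widened or a sequence-based classifier.
* Hindlimb kinetics beyond strike timing are deliberately out of scope
  (hindlimb loading is not a useful forelimb-pain readout); so are
  contact-area and centre-of-pressure analytics and import of
  proprietary vendor binary formats.
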