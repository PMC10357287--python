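# Methods

This note records how `iliorisk` measures, models and simulates — the
conventions, the tunable parameters and why their defaults are what
they are, and what the synthetic data do and do not establish.

## Centerline representation and tortuosity

A vessel is an ordered 3D polyline (mm, puncture site → aortoiliac
bifurcation) with a lumen cross-section (diameter, area, perimeter) at
every point.  Readers never reorder points; missing area/perimeter are
imputed under a circular idealization and flagged.

**Resampling and smoothing.** Before curve detection the polyline is
resampled at uniform arc-length spacing (default 1 mm) and smoothed
with a symmetric moving average (default window 5 mm, truncated
symmetrically near the ends so the endpoints never move and straight
lines are fixed points).  A moving average is not idempotent: a second
pass keeps rounding a bend's apex by ~0.1–0.2 mm.  This is well below
CT voxel scale and is accepted; the stability test bounds it at
0.25 mm.

**Turning angle.** The angle at a point is the deviation from straight
— the angle between the chord arriving from 10 mm of arc length before
the point and the chord leaving to 10 mm after (probe offset default
10 mm, interpolated on the polyline).  0° is straight; larger is
sharper.  This convention matches the reported magnitudes (sums of
110–165° over 3–6 curves); interior angles would not.

**Curve detection.** A curve is a maximal contiguous region where the
smoothed turning-angle profile exceeds a 5° noise floor, containing one
local maximum; maxima closer than 20 mm of arc length are one anatomic
bend (the larger peak is kept).  Curves with peaks under `min_angle`
(default 15°) are discarded.  Detection runs on the smoothed profile
for noise robustness, but smoothing (and an apex falling between
samples) biases the chord-probe peak angle low by up to ~12%, so the
pipeline re-measures each peak on the *original* polyline by sweeping
the continuous turning angle over ±2 mm around the detected peak
(0.25 mm grid) and keeping the maximum; `min_angle` is applied to the
refined value, with detection at 0.75·`min_angle` so borderline curves
are not lost before refinement.  On sharp planar elbows this recovers
the constructed angle to well under 2°.

**Profile quantities.** NOC is the curve count; SOA sums the refined
peak angles (sub-threshold wiggles are not counted); the mean
inter-curve distance is the mean arc-length gap between consecutive
peaks (absent with fewer than two curves); true length is the polyline
arc length of the analyzed segment, ideal length the straight chord
between its endpoints (between the puncture/bifurcation landmarks when
given), and IFT = (true/ideal − 1) × 100.  The lumen summary (MLD,
minimal area/perimeter, mean diameter) is taken on the *original*
sections, never the resampled ones, so measured minima are reported
exactly.  Reversing the point order, rigid motions, and uniform scaling
behave as expected (tested invariances).

## Plaques and the free lumen

Calcification categories: I — plaque occupies under half of both the
wall perimeter and the lumen cross-section; II — at least half the
perimeter only; III — at least half the lumen only; IV — both; "half"
counts as at least half.  Category ≥ III is the high-risk indicator.

Wall position is discretized to three classes relative to the bend's
outward bulge: `inner_wall` (on the bulge/tip), `outer_wall` (the wall
opposite the bulge) and `circumferential`.  Re-aligning to the free
lumen moves centerline points along the bend's bulge axis by the
centroid shift of the free-lumen area — a circular segment of the
plaque's depth cut from a circular lumen — tapering linearly over 5 mm
at the span edges; lumen diameters inside the span shrink by the plaque
thickness.  Consequences, each tested: circumferential plaques produce
no shift; `outer_wall` plaques sharpen the measured angle (positive
delta), `inner_wall` smooth it; |delta| grows with thickness and, at
fixed thickness, with 1/diameter; for plaques up to 30% of the lumen
radius the angle change stays within ~10% of the angle.  The 10% figure
is an emergent bound verified at simulator scale, not a clamp.  The
centroid-shift magnitude, taper length and probe offset are documented
constants in `plaque.py`.

The risk pipeline measures tortuosity on the wall-aligned centerline
and reports the free-lumen adjustment separately through
`poc_angle_effect`; both views are available to callers.

## Risk score and rule model

CSI = SOA × NOC / MLD; SFAR = sheath outer diameter / MLD (the outer
diameter must be supplied in mm; a French-size lookup table of typical
outer diameters is provided for convenience).  The default rule model
evaluates SFAR > 1.00 then CSI > 100, both strict, so boundary values
are low risk; the first satisfied rule classifies and is recorded as
the triggering step.  Quadrants: QI (both at or under threshold), QII
(SFAR only), QIII (both), QIV (CSI only).  NOC enters as an integer for
a patient; fractional values are accepted only for group-mean
arithmetic.

## Cohort statistics

* Confusion metrics are computed in exact rational arithmetic
  (`fractions.Fraction`) and rounded to one decimal of a percent only
  for display; zero-denominator metrics are undefined, never zero.
* The ROC area is the pairwise concordance probability with ties
  counting ½ (midranks); its 95% CI uses the DeLong structural-
  components variance.  The operating point scans midpoints between
  adjacent distinct scores plus ±∞ for maximal accuracy, breaking ties
  toward higher sensitivity, then lower threshold.
* Logistic fits use the binomial GLM (IRLS, tolerance 1e-8) from
  statsmodels with AIC = deviance + 2·parameters.  Rank-deficient
  designs raise an error naming the redundant column; non-convergence
  or runaway estimates raise an error naming the most extreme feature
  (typical of perfect separation).
* Variable selection is greedy forward minimum-AIC from an
  intercept-only start, candidates pre-screened by univariate p < 0.05
  (Welch t-test or Mann-Whitney for continuous variables; chi-square
  with a Fisher fallback for binary).  Ties break alphabetically; the
  search stops when no addition lowers the AIC.  A single null
  candidate survives screening-free addition only when its chance
  deviance gain exceeds 2 (probability ≈ 15.7%).
* Propensity matching: scores from a logistic fit on the requested
  covariates (constant covariates are dropped); cases processed in
  descending score order, each taking up to `ratio` (default 2) nearest
  unused controls within the caliper (default 0.10 on the propensity
  scale; a logit-SD convention is available).  Unmatched cases are
  dropped and reported; balance is reported as standardized mean
  differences before/after.  The no-reuse and caliper invariants are
  asserted on every run.
* The threshold tree is exhaustive binary Gini partitioning to depth 2
  over midpoints of each feature, leaves labelled by majority, emitted
  as an ordered rule list (subtrees whose leaves agree are collapsed
  first; the flattening is exact for rule-list-shaped trees, which the
  two-step model is).
* The calibration slope refits the outcome on logit(p); optimism is
  estimated by refitting the recalibration on 200 seeded bootstrap
  resamples and measuring the slope shrinkage back on the original
  data.

## The simulator

The generator emulates the study conditions the package is tested
under.  Two latent anatomy strata: normal — NOC = 2 + Poisson(1.4),
per-curve angle Gamma with mean 110/3.4 ≈ 32.4° (shape 16), MLD normal
(6.8, 1.0) mm; high-risk — NOC = 2 + Poisson(3.6), angle mean
165/5.6 ≈ 29.5°, MLD (5.6, 0.8) mm; 20% of patients draw from the
high-risk stratum.  Angles are clipped to 18–85° so every planted curve
is detectable above the 15° reporting threshold; MLD is floored at
3.0 mm.  Segment lengths scale with an ideal-length draw of
N(205, 13) mm.  Vessels are straight runs (30–55 mm, whole mm so elbow
vertices land on sample points) joined at sharp planar elbows whose
planes rotate randomly about the vessel axis; 0.03 mm Gaussian jitter
is added to coordinates.  A Gaussian stenotic dip placed on a grid
point makes the planted MLD the exact minimum of the diameter profile.
Sheath outer diameters draw from N(5.9, 0.6) mm clipped to 4.0–7.5 mm,
straddling SFAR = 1 at the configured lumen sizes.  Plaques occur with
probability 0.7; their lumen fraction exceeds ½ with probability 0.31
(normal) or 0.48 (high-risk), reproducing roughly 22% vs 34% category
≥ III.

Outcomes are Bernoulli draws from a logistic mechanism on the
**pipeline-measured** features — SOA, NOC, MLD, SFAR > 1, category
≥ III — never the latent draws.  Coefficients (per degree 0.02, per
curve 0.45, per mm −0.60, indicators 0.70 and 0.50) encode the
directions of the multivariable associations; their magnitudes are
generator configuration, not clinical estimates.  The intercept is
calibrated by root-finding on a 100,000-draw latent sample so the mean
probability equals the target incidence (default 7.2%); at n = 10,000
the realized cohort incidence lands within 1 percentage point.
Complication types are assigned from the reported distribution
(dissection 36%, perforation 25%, pseudoaneurysm 19.8%,
stenosis/thrombosis/embolism/ischemia 16.3%, AV fistula 2.9%).
Reproducibility: patient *i* uses the substream
`SeedSequence(seed, spawn_key=(1, i))`, so any patient regenerates
bit-exactly in isolation.

**What the simulator does not emulate.** Real centerlines curve
continuously rather than bending at sharp vertices; measured angles are
therefore probe-offset-dependent in reality in a way the planted
geometry hides.  Simulated IFT (~6–20%) runs lower than clinical
means because the inter-curve segments are straight.  Plaque
composition, imaging noise, partial-volume effects and the correlation
structure between anatomy and clinical covariates are out of scope.
Consequently, passing tests establish the correctness of the
measurement and modelling machinery and the internal consistency of
the score — not the clinical discrimination figures, which require
patient CT data.

## Planted-rule identifiability

The tree-recovery experiment labels points by "SFAR > 1 or CSI > 100"
with empty margin gaps of 0.05 / 5 around the thresholds.  Margins
alone do not identify the thresholds: a Gini split at a gap's *edge*,
absorbing neighbours that are positive through the other rule,
separates the labels exactly as well as the planted cut, so a greedy
tree recovers the edge on a large share of random draws.  The
experiment therefore adds buffer regions — points just below each gap
are forced negative on the other feature — making the planted rule the
unique optimum; thresholds are then recovered within half the margin
(verified over 20 seeds at n = 2,000).

## Problem sizes and numerical choices

Test and acceptance runs use 200 vessels for geometry recovery, 10,000
patients for incidence calibration and discrimination, 20,000 for
coefficient recovery (signs and 3-standard-error coverage), 2,000 for
threshold recovery, 500 random tables (n ≤ 50) for the concordance
oracle and 200 bootstrap resamples for calibration — sizes at which
each check's sampling error is small against its tolerance.  Angle
tolerances: 2° per curve, 6° on a per-patient SOA (errors accumulate
over up to ~8 curves).  MLD recovery is exact by construction.
Thresholds in the rule model are strict; probability clipping at 1e-12
guards logit transforms; GLM convergence tolerance is 1e-8.

## Known limitations

The curve-detection algorithm reproduces the *behaviour* of the
proprietary imaging tool (three curves on normal anatomy, the reported
angle magnitudes) but cannot be verified against it; published group
means are mutually consistent with several detection conventions.  The
eight alternative regression-equation scores mentioned alongside the
CSI are unspecified and not implemented.  The sample-size formula
behind the validation design is not reconstructible and is out of
scope, as are DICOM ingestion, CT segmentation and clinical-outcome
group comparisons.
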