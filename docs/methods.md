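# Methods

This note records the models the package implements, the conventions
and parameter choices behind them, and what the synthetic-data
generator does and does not emulate.

## Coordinate frame and geometry

All landmark coordinates live in the image frame of a lateral
cephalogram: x grows rightward (anteriorly — the patient faces right),
y grows downward.  The packaged reference coordinates follow this
convention (the nose tip Ap has the largest x, Menton Me the largest
y).  Angles are computed with the atan2 form
`atan2(|cross|, dot)`, which is well conditioned near 0° and 180°
where the arccos form loses half the floating-point precision.

Signed point-to-line distances use 2-D cross products, so signs are
invariant under rigid motions applied to the whole tracing.  Two
clinical conventions are exposed: `anterior_positive` for lines given
cranial→caudal (facial plane N→Po, incisor reference A→Po, esthetic
line Ap→Pom) and `inferior_positive` for lines given
posterior→anterior (palatal plane Spp→Spa).  The measurement engine
always builds lines from ordered landmark pairs that satisfy these
directions anatomically, so the conventions hold automatically.

Line intersection treats |sin| < 1e-9 between unit directions as
parallel and raises rather than returning an ill-conditioned point.

### Constructed landmarks

- **Gnk** (constructed gnathion): intersection of the mandibular plane
  (hT→Me) with the facial plane (N→Po), by a 2×2 linear solve.
- **Xi** (ramus center): in the frame aligned with the Frankfurt
  horizontal (u along P→Or, n perpendicular), Xi is the center of the
  FH-oriented rectangle bounded by the ramal border points —
  u(Xi) = (u(R1)+u(R2))/2, n(Xi) = (n(R3)+n(R4))/2.  The textbook
  definition of Xi ("center of the ramus" via FH-parallel and
  FH-perpendicular constructions through R1–R4) leaves the exact rule
  implicit; this rectangle-center reconstruction reproduces the
  packaged expert Xi to better than 0.05 px, but it remains a
  reconstruction, not a quoted formula.

When a tracing contains manually placed Gnk/Xi, `derive_constructed`
validates them against the geometric construction and keeps the manual
points by default (matching study practice, where examiners place
them); `prefer="constructed"` overrides.

## The 22-item analysis

The measurement rules are not published as formulas anywhere in one
place; they were reconstructed from the classic Downs / Ricketts /
Rakosi / Steiner analyses and validated item by item against the
packaged expert reference of image A.  Every angle item reproduces the
reference analysis within 0.06°, every mm item within 0.08 mm, well
inside measurement noise.  Each `MeasurementDefinition` carries a
provenance status; 21 items are `verified`.  The one exception is the
maxillary/mandibular length ratio: the plausible definition
|Co−Po| / |Co−A| gives 1.159 where the reference analysis reports
1.17, so that item is flagged `reconstructed` — the reference value
may be an average of per-rater ratios rather than the ratio of
averaged lengths, which cannot be decided from mean coordinates alone.

Conventions that matter and reproduce the reference signs:

- facial axis uses the obtuse angle (180° − acute) between Ba–N and
  Pt–Gnk;
- the palatal plane angle is the signed inclination of FH minus that
  of Spp→Spa (negative when the palatal plane dips caudally toward
  anterior);
- incisor inclinations use the acute angle between the incisor axis
  (apex→edge) and A–Po; the inter-incisor angle is the angle between
  the two directed axes.

**Pixel spacing.** Landmark exports carry no physical scale.
`calibrate_spacing` inverts any one mm-valued item against a known
physical value; calibrating on the convexity of point A (3.25 mm)
yields 0.2043 mm/px for image A, and an independent calibration on the
relative mandibular length agrees within 0.2%, which corroborates both
the rules and the spacing.  Image B's spacing is derived by matching
the anatomical S–N distance across the two radiographs.

## Accuracy metrics

Radial errors are Euclidean distances to the reference in mm; the MRE
of a tracing is their arithmetic mean over the 33 landmarks.  SDR uses
the strict inequality d < t (configurable); for continuously
distributed errors the distinction is measure-zero.  The per-landmark
95% confidence intervals use the normal approximation
mean ± 1.96·SD/√n, matching two-decimal table reporting; the CI
method of the original tables is not documented, and a bootstrap can
be substituted by the caller if needed.

## Reliability

ICC(A,k) follows the McGraw–Wong two-way model for absolute agreement
of k averaged raters, computed from the classical ANOVA mean squares.
Negative estimates are reported as computed (band "poor"); a matrix
with zero total variance has no defined ICC and is reported as NaN
("undefined").  Per-landmark matrices are built, by default, with the
pooled (image × axis) coordinate values as targets — with two images
this gives 4 targets × k raters per landmark; a `per_axis` mode keeps
x and y separate.  The pooled layout matches reporting one ICC per
landmark spanning both images, but the original matrix layout behind
such tables is not published, so both interpretations are preserved.
Note the pooled ICC benefits from the large between-target spread of
coordinates across images and axes; it answers "do raters agree in
absolute position", not "how small is rater noise".

## Mixed models and selection

Responses (per-submission MRE in mm; tracing time in minutes) are
modelled as

    y = Xβ + b_subject + ε,   b ~ N(0, σ_b²),  ε ~ N(0, σ²)

with dummy-coded fixed effects and reference levels image A, female,
first order, desktop.  Fitting is maximum likelihood (not REML)
because likelihood-ratio tests of fixed effects are only valid on ML
likelihoods; fits are delegated to statsmodels' MixedLM with a chain
of optimizers, and a fit whose subject variance collapses to the
boundary falls back to the exact OLS-equivalent solution and is
flagged `singular`.  Wald 95% intervals match symmetric reporting.

Selection is two-stage: each candidate effect is screened singly
against the intercept-only model by LRT; screened effects are then
added in order of ascending stage-1 p-value (ties alphabetical), each
kept only if the incremental LRT is significant at 0.05.  The
insertion order is a choice — "add significant effects one at a time"
admits several orderings — and is documented here rather than hidden.

Welch's t-test (heterogeneous variances, Welch–Satterthwaite df) backs
the measurement-level comparison between examiner and expert values.

## The synthetic-data generator

The generator emulates the study conditions end to end and is the
package's test bed; its defaults are the study conditions themselves:

| parameter | default | origin |
|---|---|---|
| students | 161 (108 female) | study cohort |
| submissions | 277 (116 students submit both) | study cohort |
| baseline MRE | 2.04 mm | accuracy-model intercept |
| image B effect | +0.21 mm | accuracy model |
| male effect | −0.24 mm | accuracy model |
| device / order effect on MRE | 0 | no effect found |
| subject intercept SD | 0.3 mm | not reported; chosen plausible |
| residual SD | 0.4 mm | not reported; chosen plausible |
| time intercept | 23.79 min | time model |
| order effect on time | −11.72 min | time model |
| time subject / residual SD | 4 / 3 min | see below |
| per-landmark error profile | cohort per-landmark MRE means | accuracy table |

Placement noise is bivariate normal.  Per-landmark scales are obtained
by inverting the Rayleigh mean (E[r] = σ√(π/2) in the isotropic case)
from the cohort's per-landmark mean radial errors, then rescaled
multiplicatively per submission so that the submission's expected MRE
equals baseline + fixed effects + subject intercept + residual.  This
keeps the relative landmark-difficulty profile (incisal edges easy,
ramal border points hard) while carrying the study's effect structure
exactly.  Anisotropic noise — elongated along a given orientation, as
observed for landmarks on gradually curved surfaces — is available
per landmark via the config (`anisotropy`); the expected radial error
is preserved using the closed form E[r] = √(2/π)·a·E(1 − b²/a²) with
E the complete elliptic integral of the second kind.  Anisotropy is
opt-in because only means and SDs of radial errors are available, not
covariances; the isotropic default reproduces the marginal means,
which is what the downstream metrics consume.

Tracing times use a normal model floored at 1 minute.  The subject and
residual SDs (4 and 3 min) are chosen so the floor is essentially
inactive (<0.5% truncation): the generator must actually draw from the
linear model whose coefficients define the simulation truth, otherwise
"parameter recovery" is ill-posed.  Real tracing times are strongly
right-skewed (cohort median ≈ 12 min against a first-analysis mean of
≈ 24 min); a lognormal variant is available via `time_model`, but no
claim of distributional fidelity is made for either variant.

The crossover design is emulated: each student's tablet image is fixed
by semester parity (8 semesters), the desktop gets the other image,
and device order is randomized per student.  An `exclusion_fixture`
serializes the study together with the standard excludable mix — 16
tracings of a wrong cephalogram, 5 screenshot re-imports, 3 incomplete
tracings, 2 invalid JSON files — which the ingestion rules must filter
down to the 277 valid submissions (9141 landmarks).

What the generator does *not* emulate: real radiographic appearance
and superimpositions (landmark difficulty is imposed, not emergent),
inter-landmark error correlations within a tracing beyond the shared
submission factor, right-skew in per-submission MRE, and drift of
examiner skill across semesters.  Passing closure tests therefore
demonstrates that the pipeline's statistics are correct and calibrated
for data of the assumed structure — not that the assumed structure
exhausts real student data.

## Numerical and procedural choices

- Duplicate submissions are resolved by keeping the earliest per
  (subject, image, device) by first-placement timestamp; stable on
  ties.
- Pseudonyms are 1-based zero-padded rank labels of salted SHA3-256
  digests; equal names map to equal pseudonyms and raw names never
  appear in outputs.
- Reported tables are rounded to two decimals to match conventional
  cephalometric reporting; internal computation is double precision
  throughout.
- Monte Carlo sizes in the validation suite (500 null replicates for
  LRT calibration, 50 studies for effect recovery, 60 for selection
  consistency) were sized to keep Monte Carlo error comfortably below
  the effects being checked.
- Seeds: all generator randomness flows through one
  `numpy.random.default_rng` seeded from the config, making studies
  byte-reproducible; derived seeds stay below 2³¹.

## Known limitations

- The measurement-rule provenance is reconstruction-plus-validation on
  one reference tracing per image; an item could in principle agree on
  the reference by coincidence and disagree elsewhere, though the
  independent two-anchor spacing agreement makes this unlikely.
- ICC confidence intervals and F-tests are not implemented (not needed
  for banded reporting).
- The mixed models assume Gaussian responses; per-submission MRE is
  mildly right-skewed in practice, which ML fixed-effect estimates
  tolerate but which matters for prediction intervals (not provided).
- Tracing-time medians of real cohorts are not reproduced by the
  default normal time model (see above).
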