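# Methods

`phossum` re-implements, as a tested pipeline, the quantitative analysis of
single- and paired-electrode phosphene drawings from epiretinal prosthesis
(Argus II) psychophysics: moment-based shape quantification of binary
drawings, an axon-map decomposition of inter-electrode distances, a
normalization/averaging/transformation scheme, and a regression battery.
Because the clinical drawings are not publicly available, the package ships
a synthetic drawing generator that reproduces the statistical structure the
analysis assumes, so every stage can be validated end to end.

## Shape descriptors

A drawing is an M×N binary raster (x = column, y = row, 0-based).  Connected
regions (8-connectivity, since touchscreen strokes are diagonally adjacent)
are the phosphenes.  For each region we compute raw image moments
M_ij = Σ_x Σ_y x^i y^j I(x,y), from which

- area A = M00,
- centroid (x̄, ȳ) = (M10/M00, M01/M00),
- central second moments μ′20 = M20/M00 − x̄², μ′11 = M11/M00 − x̄ȳ,
  μ′02 = M02/M00 − ȳ², and
- major/minor axis lengths 4·√λ, with λ the eigenvalues of the 2×2
  central-moment matrix [[μ′20, μ′11], [μ′11, μ′02]].

The perimeter approximates the length of the contour polyline through
border-pixel centers using the standard weighted border-count scheme
(weights 1, √2 and (1+√2)/2 for straight, diagonal and corner
configurations, the scheme `skimage.measure.perimeter` implements).  On an
axis-aligned m×n rectangle this equals the exact polyline length
2(m+n)−4, which the tests use as a closed-form oracle.  A single-pixel
region has perimeter 0 (a polyline through one point), and the minor axis of
collinear pixels is 0.

Drawing validation closes 1–2 px stroke gaps with a morphological closing
(Chebyshev ball, radius 1 by default — a cross-shaped footprint fails to
bridge 1-px gaps in 1-px strokes) and fills interiors, so region extraction
sees solid shapes.  Grayscale inputs are binarized at 0.5; values outside
[0, 1] are rejected.  Regions smaller than 10 px are discarded as additional
phosphenes unless small regions appear in at least 50% of the trial set's
drawings; areas are measured after hole filling.  The filter is idempotent.

Mean images translate each trial's drawing (integer pixels) so its center
of mass sits at the trial-averaged center of mass; the shift is decomposed
as a common offset plus an integer offset relative to the first drawing so
that pure integer translations overlay exactly.

## Axon map and distances

Coordinates are retinal microns in a canonical right-eye frame (fovea at the
origin, optic disc toward +x, temporal raphe on −x; left eyes mirrored at
ingest; 288 µm per degree of visual angle by default).  The Argus II array
is a 6×10 grid (rows A–F, columns 1–10) of 200 µm electrodes at 575 µm
pitch, rotated then translated by the placement parameters.

Nerve-fiber bundles follow the spiral family of Jansonius et al. (2009):
in polar coordinates (r, φ) about the optic disc, a bundle entering the disc
at angle φ0 follows φ(r) = φ0 + b(r − r0)^c for r ∈ [r0, r_max], with
b and c smooth tanh functions of φ0 fitted separately for the superior and
inferior hemiretina (constants live in a versioned config dict;
r0 = 4°, r_max = 45°).  Trajectories are clipped where φ would cross ±180°,
so no bundle crosses the temporal raphe.  The family is generated in a
horizontal-raphe frame (disc on the +x axis) and a nasal-side vertical shear
(y ← y + y_od·clip(x/x_od, 0, 1)) lifts the disc to its anatomical elevation
(default (4600, 260) µm) while leaving the temporal half-plane — and hence
the raphe — untouched.  Each polyline runs from the peripheral end toward
the disc, is resampled at a uniform 10 µm arc step, and terminates at the
disc center.

The bundle through an arbitrary point is found by scanning a dense fan of
disc-entry angles (181 seeds per hemifield) and refining the entry angle by
golden-section search; the result passes within a small fraction of the
discretization step of the query point in the modeled region.  One property
of this family worth stating: near the temporal raphe, bundles are the
clipped terminal arcs of arcuate trajectories and arrive at the raphe
steeply rather than asymptotically, so the map's raphe neighborhood looks
fan-like.  The between/along decomposition and the synthetic renderer use
the same bundles, so all downstream constructs remain mutually consistent.

For an electrode pair, roles are assigned by x (larger x = nasal; at equal
x the electrode with larger |y| is temporal).  The reference bundle is the
temporal electrode's axon (the variant that follows the nasal electrode's
axon is selectable).  Then

- between-axon distance = minimum distance from the nasal electrode's
  center to the reference bundle (clamped at the Euclidean separation,
  which discretization at clipped bundle ends could otherwise exceed by
  ~1 µm), and
- along-axon distance = arc length along the reference bundle between the
  temporal electrode's foot point and the between-axon foot point.

This works unchanged for pairs straddling the raphe.  Distances are
validated against a brute-force minimum over the bundle resampled at 1 µm
(within 1% in the acceptance run) and are stable under step refinement.

OCT electrode–retina distances enter as pixel counts converted by the known
electrode diameter: d_µm = d_px · (200 / shadow_width_px).

## Preprocessing

In order: (1) standard-pulse normalization — each descriptor is divided by
the participant's mean descriptor over all of their single-electrode
drawings at the standard pulse (2× threshold, 20 Hz), absorbing drawing
bias; (2) trial averaging per (participant, electrode(s), amplitude,
frequency); (3) power transforms, area^(1/3) and perimeter/axis^(1/2), for
residual normality; (4) outlier removal — a row is dropped if any of its
four transformed descriptors lies more than 2.5 SD from its
within-participant mean (a joint mask, matching a single shared removal
count across analyses; per-descriptor masks are the logged alternative);
applied to single-electrode rows only, as paired analyses had no removals;
(5) z-scoring of predictors across all participants, computed after outlier
removal so removed rows do not influence the scaling.  SDs and z-scores use
the population convention (ddof = 0) throughout.  Paired rows carry the sum
of the matching single-electrode descriptors (same electrodes, the pair's
amplitude, 20 Hz) for the summation analysis; a pair's EFD/ERD is the mean
over its two electrodes, and the paired amplitude is the mean of the two
electrodes' amplitudes.

## Statistics

Statsmodels-style model objects whose `fit()` returns a results object:

- `StandardizedOLS`: OLS on z-scored response and predictors; β is the
  standardized coefficient; the partial correlation uses the
  residualization convention (correlate the residuals of y and of X_j after
  regressing each on the remaining predictors) — numerically identical to
  the t-statistic transform and cross-checked against pingouin in tests.
  Two-sided p-values, Bonferroni-correctable (m defaults to the number of
  predictors and is configurable).
- `SummationRegression`: no-intercept simple regression (slope Σxy/Σx²) of
  a paired descriptor total on the summed single totals; zero predictor
  must imply zero response, hence no intercept.  A slope in (0.5, 1) is
  flagged: paired percepts larger than the average of their single
  counterparts but smaller than their sum.  The pipeline runs it on
  untransformed (normalized) totals so the slope reads directly as the
  summation gain.
- `MixedShapeModel`: linear mixed-effects with a participant random
  intercept (random slopes out of scope); REML by default, refitted by ML
  for information criteria; Powell optimization first, since quasi-Newton
  optimizers can return stale fixed effects at the zero-variance boundary.
  Partial correlations are approximated by t/√(t²+df).
- AIC/BIC from the Gaussian log-likelihood with the ML variance estimate;
  the parameter count includes the intercept and the residual variance, a
  constant convention across compared models so Δ is well defined.  Bands:
  Δ < 2 both supported; 2 ≤ ΔAIC < 7 (2 ≤ ΔBIC < 6) some evidence;
  larger, strong evidence.
- Welch's t from summary statistics: t = (m1 − m2)/√(sem1² + sem2²).  Only
  the t value is reproduced; printed degrees of freedom in the source
  tables do not follow from the summary statistics and are not modeled.
- Q-Q normality: correlation of sorted residuals against normal quantiles
  at Blom plotting positions.

## Synthetic generator

The generator renders latent percept intensities on a 1024×768 raster
(≈26 px/deg, a touchscreen at 76 cm) and binarizes at 0.5.  For an
electrode at eccentricity EFD on bundle arc-position s₀:

    I = exp(−d_perp²/2ρ_eff²) · exp(−d_along²/2λ_eff²)
    ρ_eff = ρ0 · amplitude^a
    λ_eff = max(λ0 · (1 + f·log(freq/20)) · (1 + c·EFD), ρ_eff)

with d_perp the distance from the bundle and d_along the arc offset from
s₀.  The λ floor at ρ encodes that radial current spread is isotropic:
axonal spread only ever adds elongation, and the λ0 → 0 limit is a compact
blob.  Defaults per simulated participant (ρ0 100–180 µm, λ0 600–1100 µm,
a 0.2–0.7, f 0.15–0.45, c 2.5·10⁻⁴/µm, gains 0.58–0.73) are chosen so the
three participants echo the study's qualitative repertoire — blobs/wedges
with a strong amplitude effect, long arcs with a weak one, and a strongly
frequency-modulated drawer — without being fitted to any figure.

Paired stimulation takes the pixelwise maximum of the two intensity fields
after multiplying each percept's spatial scales by √g, g ∈ (0, 1] the
summation gain.  Scaling both spatial scales by √g attenuates each
component's *area* by exactly g (an intensity gain would be destroyed by
binarization), so for non-overlapping percepts the paired area total equals
g times the summed single areas, and the no-intercept slope recovers g;
perimeter and axis totals attenuate by √g.  Overlapping percepts merge into
one connected region — since percepts extend ~1.2λ along their bundles but
only ~1.2ρ across, merging is governed by the between-axon separation,
which is the mechanism the count analysis is designed to detect.  Where
percepts overlap, the union area is sub-additive, so a slope estimated over
a mixed population of merged and distinct pairs sits slightly below g
(≈0.67 for g = 0.7 in the acceptance run).

Drawing noise: a per-participant multiplicative size bias (lognormal,
σ = 0.1) and per-trial integer-pixel centroid jitter (SD 3–4 px).  Noise
off means bias 1 and no jitter; everything is deterministic given the seed.

What the generator does *not* emulate: hand-drawn stroke irregularity,
open contours, drawing-time dynamics (fading, persistence), threshold
psychometrics, and electrode–retina-distance effects (ERD enters the
analysis as a given covariate, zero by default).  Passing recovery tests
therefore shows the pipeline is correct and sensitive under the assumed
statistical structure, not that the structure holds in any particular
patient.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at reduced but
statistically adequate sizes, chosen as the smallest designs at which the
recovery contracts are comfortably identifiable: descriptor oracles on 100
random masks; axonal distances on 200 random pairs against a 1 µm oracle;
gain recovery on ~100 noiseless pairs; effect recovery on ~100 noisy
single-electrode stimulus cells (3 trials each); and the between- vs
along-axon model comparison on 20 replicates of 60 pairs.  Degenerate
inputs are contracts, not silent fallbacks: empty drawings are flagged,
empty trial sets / constant predictors / rank-deficient designs /
zero-variance groups raise, and the optic-disc region rejects bundle
queries.  Bundle polylines use a 10 µm arc step (distance errors are
quadratic in the step and far below the 1% oracle tolerance); rendering
resamples bundles at 5 µm and evaluates intensities only where they can
exceed the binarization threshold.

## Known limitations

- The trajectory family's steep raphe arrivals (above) make near-raphe
  between-axon distances direction-insensitive; this is a property of the
  published parameterization, shared consistently by the distance
  decomposition and the renderer.
- Phosphene matching across trials in paired-mode mean images uses centroid
  rank, which can mismatch when phosphenes cross paths between trials.
- The mixed model supports a single random intercept; crossed or nested
  random effects and random slopes are out of scope.
- The ERD covariate is carried through the design table but the generator
  produces no ERD-dependent structure to recover.
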