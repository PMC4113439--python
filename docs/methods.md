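# Methods

## Index computation

Fundus photographs are 8-bit RGB rasters. Pixel coordinates are 0-based
integers, x rightward, y downward; a pixel `(px, py)` is treated as the
unit square with centre `(px + 0.5, py + 0.5)`. The analysis region is a
closed disk: a pixel belongs to it when its centre lies at Euclidean
distance ≤ diameter/2 from the centre pixel's centre. This inclusion rule
is exact and checkable against brute-force rasterization, which the test
suite does for random centres and diameters.

The disk (default diameter 250 px) is centred on the midpoint of the
fovea–optic-disc segment, rounded to the nearest integer pixel with halves
away from zero. The clinical protocol only requires the region to lie
"between" the two landmarks while avoiding the vessel arcades and the
peripapillary conus; the exact midpoint is this package's convention,
chosen because it is symmetric and reproducible. Landmarks are supplied
externally in a CSV (`eye_id,fovea_x,fovea_y,disc_x,disc_y`); automatic
detection is out of scope. A disk that does not fit entirely inside the
image is a hard geometry error, never silently cropped.

Channel statistics use the raw 0–255 intensities, with no gamma or
white-balance correction: the photographs are assumed to come from one
camera with fixed settings, and the indices are brightness-ratio
constructions precisely so that residual exposure differences cancel. The
standard deviation uses the population divisor n (histogram-summary
semantics); at typical region sizes (~49 000 px) the difference from the
sample divisor is immaterial, but a fixed convention is needed for exact
tests. The median of an even count is the midpoint of the two central
values. No vessel masking is applied inside the region — avoidance is by
placement only.

The indices are computed from the disk-wide channel means (not as per-pixel
indices averaged afterwards):

- TFI-1 = (R − G)/R — undefined when R = 0;
- TFI-2 = R/(R + G + B) — undefined for an all-black region;
- TFI-3 = (R − G)/(R + G + B) = TFI-1 · TFI-2.

All arithmetic is double precision; rounding to 3 decimals happens only in
the human-readable report, never in the CSV outputs.

Consensus grading takes the grade assigned by at least two of the three
raters and raises an error when all three disagree — reported never to
occur in practice, but a silent tie-break would corrupt downstream group
statistics.

## Statistical battery

Spearman correlation is the Pearson correlation of mid-ranks (ties receive
average ranks). The two-sided p-value uses the Student-t approximation
`t = rho·sqrt((n−2)/(1−rho²))` with n−2 degrees of freedom, adequate in the
n ≈ 100 regime this package targets; the unit tests compare it against
exact permutation at small n. `|rho| = 1` reports a sub-machine-floor p
rather than NaN. Floating-point rank noise within 1e-12 of ±1 is snapped
to ±1 so exactly monotone data report an exact coefficient.

The Steel–Dwass (Dwass–Steel–Critchlow–Fligner) all-pairs comparison pools
each pair of groups, assigns mid-ranks, and standardizes the rank sum of
the first group with the tie-corrected variance
`V = n_i n_j/(N(N−1)) · (Σ r² − N(N+1)²/4)`. The familywise-adjusted
p-value refers `|t|·√2` to the studentized range Q(k, ∞) where k is the
total number of groups — the standard large-sample implementation. The
survival function of Q(k, ∞) is evaluated by the classical single-integral
formula on a fixed 256-point Gauss–Legendre grid; this matches
`scipy.stats.studentized_range.sf(·, k, inf)` to better than 1e-12 while
being orders of magnitude faster per call, which makes the 2000-replicate
null simulation in the test suite cheap. With exactly two groups the
procedure reduces analytically to the tie-corrected normal-approximation
rank-sum test.

Small-sample behaviour: the tests include an exhaustive permutation oracle
that enumerates every relabelling of the pooled observations and computes
the exact familywise null distribution of the maximum pairwise statistic.
At group sizes ≤ 5 the asymptotic p deviates from this exact law by up to
~0.1–0.2 in the mid-range (the normal approximation to a coarse discrete
distribution), shrinking rapidly with group size: at 3 × 20 the simulated
familywise type-I error is ~0.03–0.05 at nominal 0.05. The package
deliberately ships only the asymptotic procedure — the regime it is meant
for — and documents the small-sample gap instead of hiding it.

Fleiss kappa and ICC(A,1) follow their defining formulas. The ICC variant
is the single-measurement, absolute-agreement coefficient of the two-way
model, chosen because each measurement session yields one index per eye
and sessions are meant to be interchangeable in value, not merely in
ranking. Degenerate inputs (all ratings in one category, zero total
variance, a vanishing ICC denominator) raise typed errors rather than
returning NaN. No multiple-testing adjustment is applied across the nine
index × outcome correlations; each is reported marginally, and the 0.05
threshold is used only to label significance in reports, never to filter
data.

## Synthetic data

No public dataset of graded tessellated-fundus photographs with matched
choroidal thickness exists, so the package generates its own. The renderer
operationalizes the accepted mechanism of tessellation — melanin in the
RPE/choroid hides the large choroidal vessels; a thin choroid exposes
them — as the simplest model that makes the indices behave correctly:

- a uniform RPE background (default RGB (180, 125, 75), an orange fundus);
- ~14 roughly horizontal sinuous choroidal vessel bands (width 8–18 px,
  redder and darker-green than the background: (200, 70, 60)),
  alpha-blended at opacity 0.8·v for visibility v ∈ [0, 1];
- dark retinal arcade vessels, a bright optic disc and a dark macular
  pigment spot, all drawn strictly outside the analysis disk, as in the
  clinical protocol;
- additive Gaussian sensor noise (SD 2 intensity units), clipped to
  [0, 255] and quantized to 8 bits.

Because the blended mean color moves linearly toward the vessel color as v
grows, the red−green difference rises while the intensity sum falls, so
every index is strictly increasing in v in expectation — verified by
rendering across a visibility grid.

Visibility maps linearly from choroidal thickness:
`v = clamp((ct_hi − ct)/(ct_hi − ct_lo), 0, 1)` with defaults
[ct_lo, ct_hi] = [76, 500] µm, the plausible thickness range of a healthy
young cohort. The true physiological mapping is unknown; linearity is the
minimal monotone choice, and the generator exposes the endpoints and noise
knobs rather than asserting any particular effect size as ground truth.

Cohort covariates emulate a healthy young myopic cohort of 100 right eyes:
age 25.8 ± 3.9 y (range 22–39), axial length 25.3 ± 1.4 mm (22.4–30.4),
both truncated normal; spherical equivalent tied to axial length at
−2.3 D/mm with 1 D scatter, clamped to [−13, 0]; subfoveal choroidal
thickness 261.8 ± 84.9 µm decreasing in axial length, with the linear
coefficient set through the normal-score transform
`rho_pearson = 2·sin(π·rho_s/6)` so the realized Spearman(AL, SFCT) tracks
the configured target (−0.382 by default) up to sampling noise at n = 100;
nasal thickness is the subfoveal value offset by −17.8 µm with 30 µm
scatter. Each eye's RPE background color is additionally jittered
(SD 6 intensity units per channel), representing inter-eye pigmentation
differences that are independent of choroidal thickness; this is what
keeps the index–thickness correlations realistically moderate (about −0.2
to −0.5 at n = 100) instead of near −1.

Grades derive from visibility thresholds (NT below 0.60, WT to 0.76, ST
above), placed so the expected grade split approximates the 57/27/16
proportions of a real validation cohort given the visibility distribution
the thickness model induces. Each of the three simulated raters
independently misgrades by one step with probability 0.115, calibrated so
the expected Fleiss kappa is ≈ 0.67 at n = 100; the middle grade errs up
or down with equal probability. A draw in which all three raters disagree
(no majority) is redrawn from the same per-eye substream — mirroring real
cohorts, where such cases are not observed — keeping generation
deterministic.

Reproducibility: a single master seed spawns one `SeedSequence` substream
per eye plus one for the covariates, so cohorts are bit-identical across
runs and any single eye can be regenerated in isolation. Rendering uses a
float32 buffer (ample headroom for 8-bit output) for speed.

What the simulator does not model: photographic vignetting and optical
blur, fixation and registration variability, real choroidal vessel
morphology, media opacity, and any within-eye spatial gradient of
pigmentation. Passing tests therefore demonstrate that the pipeline
recovers the structure the generative model encodes — monotone index
response, the sign of the index–thickness correlations, rater-agreement
levels — not that the indices are clinically valid on real photographs.

## Problem sizes in the validation suite

The end-to-end suite uses 100-eye cohorts over 50 seeds for correlation
recovery, 10 render seeds per visibility level for monotonicity, 2000
replicates for the null simulation, and exhaustive enumeration (up to
~6 × 10⁴ relabellings per dataset) for the exact Steel–Dwass oracle —
sizes at which every check is stable while the whole suite stays
desk-runnable. The acceptance script re-runs the pipeline at a single
user-supplied seed.
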