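# Methods

## The measurement problem

A particulate intravitreal depot shows up on OCT b-scans as hyperreflective
aggregates in the otherwise dark vitreous.  Three quantities track its fate
over a follow-up of weeks to months: the VIT/RPE relative intensity (bulk
vitreous haze, referenced to the RPE band so it is gain-invariant), the
aggregate load (count, total area, mean area after a physical minimum-area
filter), and the ILM–RNFL co-layer thickness (aggregates that settle on the
retinal surface merge optically with that band).  The pipeline computes all
three per eye per visit and feeds them into nonparametric group statistics
and trend fits against measured drug levels.

## Layer segmentation

The tracer finds four boundaries per column — ILM, outer border of the
ILM–RNFL co-layer, inner and outer RPE — under the assumptions that the
retina is a contiguous bright band, the RPE is the brightest sustained
band, and speckle is multiplicative.

Per column (vectorised across columns):

1. The profile is smoothed with a 7-row moving average.
2. The vitreous background level is the median of the top rows (50 by
   default) and its spread the MAD.  The bright-tissue threshold is
   `background + max(k·MAD, 0.1·(column max − background))` with k = 4;
   the second term keeps the threshold meaningful on noiseless images
   where the MAD vanishes.  Because every term scales with the image,
   segmentation is invariant under global multiplicative intensity
   scaling (covered by a quantified test at ×0.5, ×2, ×10).
3. The RPE anchor is the deepest row whose smoothed intensity is within
   5% of the column maximum.  Taking the *deepest* near-maximum row is
   the tie-break when several bands are comparably bright.
4. The ILM is the first run of ≥ 5 consecutive above-threshold raw rows
   that lies below the last dark gap (≥ 7 consecutive smoothed rows below
   the dark level, halfway between background and threshold) above the
   RPE anchor.  This rule has the behaviour the application needs for
   free: a floating aggregate is bright but has dark vitreous beneath it,
   so it sits above a gap and is skipped; an aggregate resting on the ILM
   has no gap under it and is absorbed into the co-layer, which is exactly
   how such deposits are measured (they are optically indistinguishable
   from the band).
5. The remaining boundaries are midpoint-level crossings of the smoothed
   profile: the RNFL outer border is the first row below the midpoint of
   the band level (median of 10 rows under the ILM) and the inner-retina
   level (25th percentile between ILM and anchor); the RPE borders are
   the corresponding crossings around the anchor against the inner-retina
   and sub-RPE levels.  For a symmetric smoothing window the midpoint
   crossing of a step edge lands exactly on the edge row, which is why
   noiseless phantoms are segmented exactly.  A "first local minimum"
   rule for the RNFL outer border is not well defined on
   piecewise-constant profiles (a plateau has no strict minimum); the
   midpoint crossing reproduces the intended row and degrades gracefully
   under speckle.
6. Each boundary trace is median-filtered across columns (window 15) to
   remove single-column outliers; columns where detection failed are
   interpolated from their neighbours.  A b-scan with more than 30%
   failed columns is rejected (the pipeline counts rejections per eye); a
   uniform image raises a "no retinal band" error.  Depth ordering
   (ILM ≤ RNFL-outer ≤ RPE-inner ≤ RPE-outer) is enforced and an error is
   raised if more than 30% of columns violate it beforehand.

Measured performance (recomputed by `scripts/acceptance.py`): exact on the
noiseless step phantom; mean absolute boundary error ≈ 0.15 rows at
speckle σ = 0.2 (the target is ≤ 2 rows).

## VIT/RPE relative intensity

The vitreous is all pixels above the ILM; the RPE region is the band
between its inner and outer borders; both region means are plain averages
over all masked pixels (saturated pixels are not excluded — nothing is
known about the export's saturation behaviour, and the ratio is the same
either way for the synthetic data).  The per-b-scan ratio is
vit_mean / rpe_mean and the eye value is the unweighted mean of the
per-scan ratios, which is the marker's definition; the pooled alternative
(ratio of pooled means) is available as an option but is not the default.
Rejected b-scans are excluded and the effective n is recorded.

## Aggregate detection and quantification

1. **Denoise**: 3 × 3 median filter — the smallest speckle suppressor that
   removes isolated bright pixels while leaving multi-pixel blob interiors
   untouched.  Window configurable.
2. **Threshold**: median + 3·MAD over the vitreous pixels of the denoised
   scan ("brighter than background" made robust).  k configurable.
3. **Label**: 8-connected components within the vitreous mask (diagonal
   contact joins; 4-connectivity optional).  Labelling is cross-checked
   against an independent BFS flood fill in the tests and the acceptance
   script.
4. **Refine**: the median-of-9 statistic compresses the background MAD, so
   the detection threshold sits only ~2σ above the denoised background and
   raw components carry a halo of adjacent speckle pixels (≈ +14% area).
   Each component is therefore trimmed at the midpoint between the
   vitreous background median and the component's mean intensity; if the
   trim splits a component its largest piece is kept.  With refinement the
   mean per-aggregate area error on planted ellipses is ≈ 1–2%
   (target ≤ 10%) at 2× threshold contrast, and sensitivity is 1.0
   (target ≥ 0.95).
5. **Filter**: components below 500 µm² are discarded.  Under the printed
   3815 µm²/pixel calibration this passes every 1-pixel component; under
   the isotropic 9 µm²/pixel it requires ≥ 56 pixels.  The two
   calibrations are mutually inconsistent by construction (the printed
   ratio conflicts with the 3 µm pitch); the package keeps the printed
   value as the default for fidelity to the published method, treats it as
   an opaque constant, and stamps every result with the calibration used.
   Note the printed constant itself rounds 2906 mm² / 761,856 px =
   3814.37 µm²/px up to 3815; `pixel_area_ratio` returns the exact
   quotient.
6. **Summaries**: count, total area and mean area pooled over the
   session's b-scans; a boolean voxel volume (scan × row × column) rebuilt
   from the retained pixels can be exported as a multi-page TIFF for 3-D
   inspection.

The minimum-area filter is applied per connected component.  Shape or
texture descriptors beyond area and centroid, and tracking of individual
aggregates across visits, are out of scope.

## Longitudinal statistics

Group time series are per-week mean ± sd with eye counts; weeks are never
interpolated.  Distribution is assessed with a one-sample
Kolmogorov–Smirnov test against a normal with the sample's moments;
cohorts are compared with the two-sided Mann–Whitney U (exact p when
n₁+n₂ ≤ 12 and untied, tie-corrected normal approximation with continuity
correction otherwise — measured type-I error 0.047–0.055 at α = 0.05 with
n = 20 per group); within-eye change uses the paired Wilcoxon signed-rank
test with zero differences dropped (exact p for n ≤ 15 untied
differences).  α = 0.05 two-sided throughout, with no multiple-testing
correction, matching the published analysis.  Trend fits are unweighted
OLS, linear or logarithmic (y = a·ln x + b); R² is clipped to [0, 1] and
defined as 0 for constant responses.  Drug correlation reports the OLS fit
of the metric on the drug level plus Pearson's r on ≥ 3 matched weeks.

## Synthetic data

The phantom is a layered step image — vitreous, ILM–RNFL band, inner
retina, RPE band, sub-RPE — with a smooth sinusoidal per-column boundary
undulation (amplitude 4 rows, period 500 columns, random phase) and
unit-mean multiplicative lognormal speckle (σ = 0.2 by default), the
standard first-order OCT speckle approximation.  Unit mean means region
averages equal the configured levels, so the true VIT/RPE ratio is simply
vit_mean / rpe_mean.  Default levels (vitreous 34, ILM–RNFL 170, retina
120, RPE 200, below 40 on an 8-bit-like scale) give the healthy-eye ratio
0.17; study generation rescales the vitreous per group and week.

Aggregates are filled ellipses (aspect 1.5–3, boundary radius modulated by
±15% low-order angular jitter) planted in the vitreous with a ≥ 10-row
dark gap to the ILM and disjoint bounding boxes.  Their intensity is a
controlled multiple (2–3× by default) of the *expected post-denoising
detection threshold*, estimated once per speckle σ by simulating the
median-of-9 lognormal distribution — so detection sensitivity is a designed
experiment, not an accident of parameter choice.

The longitudinal design reproduces the published dynamics
phenomenologically (the study reports observations, not a mechanism):

- relative load λ(w): 1 up to week 1, linear rise to the swelling peak s
  (default 1.5) at week 2, then exp(−k₁·(w−2)) to week 6 (k₁ = 0.5/week)
  and exp(−k₂·(w−6)) after (k₂ = 0.05/week), giving a near-plateau from
  week 12;
- aggregate count and mean size each scale with √λ (so total area ∝ λ and
  the week-2 peak partly reflects larger aggregates, as observed);
- treated-eye VIT/RPE ratio tracks λ between the untreated baseline 0.25
  and the week-2 peak 0.30; untreated hypertensive eyes stay at 0.25 with
  no aggregates; healthy controls at 0.17 (published cohort values, used
  as generator calibration only);
- aggregates settle toward the ILM over time (Beta-distributed depth with
  a week-dependent shape) and the treated co-layer thickens by up to 4
  rows with a saturating time course;
- drug levels decay as D₀·exp(−k_d·w) (D₀ = 80 ng/mL, k_d = 0.3/week)
  with additive Gaussian noise truncated at zero;
- per-eye load heterogeneity is a lognormal factor (sd 0.10); follow-up
  weeks default to {0, 1, 2, 4, 6, 8, 12, 24} with balanced groups.

Everything is a pure function of (parameters, seed); sessions of a study
stream lazily so a full study never needs to sit in memory.

What the generator does *not* emulate: real speckle correlation
structure, motion/registration artifacts between visits, vendor intensity
compression, floater shadows, intraretinal deposits, or attrition-driven
unbalanced eye counts (per-week n is supported but balanced by default).
Passing the recovery suites therefore demonstrates the pipeline's
correctness under the stated statistical model, not clinical-grade
performance on raw device exports.

## Validation checks and problem sizes

The recovery suites run on a scaled phantom (248 × 512 pixels, sessions of
5 b-scans; the step-phantom worked example is 340 × 64) and the dynamics
study on 10 treated eyes × 8 weeks × 5 scans; these sizes give every
estimator comfortably tight sampling error while keeping the whole
validation run at about a minute.  The full device geometry
(496 × 1536 × 61) remains the generator default and is used for the
pixel-accounting check.  The fast decay rate is recovered by a log-linear
fit of the treated group's mean total area over weeks {2, 4, 6} (the fast
segment of the design), and the drug correlation is evaluated at weeks
{1, 4, 8, 24}, the follow-up points at which imaging markers and drug
levels are matched in this monitoring design; the week-2 swelling peak is
a feature of the aggregate curve only, so an all-weeks correlation would
conflate the two processes.

Published regression coefficients from the original cohort (e.g.
y = −0.0002x + 0.2543, R² = 0.4301) are used only as exact-line fixtures
for the fitting code — the raw per-animal data needed to reproduce them do
not exist in public form, and the package makes no claim of matching them
numerically.  Likewise the cohort ratio values 0.30/0.25/0.17 parameterise
the generator rather than serving as targets.

## Known limitations

- The segmentation assumes the RPE is the brightest band and the retina a
  single contiguous band; pathologies that break these assumptions
  (detachment, severe atrophy) are out of scope.
- Only four boundaries are traced; no full multi-layer segmentation.
- Proprietary vendor formats (E2E/VOL) and AVI codec decoding are not
  parsed; the library consumes decoded frames, multi-page TIFFs or PNG
  directories.
- The two-reader reproducibility of the original protocol is emulated as
  a segmentation-parameter perturbation (`reproducibility_check`), which
  probes algorithmic stability, not human inter-rater variability.
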