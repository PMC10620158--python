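# Methods

This note records the models behind each pipeline stage, the parameters
that matter, what the synthetic generators do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Actin line-profile analysis

**Measurement model.** A wound-perpendicular line through a squamous
epithelial sheet crosses the cortical actin band of each successive
cell; the intensity profile is a train of peaks roughly one cell
diameter (~50 µm) apart, superimposed on a slowly varying background
(illumination, out-of-focus light, diffuse cytoplasmic signal). The
quantities of interest are the peak amplitudes by cell rank from the
wound and their ratios to the wound-margin peak, which cancel staining
and illumination scale between animals.

**Baseline.** `correct_baseline` subtracts a morphological opening
(rolling minimum then rolling maximum) with a flat 80 µm window. An
opening is the largest signal below the profile containing no feature
narrower than the window, so peaks narrower than 80 µm are untouched
while constant offsets and ramps are removed exactly; the output is
invariant under adding any constant. The window must exceed the widest
acceptable peak (40 µm); 80 µm — about 1.6 cell diameters — also spans
the inter-peak valleys, which makes the baseline follow the *valley
floor*: any diffuse cortical signal shared by all edges is treated as
background. That is the intended reading of the ratio statistic
(wound-induced accumulation above the resting level).

**Peak detection.** `detect_peaks` keeps interior local maxima
(plateaus resolved to their center sample) whose prominence is at least
`min_prominence` (default 5× a robust noise estimate from the median
absolute successive difference) and whose width at half prominence
falls in [20, 40] µm. The width band is read as an acceptance band on
width-at-half-prominence; alternatives (FWHM, a smoothing window) are
plausible but produce the same behaviour on well-formed profiles. The
implementation rides on `scipy.signal` peak utilities; the test suite
holds it exactly equal to an independent brute-force enumeration
(every local maximum, prominence and width by direct scan) over
hundreds of random profiles.

**Amplitude readout and pre-smoothing.** The amplitude is the
baseline-corrected intensity at the maximum. Sampling a maximum of a
noisy signal is biased upward by the extreme value of the noise across
the peak top, and the bias inflates the margin and submarginal peaks
unequally; `analyze_profile` therefore applies a light Gaussian
smoothing (σ = 2 µm, an order of magnitude below the 20 µm width
floor) after baseline correction and before detection. With it, mean
recovered ratios on 50 noisy synthetic profiles (noise 5% of the
margin amplitude) are within ±0.01 of truth.

**Rank assignment and aggregation.** The first retained peak from the
wound end is the margin peak — the margin cell is nearest the wound by
definition, so no global-maximum search is used; the next three peaks
are cells 1–3, extra peaks are dropped, and absent ranks are marked
missing (never imputed; means use pairwise exclusion). Ratios are
averaged as ratios: lines within a wound, then wounds within an animal.
The expected design (4–8 lines/wound, 1–5 wounds/animal) is enforced as
a warning, not an error.

## Spot assays

**Particle detector.** Difference-of-Gaussians band-pass with
σ_low = max(d_min/4, 1 px) and σ_high = d_max/2, threshold on the
filtered image, connected components, and an equivalent-diameter gate
[d_min, d_max] (defaults 1–6 µm, threshold 20 a.u.). This exposes
exactly two knobs — a size constraint and an intensity threshold — as
a transparent stand-in for interactive plugin-based detection. Because
the filter is linear, rescaling image and threshold together leaves
the result unchanged.

**Nuclei.** Global Otsu threshold on the stain channel, connected
components, area gate (default ≥ 20 µm²). Watershed splitting of
touching nuclei is available but off by default: over-splitting
inflates the denominator of particles-per-nucleus, and the fields this
pipeline targets are sparse enough that fusion is rare.

**Transcription positivity.** Mean label intensity inside each nuclear
mask, thresholded by an exact 1-D Otsu split of the per-nucleus means
(between-class variance maximized over every split of the sorted
values — histogram-free, because with ~10²  values a 256-bin histogram
can park the threshold half a bin inside a mode). The rule is invariant
to affine intensity transforms while the modes remain separable; an
absolute threshold can be supplied for sensitivity analysis. A field
with zero nuclei is an error (the fraction is undefined), and a field
with no intensity contrast between nuclei is scored uniformly positive.

## Closure kinetics

Percent-of-original = `100·A(t)/A(0)` after resampling to every 10th
frame of an 11 s/frame time-lapse; the first measured frame defines
100% and transient values above 100% (wound expansion) are kept. The
initial closure rate is the least-squares slope of percent vs time over
the first 10 min (the window where treatment effects concentrate),
reported in %/min, negative for closing wounds; the curves, not the
scalar, are the primary output. Group summaries align series by
nearest-time matching within half a sampling interval and report mean,
SEM (sd/√n, n − 1 denominator; undefined at n = 1) and an unpaired
two-tailed t test (two groups) or one-way ANOVA (more) at each
timepoint. Per-timepoint p-values are reported unadjusted, matching how
such curves are conventionally annotated; a Holm adjustment across
timepoints is available behind a flag. The experimental unit is one
wound in one animal throughout.

## Statistics

Pooled-variance Student t (Welch behind a flag), fixed-effects one-way
ANOVA, and Tukey–Kramer HSD with p from the studentized range
distribution on (k, N − k). Degenerate inputs are defined rather than
NaN: zero variance with equal means gives t = 0/F = 0, p = 1.
Implementations are written from the definitions, with
`scipy.stats` distributions supplying tail probabilities; the suite
pins them to independent references (scipy's `ttest_ind`, `f_oneway`,
`tukey_hsd`) to 1e-8 and verifies empirical type-I error within ±1.5
percentage points of α = 0.05 under null simulations (≥2000
replicates per test). `tukey_hsd(compute_p=False)` exposes the q
statistic alone so simulations can compare against a critical value
computed once (identical decisions, since the adjusted p is strictly
decreasing in q).

## Synthetic generators

The generators emulate the *measured structure* of the study system,
not its optics:

- **Sheets** are jittered hexagonal tessellations (jitter σ = 5% of
  the 50 µm cell diameter — guarantees near-constant cell size, unlike
  a Voronoi of uniform points) around a central disk wound (default
  0.05 mm², within the studied 0.02–0.125 mm² range). Cell rank is
  breadth-first distance from the margin cells over the Delaunay
  adjacency. Edges are rendered as ~28 µm bands (so that after the
  2 µm PSF blur their width-at-half-prominence lands inside the
  20–40 µm detection band) carrying the amplitude of the deeper cell's
  rank: wound boundary 200, cells 1–3 100/80/60, background 10 a.u.
  Lateral (equal-rank) edges get the background amplitude, since the
  wound-induced signal accumulates on wound-facing edges. The
  background must be small relative to the induced bands for the
  truth bookkeeping to equal what the ratio statistic measures — the
  opening baseline deliberately removes any shared cortical floor.
  Noise is additive Gaussian (default 5 a.u., 2.5% of the margin
  amplitude). Defaults: 16-bit-scale intensities, 0.5 µm/px.
- **Profiles** are peak trains at 50 µm spacing. The default shape is
  a generalized Gaussian of exponent 4 ("compact"): its width at half
  maximum is the nominal FWHM (default 30 µm) but its flanks fall much
  faster than a Gaussian's. This matters: true Gaussians 50 µm apart
  that are wide enough for the 20–40 µm band overlap enough that
  inter-peak saddles bias baseline-corrected amplitudes by >10%,
  which is a property of that surrogate shape, not of the method;
  steep-flanked bands are also the more faithful rendering of a thin
  cortical band under a ~2 µm PSF. A plain Gaussian shape remains
  available.
- **Spot fields** place particles (isotropic Gaussians, σ = 1 µm,
  i.e. FWHM = 2.355 σ) and disk nuclei (r = 5 µm) by rejection
  sampling with a minimum separation (error after a bounded number of
  tries). The optional label channel fills each nucleus at a level
  drawn from one of two modes (30 vs 150 a.u., σ = 8) with
  `round(fraction·n)` positives.
- **Closure series** follow exponential area decay
  `A(t) = A0·e^(−kt)` by default (k = 0.1/min) or a linear-front model
  (radius shrinking at constant speed), sampled at 11-s frames, with
  multiplicative lognormal noise of given CV (mean-one), clipped at
  zero. The real curves follow no declared model; the generator only
  needs a known monotone truth.

All randomness in one call flows from a single integer seed; identical
(params, seed) give bit-identical outputs, and every quantity a
downstream stage estimates is in the returned ground-truth object.

**What passing tests show — and don't.** Recovery tests demonstrate
correctness of the estimators under the stated geometry, separable
intensity modes, and white noise. They do not exercise uneven
illumination, focal drift, folded tissue, touching nuclei at high
density, or segmentation error in the area series — in the real
workflow those are handled by upstream curation (lines avoid folded or
out-of-focus regions) and are out of scope here.

## Problem sizes

The shipped test suite and acceptance script use: 200 profiles
(≤2000 samples) for the oracle-equivalence check; 50 seeded profiles
and 2 × 20 sheet "animals" (6 lines each, 1 µm/px, 0.02 mm² wounds)
for ratio recovery and the treatment contrast; 50 spot fields for
count recovery; 4000/2000/2000 null replicates for the t/ANOVA/Tukey
size checks. These sizes put Monte-Carlo error well below the asserted
tolerances while keeping a full run in tens of seconds.

## Known limitations

- The wound is a disk and lines are radial; irregular wound outlines
  change only the ROI helper, not the pipeline.
- The 20–40 µm width band is applied to width-at-half-prominence; if a
  dataset's peaks are systematically near a band edge, detection
  becomes sensitive to noise in the width estimate.
- Per-timepoint closure tests are unadjusted by design; over ~20
  timepoints some early rejections are expected under the null.
- The particle detector is not a deconvolution method: overlapping
  particles closer than roughly one diameter merge.
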