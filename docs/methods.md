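# Methods

This note records the models behind `turfscreen`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic validation can
and cannot say about real imagery.

## Scene model

A scene is a nadir frame of one germplasm cell: a rectangular cell box
containing canopy over bare sandy soil, with uniform-reflectance calibration
tarp panels elsewhere in frame. Per-pixel surface reflectance is painted from
class spectral profiles:

| class | blue | green | red | red edge | NIR |
|---|---|---|---|---|---|
| green foliage | 0.04 | 0.22 | 0.06 | 0.35 | 0.55 |
| senescent foliage | 0.10 | 0.16 | 0.20 | 0.42 | 0.48 |
| soil (sand) | 0.18 | 0.20 | 0.22 | 0.21 | 0.22 |
| moss confounder (optional) | 0.12 | 0.26 | 0.14 | 0.22 | 0.24 |

The shapes encode the contrasts the analysis relies on: green foliage has a
visible green peak and a strong NIR plateau; senescent foliage loses pigment
contrast (red ≥ green) but keeps most of its NIR reflectance, because NIR
response is governed by leaf cell structure rather than chlorophyll — this is
also why the soil/canopy NIR contrast survives late-season browning, which the
canopy segmentation depends on; soil is spectrally flat. The optional moss
profile is ExG-positive but soil-like in NIR, reproducing the failure mode in
which ground cover inflates the green mask beyond the canopy mask (absorbed
downstream by the 100% cap on GCP).

Canopy and green-subset textures are drawn by thresholding Gaussian-smoothed
white noise (smoothing σ of 2.0 and 1.5 px — grass-blade scale at this
resolution); taking top-order statistics of the field makes realized pixel
counts exact, so the programmed green fraction equals the pixel-count truth to
within rounding. The default frame is 300 × 400 px with a 210 × 260 px cell —
a desk-scale stand-in for the study geometry of 1600 × 1300 px frames, fully
configurable.

The forward camera model is linear for the multispectral bands
(`DN = 200·R + 10`, 16-bit container) and exponential for RGB
(`DN = 25·exp(3.8·R)`, 8-bit). The RGB coefficients were chosen so the panel
reflectance range [0.05, 0.6] maps across most of the 8-bit range (DN ≈ 30 to
244); an underexposed model compresses the visible classes into a few dozen
DN, where quantization and read noise dominate the chromaticity signal.
Additive Gaussian DN noise (default sd 2) is applied in the DN domain and
truncated at the sensor range; quantization is round-half-even. Per-session
illumination drift is a multiplicative factor on the camera gains, drawn
uniformly from [0.85, 1.15] per session — the calibration stage is expected to
undo it exactly, since the tarp panels share the drift. The RED band content
is translated by an integer offset (default (2, 5) px) relative to the shared
frame, emulating inter-lens misregistration; the exposed border is filled with
soil, as if the scene continued past the cell.

## Senescence and cohort design

Each germplasm's green canopy fraction follows a logistic decline in session
time, `g(t) = 1/(1 + exp((t − m)/s))`: `m` is the session at which half the
canopy has browned, `s` the decline timescale in sessions. The paper-scale
default is 20 germplasm × 5 sessions × 57 scenes per session (285 scene
records; scene slots cycle over germplasm, so each appears 2–3 times per
session) with four replicate ROIs per scene. Default midpoints spread evenly
over [1.5, 4.5] with s = 0.8, spanning vigorous to rapidly browning material
within the five-session window.

The ranking-recovery validation uses midpoints 0.5 sessions apart with
s = 3.0: a slower timescale keeps final-session green fractions distinct
across the whole panel instead of saturating near 0 or 1, so the programmed
ranking is identifiable, and two scenes per germplasm per session — the
desk-scale analog of the study's 57 scenes / 20 germplasm ≈ 2.85.

## Calibration

Empirical-line fits use least squares: directly in reflectance-vs-DN space
for the linear form, and in log-DN space for the exponential form
(`ln DN = ln a + b·R`), which is deterministic and needs no initialization;
RMS residuals are recorded so poor fits are detectable. Panel DN is
summarized as the mean over the panel rectangle, the empirical-line
convention. Recovered reflectance is clipped to [0, 1] because the index
formulas assume reflectance-scale inputs; exponential-domain failures
(DN ≤ 0) become NaN and stay excluded from every histogram and mean
downstream. Histogram equalization is the global 8-bit CDF remap, per
channel, applied after calibration; it is monotone, so pixel rank order is
preserved, and a constant channel is returned unchanged.

Panel pixel coordinates are taken in each band's own frame: the RED band's
content is displaced relative to the nominal frame, so its panel rectangles
are translated by the band offset before sampling. Without this the red
calibration is contaminated by soil at the panel edges, which biases red
reflectance low and inflates NDVI — the pipeline therefore resolves the
RED/NIR offset *before* calibrating.

## Alignment

Shifts are integer-only; DN values are never resampled, and the border a
shift exposes becomes NaN (never zero, which would corrupt Otsu histograms
and ROI means). Offsets come from lens metadata (relative optical centers,
`offset = (nir.y − red.y, nir.x − red.x)`, the shift that lands RED content
on the NIR frame) or from an exhaustive search minimizing the sum of squared
differences over the finite overlap, normalized by overlap area, ties broken
toward the smallest |dy|+|dx|, then dy, then dx. Cross-band search runs on
Sobel gradient magnitudes rather than raw intensities: RED and NIR are
anti-correlated over vegetation (the very contrast NDVI exploits), so a raw
intensity-difference criterion prefers misregistration, while band edges
coincide and correlate positively. Only RED is aligned by default; the other
index bands accept configured offsets.

## Segmentation, GCP, indices

Otsu's threshold is computed on a 256-bin histogram of the finite values;
among tied maxima of the between-class variance the lowest cut is returned,
and foreground is strictly greater than the threshold — both rules fix
boundary behavior deterministically. ExG defaults to chromaticity-normalized
channels (illumination-invariant, bounded in [−1, 2]); the raw `2G − R − B`
variant is available behind a flag. The green mask is deliberately not
intersected with the canopy mask: with the moss confounder enabled a
replicate's green count can exceed its canopy count, and the GCP cap (values
above 100% normalized to 100 at record creation, raw value retained for
audit) absorbs the overflow exactly as the downstream normalization rule
prescribes. A replicate with no canopy pixels has undefined GCP and is
recorded as missing — substituting 0 or 100 would bias group means.

The protocol ROI of 48.5 × 132 px is realized as 48 × 132 (half pixels are
not representable without resampling); four ROIs are tiled deterministically,
evenly spaced in the cell box, and each ROI is one statistical replicate.
Index means are taken over pixels that are canopy-mask foreground and finite;
EVI pixels with a nonpositive denominator are missing, not clamped.

## Statistics

Group comparison is rank-based: tie-corrected Kruskal–Wallis H with a
chi-square upper-tail p (df = k − 1) as the default reporting convention, and
Dunn's pairwise z with the tie-corrected variance term, two-sided normal p,
and Benjamini–Hochberg step-up adjustment over all k(k−1)/2 pairs — one BH
family per session × metric. At four replicates per group the chi-square
approximation is conservative (empirical type-I ≈ 0.03 at nominal 0.05 for
k = 20), so `kruskal_wallis` also offers an exact Monte Carlo permutation p
(group labels reshuffled on the pooled midranks; the tie pattern is
permutation-invariant, so raw rank sums compare one-to-one) for small-sample
calibration work. The omnibus H is identical under both modes. A single
group shifted by even 3 pooled sd moves H by only ~11 against a
chi-square(19) critical value of ~30, so omnibus power against one-group
alternatives is intrinsically modest at this design size; detecting such
shifts is the job of the pairwise stage.

The compact letter display uses insert-and-absorb: one letter covering all
groups (ordered by descending raw mean), each significant pair splits every
letter containing both members, subset letters are absorbed; the output
satisfies "two groups share a letter iff their adjusted p ≥ α". Pearson
correlation between GCP and each index is computed on per-germplasm session
means, one point per germplasm per session, with p from the t distribution
(n − 2 df).

## What the synthetic validation does and does not show

Passing tests demonstrate that the implementation recovers what it was
pointed at: programmed offsets, calibration coefficients, green fractions,
and rankings, under piecewise-constant spectra, Gaussian DN noise, and exact
class boundaries. Real canopies add mixed pixels, shadows, specular foliage,
within-class spectral variation, non-uniform illumination across the frame,
and lens distortion (corrected upstream of this pipeline and not modeled
here); none of these are emulated, so the recovery tolerances measured on
synthetic scenes are best-case figures, not field-accuracy claims. The
generator also does not model weather, optics (PSF, vignetting), or
geo-referencing.

## Problem sizes used in validation

Validation runs at desk scale by choice: 300 × 400 px scenes, 50-seed
recovery sweeps, 2000 null simulations for test calibration, and 100
simulated cohorts (final session measured, two scenes per germplasm) for
ranking recovery. All randomness flows from explicit integer seeds; every
table the study writer emits is byte-reproducible given the same
configuration and seed.
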