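# Methods

## The segmentation model

A B-scan is treated as a 2-D 8-bit intensity raster whose rows encode
depth into the tissue. The pipeline has five stages per image:

1. **Conversion and crop.** Device exports (commonly 24-bit RGB TIFF,
   1024 × 992 px) are collapsed to 8-bit grayscale with BT.601 luma
   weights (device exports are pseudo-grayscale, so the weights only
   matter for non-degenerate RGB) and cropped to a height × height
   square. The crop removes columns symmetrically — `floor((W−H)/2)`
   from the left, the remainder from the right — keeping a fovea-centred
   scan centred. All 8-bit re-quantization in the package rounds half
   away from zero, which on the clipped non-negative range equals
   `floor(x + 0.5)`; this single convention makes every stage
   bit-reproducible across platforms.

2. **Enhancement.** Three sub-steps in fixed order:
   * *Gaussian low-pass* (default σ = 1.5 px, kernel radius ⌈3σ⌉,
     reflective borders) attenuates speckle. The default was chosen by a
     robustness sweep on synthetic scans: at σ = 1 the area recovery
     under 8-look speckle fluctuated by several percent; σ = 1.5 keeps
     it under ~2% while still resolving the band edges.
   * *Spectral median filter*: the image's 2-D FFT log-magnitude is
     median-smoothed (3 × 3, periodic boundary), the phase kept, and the
     image reconstructed. Isolated spectral peaks — how a single-frequency
     power-line stripe manifests — are replaced by their local background
     level, removing ≳ 90% of the artifact bin's energy. Two parts of the
     spectrum are held fixed: the DC bin (so the image mean is preserved
     exactly before re-quantization) and the whole zero-lateral-frequency
     column. The protected column is the lateral-mean depth profile; for
     a layered scan essentially all anatomy lives there, and a plain 2-D
     median would annihilate it, while lateral stripe artifacts live on
     the orthogonal zero-axial-frequency row and remain fully filterable.
     Whether magnitude, log-magnitude, or a notch design is "the"
     frequency-domain median filter is not standardized; this definition
     is recorded as the package's.
   * *Histogram equalization* via the classic cumulative-distribution
     mapping `T(v) = round(255·(cdf(v) − cdf_min)/(N − cdf_min))`.
     T is monotone, so pixel ordering is preserved. Note that histogram
     entropy cannot increase under any level remapping; equalization
     flattens by spreading well-populated levels and may merge sparse
     ones.

3. **Superpixel clustering.** Grayscale SLIC: K centres seeded on a
   regular grid with interval S = √(N/K), nudged to the lowest-gradient
   position in a 3 × 3 neighbourhood; pixels within a window of reach 2S
   of a centre are assigned to the centre minimizing
   D² = d_I² + (d_xy/S)²·m², with d_I the intensity difference to the
   cluster mean and d_xy the Euclidean distance to the centroid; centres
   are recomputed as cluster means for a fixed number of rounds
   (default 10). Everything is deterministic: ties break to the lowest
   centre index, accumulations run in row-major order. The generous 2S
   reach means that on tiny instances every pixel sees every centre, so
   the windowed algorithm coincides exactly with an unwindowed
   brute-force loop (a property the test suite checks); the spatial
   coherence this costs at analysis scale is recovered by a higher
   compactness. Library defaults are K = 400, 10 iterations, m = 10
   (superpixels ~50 px across on a 992 × 992 scan); the recommended
   configuration for 496-px synthetic frames is K = 600, m = 30.
   A connectivity-enforcement pass then makes every label a single
   4-connected region: each connected component of the label raster
   becomes a candidate label and components smaller than S²/4 are merged
   into their largest 4-adjacent neighbour (ties to the smallest id),
   smallest first; labels are renumbered 1..K in row-major first
   appearance.

4. **Selection.** The protocol is semi-automatic: the expert chooses
   numbered superpixels from an overlay (boundaries plus rendered label
   numbers). For batch runs and testing, a band-criteria surrogate picks
   every superpixel whose mean gray level on the *unenhanced* scan lies
   in an intensity window (default 40–80, bracketing the choroid's
   reflectivity between dark vitreous/vessels and the brighter sclera)
   and whose centroid depth lies in a row window, optionally measured
   relative to a per-column anchor at the brightest (RPE) band — the
   anchor is what makes the rule invariant to a tilted retina. The mask
   is the union of chosen superpixels; it may legitimately comprise more
   than one connected component.

5. **Metrics.** CA = pixel count of the mask; COID = mean gray level
   over the mask, computed in float on the unenhanced cropped scan;
   CD = CA/COID from the unrounded values. Measuring COID on the raw
   scan (not the equalized one) is a deliberate choice: equalization is
   a per-image monotone remap, so equalized levels do not compare across
   eyes, while the raw 8-bit level is the device's common scale — and
   published per-eye COID values (51–71) are consistent only with raw
   levels. A phrase describing CD as density "per unit area" contradicts
   the ratio definition; the ratio CA/COID is authoritative, validated
   by the published worked examples to within their printed rounding.
   The printed PD example (CA = 82 072, COID = 70.95, CD = 1358.22) is
   internally inconsistent with the ratio (which gives 1156.8) and is
   excluded from checks rather than second-guessed.

## Statistics

Per-group mean ± sample SD (n−1) for each metric; one-way fixed-effects
ANOVA (F from explicit between/within sums of squares, p from the
F(k−1, N−k) upper tail); post hoc all-pairs Welch t-tests with
Bonferroni adjustment (`p_adj = min(1, m·p)`), flagged at α = 0.05.
Normality is assumed, not re-tested. Which post hoc procedure the
original analysis used is unstated; Bonferroni–Welch is conservative, so
borderline pairs may come out slightly less significant than under,
e.g., Tukey HSD.

## The synthetic generator

`SyntheticSpec` renders a layered cross-section: vitreous (gray 10),
neuroretina (120), a thin bright RPE band (210), the choroid band (60)
with darker elliptical vessel lumina (30), sclera (90) below; interfaces
default to 0.20/0.50/0.55/0.75 of the height, giving a 0.20 H-thick
choroid. Optional effects:

* **Speckle**: multiplicative unit-mean gamma noise with L looks
  (`g ~ Gamma(L, 1/L)`), the standard coherent-imaging model. The field
  is indexed in *tissue* coordinates, so a tilted acquisition of the
  same eye carries the same speckle sheared along with the layers —
  the physically right picture, and what makes a tilted scan a true
  row-sheared copy of its untilted counterpart.
* **Stripe artifact**: an additive lateral sinusoid (detector-frame,
  not sheared), emulating power-line pickup.
* **Tilt**: a column-wise vertical shear, linear across the width, up to
  `tilt_px`.

The ground-truth mask is the exact choroid band — vessels included,
since the anatomical choroid encompasses stroma and lumina — taken
before noise; `true_COID` is the noise-free mean over the mask.
`simulate_cohort` adds per-subject jitter (interface depths N(0, 0.01)
height fractions; band intensities N(0, 3) gray) around per-group specs;
the provided disease-direction deltas thin the choroid band by 10% (MS)
and 20% (PD) and brighten it by +5/+10 gray, matching the reported
direction of effects (smaller CA, higher COID in disease) at synthetic
scale — magnitudes are not clinically calibrated.

What the generator does *not* model: OCT physics (interferometry,
A-scan sampling, optical path lengths), curved retinal geometry,
depth-dependent signal roll-off, motion artifacts. Passing recovery
tests therefore show that the pipeline finds a textured dark band under
speckle, stripes and tilt — not that it meets clinical accuracy on real
eyes.

## Problem sizes and observed behaviour

Tests and the acceptance script run synthetic frames at 496 px (and
64-px frames for the statistical calibrations), with K = 600 and m = 30;
the suite completes in well under a minute. Under these conditions the
pipeline recovers ground-truth CA within 5% (typically ~3%, a known
+2–3-row dilation at the choroid/sclera edge caused by equalizing a
noise-free 5-spike histogram) and COID within 2 gray levels; under
8-look speckle CA stays within 10% (typically 1–4%); a 20-px tilt
(4% of height) changes recovered CA by ≲ 2% (typically ~1%, with rare
seeds reaching ~2.4%). The null calibration (identical groups, 200
seeded replicates, n = 5 per group) rejects at α = 0.05 in 2–9% of
replicates; the disease-direction cohort (n = 25/group) yields
p < 0.001 with all three pairwise comparisons flagged.

## Known limitations

* The band-criteria surrogate needs the choroid's gray-level band to be
  separable from sclera and vitreous on the raw scan; severe shadowing
  or pathology would require the interactive path.
* The expert-correction step of the original protocol is exposed only as
  re-selection (add/remove labels), not boundary editing.
* Areas are in px² only; no micron calibration is attempted.
* Haller/Sattler sublayer separation and vascularity-index binarization
  are out of scope.
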