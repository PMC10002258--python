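# Methods

This note documents the models, estimators and numerical choices behind
the package, what the synthetic data do and do not emulate, and the
known limitations.

## Segmentation

Each channel is binarized at the global Otsu threshold computed on the
full-bit-depth integer histogram (256 bins for 8-bit, 65 536 for
16-bit). The implementation maximizes the between-class variance
σ²b(t) = ω₀ω₁(µ₀ − µ₁)² over every integer candidate t, breaking ties
toward the lowest threshold; binarization is strictly `plane > t`.
These conventions are asserted against an exhaustive brute-force search
in the test suite.

**Separability guard.** Global Otsu has a well-known failure mode on a
channel that holds no stained population at all: it happily splits the
read-noise distribution in half. In the original semi-automatic
workflow an operator inspects the histogram and raises the threshold
when "Otsu's value is not high enough"; the scriptable counterpart here
is Otsu's own separability measure η = σ²b/σ²total. For pure Gaussian
read noise η ≈ 0.64 independent of the noise level, while any channel
with a genuinely stained population at the intensities and densities of
this assay measures η ≥ 0.8. A channel with η < 0.75 is therefore
treated as unstained (empty foreground). The guard has a documented
blind spot: a channel with only a handful of faint objects in a very
large field can fall below the floor; a configured manual threshold
always bypasses the guard, which is the intended semi-automatic path
for such fields.

The candidate-CTC mask is pixelwise `blue AND green AND NOT red`. The
CD45 veto is pixel-level by default; a component-level variant (drop
every blue∧green component that touches any red foreground) is
available as `component_red_veto`, as a stricter interpretation of
leukocyte exclusion. Artifact removal takes a JSON sidecar of
rectangles/polygons and blanks them; with no regions the mask passes
through unchanged, so fully automatic batch runs are deterministic.

## Morphology and routing

Components are 8-connected (diagonal contact joins; this avoids
splitting the diagonal boundary pixels of small cells). Area is the
pixel count. **Perimeter** is the length of the sub-pixel boundary
polygon traced by marching squares at the 0.5 iso-level and simplified
with Douglas–Peucker at 0.6 px tolerance; the simplification removes
the rasterization staircase so that the estimate tracks the continuous
boundary length of both polygonal and smooth shapes (a digital square
of side s measures within a few percent of 4s, a digital disk within a
few percent of 2πr). Circularity 4πA/P² is clamped to [0, 1] because
the digital estimator can slightly overshoot for small disks. The
calibration properties — squares near π/4, disks ≥ 0.9 and
monotonically approaching 1 with radius, thin lines far below 0.6 —
are part of the test suite.

Routing: area < 10 px → discarded; area > 400 px → cluster mask;
otherwise circularity > 0.6 → cell mask, else cluster mask. At 0.75
pixel/µm the 10–400 px window corresponds to disks of roughly 5–25 µm
diameter, the plausible CTC size range. Both area bounds are read
inclusively ("between 10 and 400") and the circularity rule strictly
("greater than 0.6"); all four cut-offs are configuration fields.

## Circle detection

The detector is a gradient-directed circular Hough transform with a
verification stage. On the CK-weighted plane, upsampled 2× (bicubic):

1. Canny edges (σ = 1, fixed absolute hysteresis thresholds 0.05/0.12
   of the normalized intensity scale) and Sobel gradient orientations.
2. Each edge pixel casts one vote per candidate radius r at
   p + r·ĝ along its gradient direction (bright cells on dark
   background make ĝ point at the center). Accumulator slices are
   lightly smoothed (σ = 0.8) and normalized so a fully visible rim
   scores ≈ 1; local maxima above a fixed permissive floor (0.12)
   become proposals.
3. Proposals are refined to sub-pixel center and radius by iterating a
   least-squares (Kasa) circle fit on their direction-consistent edge
   pixels (within 1.5 px of the circle, gradient within 35° of the
   inward normal), three iterations.
4. Each refined circle gets a **support** score: the fraction of 64
   circumference samples backed by an edge pixel whose vote lands on
   this circle's own (center, radius) within 0.8 px. Support is what
   separates true (even partially occluded) cell rims from accumulator
   ring artifacts and from "compromise" circles straddling two cells.
5. Circles are accepted greedily by *marginal* support — support
   recomputed against only the not-yet-explained edge pixels — until
   the best marginal support falls below 1 − sensitivity. Accepting a
   circle consumes its rim pixels, so concentric duplicates and
   already-explained arcs cannot be accepted twice. A split-refinement
   pass may replace one accepted circle with a pair of candidates that
   explains strictly more edge evidence, which resolves strongly
   overlapped cluster members that a single compromise circle would
   otherwise absorb.

Because raising the sensitivity only lowers the stopping threshold of a
selection order that does not depend on it, the number of detections is
monotone non-decreasing in the sensitivity — a property the tests
assert. Everything is deterministic for fixed input and parameters.

The 2× upsampling matters: at 0.75 pixel/µm, cell radii are 2.6–4.5 px,
below the range where a discrete Hough accumulator resolves overlapping
circles; detection runs per connected patch of the weighted plane in a
cropped window, which keeps large sparse fields fast without changing
results.

**Mask weighting.** The cell/cluster masks are dilated by 3 px and
Gaussian-tapered (σ = 1.5, truncated at 5%) before multiplying with the
CK channel. A hard mask would clip every cell at its Otsu iso-contour,
and that artificial cut itself reads as a circular edge; the taper
keeps the sub-threshold outer rim visible to the gradient stage while
introducing no sharp boundary of its own (it reaches the 50% level only
where the point-spread-blurred rim has already decayed to background).

**Parameters.** `sensitivity` (default 0.65; 0.75 where overlapping
clusters dominate, exposed as `high_sensitivity`) sets the acceptance
threshold 1 − sensitivity on marginal support; the conservative default
favors accuracy over false positives. `min_center_distance` (default
2 px, the minimum search radius) suppresses duplicate centers while
permitting strongly overlapping cluster members. The radius window
derives from the physical cell-diameter range: r_min =
max(2, ⌊0.5·d_min·ρ⌋), r_max = ⌈0.5·d_max·ρ⌉, giving 2–10 px for
5–25 µm at ρ = 0.75 pixel/µm. The edge/accumulator constants above are
fixed, documented values calibrated once on the synthetic suite.

## Event classification and reporting

Circles are assigned to the routed component containing their center
pixel (centers on background are dropped and logged). Per component: no
centers → rejected, not counted (no CK-consistent circular profile);
one center → free CTC; k ≥ 2 centers → one cluster with k clustered
CTCs. Total CTCs = free + clustered; per-mL densities divide by the
blood volume (default 7 mL). Free and clustered diameters come from the
Hough radii (2r/ρ); cluster areas from component pixel counts (A/ρ²).
Clustered diameters from Hough radii and from component geometry can
differ; the package reports the Hough-based value and the component
area separately rather than reconciling them.

Validation metrics against a known truth use greedy nearest-pair
matching of detected centers to true tumor centers within a match
radius (default 10 px, one maximal cell radius; ties broken by distance
then raster order; each side matched at most once): recovery =
counted/true, sensitivity = matched/true, accuracy = matched/counted.
"Well-counted" is thereby given the operational definition of landing
within one cell radius of a distinct true tumor-cell center — a
stand-in for the visual confirmation used with real samples. The
intra-assay CV uses the sample (n−1) standard deviation; correlation
reports give tie-corrected Spearman R² and an OLS slope/intercept with
95% t-intervals. Two-sample comparisons (t-test, Mann–Whitney) are
convenience wrappers, not part of the method.

## Synthetic data

The generator emulates the spiked-blood validation design: PANC-1-like
tumor cells (blue + green), leukocytes (blue + red, with the CD45
membrane disk 20% larger than the nucleus), and debris (irregular
single-channel polygons) placed without collisions in a field at 0.75
pixel/µm; a dilution series spikes exactly 100/300/1000 tumor cells
(3 replicates, 768×768 px fields, 150 leukocytes, 10 debris, one
2–4-cell cluster per 100 spiked cells).

Rendering choices that matter:

* **Additive fluorescence.** Intensities sum in projection, so
  overlapping cells produce a brighter lens whose boundary continues
  each member's rim inside the union. With opaque (max-blend)
  rendering, a tight pair is mathematically indistinguishable from one
  larger round cell; additivity is both the physically correct model
  and the information that makes cluster counting possible at all.
* **Sizes.** Tumor radii uniform in 3.5–6 µm (diameters 7–12 µm),
  leukocyte radii 3–4.5 µm; per-object brightness lognormal
  (median 140 of 255, σ_log = 0.25) per channel.
* **Clusters** are chains: each member 0.8–1.3× the mean radius from
  the previous one with a bounded turning angle, giving the
  strand/grape-like aggregates seen in enriched samples and
  guaranteeing chain-overlap.
* **Optics/camera.** Gaussian PSF blur σ = 0.5 px (a diffraction-
  limited PSF is sub-pixel at 1.33 µm pixels), constant background 8,
  Gaussian read noise σ = 2, 8-bit quantization.

One integer seed fixes everything bit-for-bit.

What the simulator does **not** model: spectral bleed-through, uneven
illumination, focus variation, red blood cells and platelets, bead
aggregates, autofluorescent debris with mixed-channel signal, or the
immunomagnetic enrichment losses upstream of imaging. Passing the
synthetic suite therefore demonstrates the counting logic and its
failure modes under controlled optics, not performance on clinical
images, where staining variability and artifacts dominate.

## Performance under study conditions

On the dilution series the pipeline recovers ~99% of spiked cells with
~99.7% accuracy, and repeated runs of one field give identical counts
(CV exactly 0). Cluster multiplicity is recovered exactly for 75–100%
of 2–4-cell chains depending on the sampled geometries (the hard cases
are members at 0.8–0.9× radius spacing, where the visible evidence for
the occluded cell is a few pixels of arc); counting individual cells
inside tight clusters is intrinsically less reliable than counting
free cells, and mis-estimates are almost always ±1 cell.

A structural note on the dilution-series correlation: because the
generator spikes each field with its exact nominal density, the nine
true counts are tied in three groups, and tie-corrected Spearman
correlation of any nine distinct detected counts against them is
bounded at ρ ≈ 0.949 (R² ≈ 0.90) no matter how good the detector is.
The Pearson R² (≈ 1.0) and the regression slope (≈ 1.0) are reported
alongside as the informative agreement measures for this design.

## Problem sizes

Default study sizes were chosen so the full validation (dilution
series, cluster study, negative controls, CV replicates) completes in
well under a minute on one CPU: 768×768 px dilution fields (~1 mm² of
membrane at 0.75 pixel/µm), 96×96 px single-cluster fields, 512×512 px
negative controls. All sizes are configuration fields and scale
linearly in cost with foreground object count.

## Known limitations

* The separability guard can misjudge channels with very few faint
  objects; manual thresholds are the intended fallback.
* Radius estimates are quantized by the discrete radius sweep before
  refinement; reported diameters are accurate to roughly ±1 px / ρ.
* Components larger than 400 px with zero detected circles are
  rejected silently (logged); a large CK-positive smear thus counts as
  nothing rather than as an error.
* The detector assumes bright cells on a dark background (gradient
  pointing inward); inverted-contrast imagery would need a sign flip.
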