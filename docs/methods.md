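# Methods

## The curvelet transform

The engine is a digital curvelet transform built as a tight frame on the
discrete Fourier grid. Frequency windows are products of Meyer-type radial
profiles (low-pass cutoffs doubling per scale, the finest band isotropic up
to the Nyquist corners) and equal-angle wedge windows on the polar angle,
constructed so the squared windows sum to one at every frequency sample.
Each windowed spectrum is wrapped into its circular bounding box and
inverse-FFT'd with unitary normalization. Because the squared windows
partition unity and the wrapping is injective, the frame is exactly tight:
the inverse transform is the adjoint, round trips are exact to machine
precision, and coefficient energy equals image energy. This is a deliberate
simplification of the classic wrapping construction — equal-angle wedges on
the true polar angle instead of equal-slope pseudo-polar wedges, and
bounding-box wrapping instead of sheared-parallelogram wrapping. The cost
is a somewhat higher redundancy (about 4-6x rather than ~2.8x); the gain is
exactness of reconstruction and energy by construction.

Defaults: `n_scales = ceil(log2(min(h, w))) - 3` (7 scales at 576 x 720),
16 wedges at the coarsest directional scale, doubling every other scale.
Coefficients are complex; reconstruction takes the real part.

Band edits act on magnitudes only and preserve phase:

* **power map** — per band, `m = |c| / max|c|`, new magnitude
  `max|c| * m^p`, coarsest band untouched. `p = 5` suppresses weak
  coefficients so bright compact objects dominate the reconstruction (optic
  disc, exudates); `p = 0.8` mildly lifts weak coefficients (contrast
  enhancement before matched filtering). The per-band normalization is
  essential: an unnormalized fifth power explodes the dynamic range.
* **high pass** — zero the coarsest band, scale all other magnitudes by a
  gain (default 2), used to sharpen the matched-filter response.

## Stage models and parameters

**Preprocessing.** CLAHE (8 x 8 tiles, clip limit 0.01) plus illumination
flattening (subtract a sigma = 30 px Gaussian background estimate, restore
the mean). These feed only the *geometry* stages — vessel segmentation and
disc localization. The photometric stages (FAZ darkness, lesion brightness)
run on the original-scale images: local histogram equalization equalizes
away precisely the absolute fluorescence cues their thresholds measure, and
with CLAHE ahead of them lesion-free images produced spurious lesions while
the FAZ dark region saturated its search area.

**Vessels.** Invert the angiogram, curvelet contrast enhancement
(power 0.8), correlate with the oriented negative-Gaussian matched filter
(sigma = 2 px, segment length L = 9 px, support |x| <= 3 sigma — the
classic values for this image scale), keep the per-pixel maximum over 12
orientations, curvelet high pass (gain 2), clip negative reconstruction
overshoot to zero, threshold strictly above the global mean, and remove
components below 50 px (scaled with the image diagonal) or blob-shaped
(largest inscribed disk >= 0.25 sqrt(area) and >= 4 px — dots are lesions,
not vessels). Clipping before the mean threshold matters: after coarse-band
removal the reconstruction is zero-mean, and a min-max rescale would place
the threshold at the noise floor. A second, more inclusive mask (length
floor 10 px) is kept for the microaneurysm stage, where fragments of faint
vessels would otherwise masquerade as dots.

**Optic disc.** Fifth-power amplification, then a grayscale opening
(disk r = 10) to erase vessels, heavy smoothing (sigma = 8) so the disc is
a single blob, and rectification at a fraction of the maximum so diffuse
perfusion glow carries no gradient. Canny edges (sigma = 3, hysteresis at
0.1/0.2 of the maximum gradient magnitude), dilate with a 1-px disk, fill
holes, erode back. Candidates are gated by area, convexity, and containment
of a near-maximal brightness peak; among survivors the one with the highest
vessel-pixel fraction wins — the disc is where the vessel tree converges. A
rectification-level cascade (0.4, 0.5, 0.6 of max) retries with tighter
levels when no candidate contour closes. The gentler Canny setting the
design started from (sigma = 2 on the raw amplified image) fragments the
rim edge wherever a vessel crosses it and the filled disc region never
forms; the suppression-smoothing-rectification chain is what makes the
contour close reliably.

**Exudates.** Green channel, local-mean contrast stretch
`g = 9 f - 9 f̄(3x3) + 90` on the 8-bit scale (mirror-padded, center pixel
included, clipped to [0, 255]), fifth-power curvelet amplification, Otsu
threshold restricted to above-mean pixels, an absolute gate on the
stretched image (> 0.5, i.e. raw g > 128 — flat background maps to 90/255,
so noise-driven Otsu splits cannot pass on lesion-free images), hole
filling plus a 1-px dilation (the stretch responds at lesion boundaries;
filling recovers the interior and the dilation the outer half of the edge
band), removal of regions touching the disc dilated by 5 px, and a 5-px
minimum region size.

**FAZ.** The macular ROI sits 2.5 disc diameters from the disc center on
the horizontal, toward the image center by default; its radius is 2.5 disc
radii. The endpoint path skeletonizes the vessel mask (the 3x3-sum tip rule
is only meaningful on 1-px curves), keeps skeleton pixels whose 3x3 sum is
2, drops tips farther from the tip centroid than the mean tip distance, and
fills the convex hull of the survivors. The intensity path zeroes vessel
pixels, applies a grayscale closing (disk r = 8), and keeps non-vessel ROI
pixels at or below the global mean of the closed image — a global
threshold on purpose, because the FAZ can fill most of the ROI and any
ROI-local split then degenerates. The final mask is the intersection,
unless the hull is implausibly small (under 0.75x the dark area — a
truncated tip ring cannot contain the avascular zone), in which case the
intensity path stands alone and the result is flagged, exactly as when
fewer than three endpoints exist. Area, centroid, 64 ordered boundary
points and the boundary-distance variance are measured on the final mask.

**Microaneurysms.** Zero the (1-px-dilated) vessel mask and the (5-px-
dilated) disc, grayscale dilation (disk r = 2), background by grayscale
erosion (disk r = 10, larger than any dot), map the background's zeros onto
the dilated image, subtract, white top-hat (disk r = 3), threshold at
ceil(0.1 x 255) = 26 on the max-rescaled 8-bit scale with an absolute
contrast floor of 0.05 (the relative threshold alone is meaningless when no
true lesion sets the maximum). Components must be 1-50 px, have
eccentricity <= 0.95, and sit on a compact bright structure in the source
image (local-Otsu component extent in (0, 16] px — fragments of faint
vessels fail this, isolated dots pass). Counts are reported overall and
for centers inside the FAZ mask dilated by 10 px.

**Grading.** Features standardized to zero mean/unit variance (areas are
~10^4, counts ~10; without standardization the areas dominate the kernel).
Both SVM stages use an RBF kernel, C = 10, width from the median heuristic
(gamma = 1/(2 median^2) of pairwise distances of the standardized training
set). Evaluation: stratified 30% train / 70% test, 10 reshuffles,
one-vs-rest sensitivity and specificity per grade, macro-averaged; with
error-free prediction every averaging convention agrees.

## The phantom generator

`render_pair` draws what the pipeline assumes: vignetted dark background; a
bright disc (radius 40 px) crossed by arcade vessels that random-walk
outward from inside it (bounded curvature, one branch and one grandchild
each); 16 perifoveal vessels converging radially on the FAZ rim, where they
terminate; short capillary segments scattered through the macular annulus
(their free tips populate the endpoint statistics the way a real capillary
plexus does); a diffuse perfusion glow (blurred vessel density — perfused
retina fluoresces, the avascular zone does not); Gaussian-profile vessel
cross-sections (sigma = 2 px) matching the matched filter's model; bright
MA dots placed off-vessel (>= 12 px clearance, in the perifoveal annulus or
scattered — MAs arise on capillaries, so none are planted inside the
avascular zone itself); and elliptical yellow exudate blobs on the color
image. Additive Gaussian noise (sigma = 0.01) is applied last; the
pre-noise renders are kept on the truth record for oracle tests. Severity
presets: grade 1 lesion-free with a 28-px FAZ and 14 arcades; grade 2
moderate lesion load, 38-px FAZ, 10 arcades; grade 3 heavy exudates, 50-px
FAZ, 7 shortened arcades and thinned capillaries (dropout).

What the phantom does **not** emulate: real texture and speckle,
pathological vessel tortuosity and neovascular fronds, hemorrhages,
media opacity, FFA timing phases, or registration error between the two
modalities (the pair is rendered co-registered, and the pipeline assumes
registration rather than computing it — each feature is extracted from a
single modality, so only geometric consistency within one image matters).
Passing phantom tests therefore demonstrates the internal consistency and
recovery power of the pipeline under its own model assumptions, not
clinical accuracy on real data.

The feature-space cohort sampler draws each feature independently from a
log-normal distribution with the per-grade mean and a 10% coefficient of
variation (areas are nonnegative and right-skewed; the means alone are
specified, so a dispersion had to be chosen — 10% keeps the classes
separated the way their widely spaced means suggest). Zero means stay
exactly zero; count features are rounded, which biases a sub-unit mean
count toward 1 — the convergence tests therefore use a grade whose count
means are large.

## Numerical and degenerate-input choices

* Featureless (constant) images return empty vessel masks rather than
  renormalized numerical noise.
* Strictly-greater comparison at the vessel mean threshold; at-or-below at
  the FAZ dark threshold.
* The ROI side defaults to the image-center side of the disc (tie broken
  toward the right); overridable per image.
* Reconstruction values may leave [0, 1] after band edits; each consumer
  renormalizes in the way its threshold semantics require (min-max before
  Canny, clip-at-zero before the vessel mean threshold).
* All randomness flows from explicit integer seeds; rendering and the full
  pipeline are bit-reproducible for a fixed seed and configuration.

## Problem sizes

Tests and the acceptance script run phantoms at the native 576 x 720
geometry; transform fidelity is additionally checked at 64 x 64 and
128 x 128. The grading simulation uses the 70-subject cohort (30/25/15)
throughout.

## Known limitations

* The endpoint path degrades when the tip ring around a large FAZ is
  angularly incomplete; the degenerate-hull fallback then leans entirely on
  the intensity path.
* Measured FAZ area carries a small positive halo (the avascular area is
  bounded by vessel edges, not centerlines).
* MA detection near dense capillary beds is limited by vessel-segmentation
  recall; dots closer than ~10 px to a vessel are suppressed by the
  exclusion margin.
* The disc radius is measured from a smoothed level set and is biased a few
  pixels low at the default suppression scale.
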