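# Methods

This note documents the model and procedure implemented by `cmbdetect`,
the choices made where the design was genuinely open, what the synthetic
phantoms do and do not emulate, and the known limitations.

## Detection model

A cerebral microbleed on T2\*-weighted MRI is modeled as a dark, roughly
spherical signal void of diameter ~1.4–3.4 mm, at least half surrounded by
parenchyma, and accompanied by the rim brightening ("blooming") that
susceptibility effects and SWI phase processing leave around a
paramagnetic deposit. The detector is deliberately built from
interpretable geometric primitives — edges, circles, entropy, Hessian
eigenvalue analysis — rather than learned features, so that its cutoffs
can be re-tuned from a handful of rated scans when acquisition parameters
change.

### Working resolution

Scans are upsampled by an integer factor (default 3) on all three axes:
intensities by third-order spline, masks/atlases by exact block
replication (nearest neighbor). At 0.43 mm native in-plane spacing this
gives ~0.143 mm pixels, so the Hough radius window [5, 12] px corresponds
to physical radii 0.72–1.72 mm. The slice axis is resampled with the same
factor; whether to resample it is exposed only through the resample
factor, and all physical distances are computed as index difference ×
spacing. Block replication (rather than spline order 0) was chosen for
labels because it makes subsampling every k-th voxel an exact inverse.

### Candidate generation

Per slice: 3×3 Sobel gradient; non-maximum suppression along the
*continuous* gradient direction using bilinear interpolation of the
gradient magnitude (the quantized 4-sector variant fragments the small,
strongly curved rims of microbleed-scale circles, which then fail the
multi-circle grouping step); hysteresis with thresholds interpreted as
fractions of the per-slice maximum gradient magnitude, because the
printed bounds (0.10/0.15) come without a normalization reference and a
per-slice reference makes the edge detector contrast-invariant.

The circular Hough accumulator votes each edge pixel into every cell
whose center lies at a rounded Euclidean distance equal to the radius
(a one-pixel annulus). Annulus binning, rather than midpoint-circle
rasterization, tolerates the half-pixel radial jitter of real edges;
votes are normalized per radius by the annulus size so a cell value is
the fraction of the circle actually present. The 80% threshold is taken
relative to the per-slice accumulator maximum across all radii (the
single-maximum reading), and a 3×3 in-plane non-maximum suppression per
radius plane removes duplicates one pixel apart.

A volume-relative gradient floor (default 2% of the volume's maximum
gradient magnitude) declares a slice featureless when nothing on it comes
near the volume's real edge scale: per-slice *relative* thresholds would
otherwise amplify numerically negligible spline-interpolation ripple on
structure-free slices into edges.

Exclusions mirror visual-rating criteria and run in the published order:
image-border circles; per-slice overlap merging (overlap = center
distance < sum of radii) with singleton rejection and a maximum pairwise
group span of 8 px; CSF-overlap rejection (strictest "any voxel" rule by
default, with an exposed overlap-fraction parameter); cross-slice linking
of surviving groups (adjacent slices, in-plane distance ≤ 8 px,
transitive union).

A candidate's center starts as the rounded centroid of its member group
centers (one per slice — per-circle weighting would drag the center
toward slices that happen to fire more accumulator peaks) and is then
refined to the minimum of the lightly smoothed intensity in a small
window (±6 px in plane, ±2 native slices): a microbleed is a signal
void, so its center is the darkest point of the merged region, and the
refinement corrects the z bias that discrete slices and interpolation
ringing impose on the raw centroid. Chain fragments that refine onto the
same void are merged into one candidate. Each candidate gets a
51×51×25-voxel ROI, edge-padded at volume borders — roughly twice the
maximum expected microbleed extent, which standardizes the geometric
features.

### Geometric filtering

* **Entropy** (bits): each ROI (or its z-axis maximum intensity
  projection) is linearly rescaled to 256 integer bins and the Shannon
  entropy of the bin histogram computed, with 0·log 0 = 0. Per-ROI
  rescaling makes the descriptor invariant to global intensity scale and
  offset.
* **Vesselness**: single-scale Frangi filter on the central-difference
  Hessian in voxel units, without Gaussian pre-smoothing — the targets
  are small and nearly constant in size, so a scale sweep buys little.
  Eigenvalues (|λ₁| ≤ |λ₂| ≤ |λ₃|, signs retained, computed by the
  closed-form trigonometric solution for symmetric 3×3 matrices) feed
  R_A = |λ₂|/|λ₃|, R_B = |λ₁|/√|λ₂λ₃|, S = ‖λ‖₂, with α = β = 0.5 and
  c = ½·max S over the ROI ("half of the Hessian norm", read as the
  per-ROI Frobenius-equivalent scope). Voxels with λ₂ < 0 or λ₃ < 0
  (bright structures) or λ₂λ₃ = 0 (undefined ratios) get V = 0.
  Derivatives are deliberately *not* spacing-corrected (a spacing-aware
  switch exists but is off): the filter runs in resampled voxel space.
* **Central blob**: the vesselness map is thresholded at a fraction of
  its maximum (defaults SWI 0.15, GRE 0.25; the useful range is 0.1–0.6)
  and the 26-connected component containing the supra-threshold voxel
  nearest the ROI center is kept (distance ties break toward lower
  indices). Volume is its voxel count; compactness is (perimeter
  voxels)²/volume with perimeter defined by 6-neighborhood face
  exposure.
* **Cutoffs** apply in a fixed order — 3D entropy, MIP entropy, blob
  volume window, compactness — recording the first strict violation;
  values exactly at a cutoff pass. The shipped defaults are derived from
  the published true-positive feature distributions (3D entropy ceiling
  6.88 = top of the printed TP range; MIP entropy 6.0 ≈ TP mean + 3 SD;
  volume ceiling 2195 ≈ TP mean + 2 SD; compactness ceilings 1368/1074
  likewise) and are provisional by design: the volume *minimum* defaults
  to 0 because no TP minimum is published, the GRE volume ceiling reuses
  the SWI-derived value because the printed GRE TP volume statistic is
  internally inconsistent (SD ≫ mean), and users are expected to re-derive
  cutoffs for their own acquisition with `sweep_threshold`, which
  reproduces the volume/compactness-vs-threshold analysis on any labeled
  ROI set.

### Localization and outputs

Accepted candidates take the atlas label at their center; label-0 centers
(atlas boundary gaps) fall back to the nearest nonzero label within 5 mm
(an invented but conservative radius), else "unlabeled". The region
vocabulary is fixed to eight categories: frontal, temporal, parietal,
occipital, basal ganglia, thalamus, infratentorial/cerebellum, other.
Outputs are rater-editable: a native-space NIfTI mask marking each
accepted candidate's neighborhood with its integer candidate id (so one
candidate can be deleted in any viewer), candidate and feature CSV
tables, and a JSON summary with per-stage rejection counts and the
region histogram. Native coordinates are recovered from resampled ones by
integer division by the resample factor.

### Evaluation

Detections are matched to rated truth one-to-one, greedy nearest-first,
within 3.44 mm (twice the maximum Hough radius in millimetres; the
correspondence criterion is not published, and greedy matching is
deterministic and adequate at microbleed densities). Sensitivity is
reported per certainty class (definite = three raters agree, probable =
two of three) and combined; precision is TP/(TP+FP) and FP/scan averages
false positives over the group's scan count. The same matcher scores
longitudinal persistence of baseline locations at follow-up.

## Synthetic phantoms

The generator renders, at native SWI-like spacing (0.43 × 0.43 × 2 mm):
dark, mildly ovoid microbleed mimics with a one-voxel cosine shoulder
centered on the nominal radius, a low-order lumpy rim (third-harmonic
radial modulation of 4–6%) and a narrow hyperintense halo ring; dark
straight cylinders (vessel mimics; default caliber 0.8 mm, thinner than
the microbleed mimics, as in real anatomy); bright axis-aligned CSF boxes
mirrored in the CSF mask; additive white Gaussian noise; a toy atlas of
eight octants; and exact ground truth. Structures are integrated
through-slice (five-point average over the 2 mm slab), as a scanner does
— without partial-volume integration, spheres thinner than the slice
thickness alias to the nearest slice center and their rendered position
is wrong by up to a millimetre.

The shape irregularity is not cosmetic. Real microbleeds are "round or
ovoid" and irregular at the upsampled resolution, and the published
exclusion rules implicitly assume that: an analytically perfect circle
produces exactly one Hough peak per slice and is deleted by the
per-slice singleton rule, a configuration real lesions never present.
Conversely, strong global ellipticity lets short rim arcs fit small
off-center circles whose spread trips the 8 px size cutoff. Mild
ovality plus small high-order lumpiness reproduces the multi-circle,
concentric response of real lesions without either failure mode.

Two rendering parameters were calibrated against the *published*
true-positive feature statistics rather than chosen freely: the halo
amplitude (1.5 × the void depth) and the noise level (σ = 1% of
background, a high-quality 3T acquisition). With a flat background and no
halo, the maximum intensity projection of any ROI is noise-dominated and
its per-ROI-rescaled entropy pins near 7 bits regardless of σ — far above
the ~5.0 bits real true positives show — because in real scans the bright
blooming rim stretches the projection's dynamic range. With the
calibrated halo the phantom's true-positive MIP entropy is 5.0 ± 0.4
bits and its 3D entropy ~4 bits, matching published true-positive
behavior. The halo is kept narrow (one taper width) so that the rim and
halo edges form two concentric Canny rings inside the Hough radius
window — the double-edge response real microbleeds produce.

What the phantoms do *not* emulate: anatomy (gyri, vessels trees, skull
base artifacts), spatially correlated or Rician noise, GRE/SWI phase
behavior, motion, or bias fields. Passing the phantom suite therefore
demonstrates internal consistency of the pipeline and recovery of
idealized targets, not clinical performance; the published cohort-level
sensitivity/precision figures are arithmetic identities of the printed
counts here, not re-measurements.

## Numerical choices and degenerate inputs

Constant slices produce no edges (zero max-gradient guard); empty edge
maps produce empty candidate lists, not errors. A constant ROI has zero
entropy, an all-zero vesselness map, an empty blob (volume 0,
compactness reported as 0 in feature tables; the standalone compactness
operation raises on empty blobs). Accumulator ties at the threshold are
kept (≥ with a 1e-12 slack); center rounding breaks .5 ties toward lower
indices. The blob-nesting property (mask at threshold f ⊇ mask at
f′ > f) holds for structured vesselness maps where the seed stays in the
central component; on pure-noise maps the nearest supra-threshold voxel
can hop components, so the property is validated on noise-free phantoms.

## Problem sizes

The end-to-end benchmark uses 20 phantoms of 64×64×12 native voxels with
two planted spheres each (diameters 1.5–3.3 mm, contrast 0.6, default
noise) plus 5 structure-free controls; after threefold upsampling each
phantom is a 192×192×36 volume, and a full run takes a few seconds per
phantom on one core. These sizes exercise every pipeline stage at the
published working resolution while keeping the whole suite quick to
re-run.

## Known limitations

* Cutoff defaults are provisional (see above) and should be re-derived
  per scanner/protocol; the published supplementary cutoff tables were
  not available to this implementation.
* Whether the original implementation resampled the slice axis, and
  whether its Hough threshold was per-slice or per-volume, are not
  documented; this implementation resamples all axes and thresholds
  per slice.
* The false-positive rate on phantoms (~20/scan) is dominated by noise
  rings that survive the entropy filters when a nearby structure widens
  the ROI's intensity range; on real data the published method similarly
  relies on a final human edit (its precision is ~7–11%).
* z localization is slab-quantization-limited: a void thinner than the
  2 mm slice images with its minimum biased toward the dominant slab, so
  detection locality is about one lesion radius plus half the slice
  thickness, not one radius. In crowded noise-free scenes, mimics at the
  very top of the radius window can additionally lose all their per-slice
  circle groups to the singleton/size rules (their halo ring leaves the
  Hough window and the per-slice accumulator maximum is set by a stronger
  neighbor); under realistic noise this does not occur at measurable
  rates.
* The per-slice "80% of the accumulator maximum" rule couples structures
  that share a slice: a strong circle can suppress a weaker lesion's
  circles. Noise levels the accumulator scores on real data, but the
  effect is visible on noise-free phantoms.
* Single-scale vesselness under anisotropic voxel-unit derivatives makes
  in-plane vessels score lower than through-plane ones; vessels are
  nonetheless removed effectively by the CSF-overlap and blob-volume
  rules.
* Brain extraction, tissue segmentation and registration are out of
  scope: masks and atlases must arrive co-registered on the scan grid.
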