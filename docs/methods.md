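# Methods

## Scope and model

`focidens` quantifies radiation-induced DNA double-strand breaks in
fluorescence micrographs of γH2AX immunostaining. The measured quantity is
the **foci density per object**: the number of detected γH2AX foci inside a
segmented object divided by the object's pixel area. An *object of
quantification* is one connected component of the nuclei mask — a single
nucleus or a small group of touching nuclei that thresholding does not
separate. Working with per-area densities instead of foci-per-cell counts
removes the dependence on nucleus size, on the confocal z-slice height, and
on any cell-splitting heuristic, which is why the pipeline deliberately
performs **no watershed separation and no border-object removal**.

Densities are aggregated per irradiation condition (treatment group × dose),
the condition means are regressed linearly on dose, and the ratio of the
treated to the control gradient is reported as the **radiosensitization
factor**. For treatment-plan evaluation the package also computes the
**dose enhancement factor** (DEF, the voxelwise ratio of absorbed dose with
vs without nanoparticles over a target mask, reported as mean ± SD) and the
**conformity number** CN_p = (Vp/V)·(Vp/Tp) at p % of the prescription dose,
where V is the target voxel count, Vp the covered target voxels and Tp all
voxels at or above the threshold (coverage × selectivity).

## Nuclei segmentation

Input is the raw nuclei-stain channel (8-bit expected, 16-bit accepted).
Steps, in order:

1. **Otsu binarization.** 256-bin histogram over the data range; candidate
   thresholds are the interior bin edges; between-class variance is computed
   from bin counts and centers; ties resolve to the lowest threshold;
   foreground is `value >= threshold`. A constant raster is degenerate and
   yields an empty labeling with a warning.
2. **Adaptive median filtering** of the *binary* mask. The classic
   growing-window scheme (3×3 up to `median_max_window`, default 7) is
   specialized to binary data, where the window median always coincides with
   an extreme, so the filter reduces to a majority vote over the largest
   window — an impulse-noise remover that preserves large blobs.
3. **Hole filling**, 4-connected background.
4. **Opening by reconstruction.** Erosion by a Euclidean disk of radius
   `min_nucleus_radius_px` (default 25 px, appropriate to ~1880×1880
   tile-scan resolution), then reconstruction by dilation (8-connected)
   under the hole-filled mask. Objects that cannot contain the disk vanish;
   surviving objects keep their exact shape. The erosion is computed as
   `distance_transform_edt(mask) > r`, which equals erosion by
   `skimage.morphology.disk(r)` with out-of-frame pixels treated as
   foreground (asserted against skimage in the tests); the degenerate
   all-foreground mask is its own erosion.
5. **Closing.** `closing_iterations` (default 4) successive dilations by a
   radius-1 disk, hole filling, then the same number of erosions
   (erosion border treated as foreground, the standard closing convention).
   The structuring element for these iterations is not dictated by the
   mask-construction recipe beyond the iteration count; a radius-1 disk
   (4-connected cross) iterated is the documented choice.

Connected components (8-connected) of the final mask are the labeled
objects. The pipeline is deterministic and, by construction, every object
eroded by the minimum-radius disk before the closing step is nonempty.

## Foci detection

Input is the foci channel normalized to [0, 1] (division by
`2**bit_depth − 1`; double normalization is a contract violation because the
intensity gate T_e lives on this scale). Per image:

1. adaptive median filter (grayscale variant of the same scheme);
2. white top-hat with a disk of radius **r_f** (the maximal focus radius),
   which suppresses background structure wider than a focus;
3. **h** = Otsu threshold of the top-hat values restricted to object pixels.
   The reference description is ambiguous about whether h is measured on the
   raw or the filtered image; it is measured on the *top-hat-filtered*
   values because that is the image the transform operates on. Whether to
   compute it per image or per object is likewise open; per image restricted
   to the object union is implemented. If the restricted top-hat is constant
   or h ≤ 0, the image contributes zero foci;
4. H-maxima transform with height h — morphological reconstruction by
   dilation of `tophat − h` under `tophat` — followed by extraction of
   8-connected regional-maximum components; a plateau counts once;
5. gating and attribution: a component counts as one focus iff the maximum
   of the **original** (unfiltered, normalized) raster over the component
   strictly exceeds **T_e**; it is attributed to the object containing its
   brightest in-object pixel (ties → lowest label), so each focus belongs to
   exactly one object and per-object counts sum to the union-mask count.

Filtering is computed once over the full frame; restriction to objects
happens at counting time. Inside objects farther than the footprint radius
from the frame border this equals per-object filtering; near the border the
reflective padding can leak intensity, which is accepted and documented.

Defaults: r_f = 13 px and T_e = 0.55, the reference tuning for
nanoparticle-treated data (controls there used r_f = 23). Parameters are
per-treatment-group config because nanoparticle incubation alone changes the
culture condition and can modulate foci morphology.

**Parameter optimization** evaluates every pair of the grids
r_f ∈ {9, 11, …, 27} and T_e ∈ {0.30, 0.35, …, 0.70} (90 cells), separately
per group, scoring each pair by the R² of the linear fit of mean density vs
dose on a calibration series (≥ 3 dose levels required). This criterion is a
documented replacement for the original appendix procedure, which is not
specified in the main reference chain; the criterion is pluggable
(any callable on the per-image results). Candidate maxima are cached per
(image, r_f) and re-gated per T_e, which is exactly equivalent to rerunning
the detector (asserted in tests).

## Dose-response statistics

- **Outlier screening** is per image, one pass: densities outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are removed, with quartiles computed by
  linear interpolation between order statistics (the convention is not fixed
  upstream; linear interpolation is numpy's default and is frozen in the
  tests). Values exactly on a fence are kept. Fewer than four densities:
  nothing is removed (quartiles of so few points are noise), with a warning.
- **Condition summaries** pool kept densities over all images of one
  (group, dose): mean and SEM = sample SD/√n; a single-object condition
  reports SEM 0 with a warning.
- **Linear fit**: ordinary least squares of condition mean density on dose
  (5 points for the standard {0, 0.25, 0.5, 1, 2} Gy design). The fit is over
  condition means, matching how such series are presented; an object-level
  fit can be built from the per-object table if wanted. Pearson-correlation
  p-value and the Shapiro–Wilk p-value of the residuals are reported as
  diagnostics only and never gate anything. A perfect fit leaves Shapiro
  undefined (NaN).
- **Radiosensitization factor** = slope_treated / slope_control; undefined
  (error) for a nonpositive control slope. Because the two arms are
  different culture conditions, absolute densities are not directly
  comparable across arms — only the gradient ratio is interpreted. A
  *relative* density mode (each group rescaled by its 0 Gy mean) is also
  emitted for presentation.

## Dose metrics

DEF is the voxelwise mean of ratios (matching a "μ ± σ" style report), not
the ratio of mean doses; voxels with zero reference dose are excluded with a
warning and counted. SD is the sample SD. CN uses the inclusive ≥ comparison
("receiving" a dose level, standard DVH convention) and returns 0 when no
voxel reaches the threshold. CN ∈ [0, 1], equals 1 iff the at-dose region is
exactly the target, and is non-increasing when hot voxels are added outside
the target (property-tested). Default report percentages are 100 % and 90 %
of the prescription (70 Gy in the worked examples).

## Synthetic data

The generator emulates what matters to the algorithms, not the optics:

- nuclei: non-overlapping filled ellipses (semi-axes uniform in
  `nucleus_radius_range`, default 30–60 px; dose-series scenes use 28–40 px
  so ~16 nuclei fit a 512×512 frame), rendered with 2× supersampled
  anti-aliasing at intensity 0.7; a 12 px minimum gap keeps the closing step
  from bridging neighbors;
- foci: isotropic Gaussian spots (σ = 3 px, peaks uniform in 0.6–0.9, above
  the T_e = 0.55 gate) planted inside the ellipse with a 2σ+1 edge margin
  and ≥ 5σ pairwise separation so each spot is one regional maximum (the
  separation relaxes gradually, never below 2 px, if a crowded nucleus
  cannot host its count);
- noise: additive Gaussian (sd 0.02) on both channels, clipped to [0, 1],
  then 8-bit quantization — quantization after noise, as in acquisition;
- dose series: per-nucleus target density drawn from
  Normal(intercept + slope·dose, noise_sd), clipped at 0, realized as
  round(density × area) planted foci. Study conditions: doses
  {0, 0.25, 0.5, 1, 2} Gy, 200 objects per condition, control slope
  5·10⁻⁴ foci·px⁻¹·Gy⁻¹, intercept 2·10⁻⁴ foci·px⁻¹, object noise sd 10⁻⁴,
  planted slope ratio 1.46 — density magnitudes chosen to mirror the
  ~10⁻⁴–10⁻³ foci·px⁻¹ range such experiments display;
- dose grids: uniform low-dose background (30 % of prescription), the
  prescription inside a spherical target, optional nearest-shell spill
  voxels at prescription level, and a with-nanoparticle grid equal to the
  reference grid scaled by a known enhancement inside the target.

What the fixtures do **not** emulate: realistic PSFs and STED depletion
profiles, intensity heterogeneity within nuclei and foci, clustered/merged
foci, autofluorescence gradients, stitching artifacts and chromatic
misalignment. Passing the recovery tests therefore shows the algorithm chain
is correct and unbiased under its own assumptions, not that detection is
error-free on real micrographs — on real data the parameter optimization
step exists precisely because those assumptions fail gradually.

## Numerical choices and degenerate inputs

- Pixel coordinates are 0-based, row-major (row, column); channel order in
  TIFFs is never assumed (indices are mandatory; for 3-D stacks the channel
  axis is the shortest axis).
- Connectivity: 8-connected foreground, 4-connected background throughout
  (standard duality, avoids topological paradoxes).
- Rank filters use reflective (symmetric) border padding.
- Strict inequalities: the T_e gate (`> T_e`) and the outlier fences
  (values on the fence kept) follow the stated definitions.
- Ties: Otsu threshold → lowest candidate; focus attribution → lowest
  object label; optimization arg-max → lowest r_f, then lowest T_e.
- Degenerate inputs: constant nuclei channel → empty labeling (warning);
  constant restricted top-hat → zero foci; empty target masks, nonpositive
  control slopes, < 3 dose levels → typed errors.

## Problem sizes and verification

The test suite verifies the detector against an independent brute-force
oracle (shift-based Minkowski morphology, iterative geodesic reconstruction,
plateau flood-fill regional maxima, exhaustive threshold scans) with exact
count equality on 50 random ≤ 64×64 images, and runs the full two-arm
recovery study at 512×512 with 200 objects per condition — the same problem
size the acceptance script reports — recovering both planted gradients and
their 1.46 ratio within 5 % with R² > 0.99. Full-size 1880×1880 frames are
supported by passing `image_size`; nothing in the pipeline depends on frame
size beyond runtime.

## Known limitations

- Touching nuclei are counted as one object by design; the density statistic
  tolerates this, but extreme confluency shrinks the number of independent
  objects per condition.
- Foci are counted, not integrated; very bright merged foci within one
  regional maximum count once.
- The optimization criterion (dose-response linearity) presumes the
  underlying biology is linear over the calibrated range; it is not suitable
  for strongly saturating responses.
- DEF is voxelwise mean-of-ratios; the ratio-of-means alternative can be
  computed from the returned per-voxel distribution if needed.
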