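# Methods

## The measurement model

A nucleus is observed in two registered channels: DAPI (total DNA, used
for segmentation and normalization) and a whole-chromosome paint (the
territory signal). Two complementary quantifications of radial position are
implemented.

### Equal-area erosion shells (2D)

The nucleus mask is obtained from the DAPI channel by a global Otsu
threshold, keeping the largest connected component and filling holes.
Nuclei touching the lateral image border are rejected — shells and
periphery distances are undefined for clipped nuclei. A user-supplied mask
can bypass automatic segmentation (the historical workflow outlined nuclei
interactively; Otsu + largest-component is the deterministic, testable
replacement).

The mask is partitioned into `n_shells` (default 5) concentric shells of
equal area. Iterating a literal morphological erosion peels whole one-pixel
rings whose areas are unequal; to obtain exact equal areas the mask pixels
are instead ranked by their Euclidean distance to the background (distance
transform, pixel units) and the ranking is split into consecutive groups
whose sizes differ by at most one pixel. Ties in distance are broken by
row-major pixel index, making the partition fully deterministic; shell 1
holds the smallest distances (periphery). When the mask area is not
divisible by `n_shells`, the extra pixels go to the outermost shells.

Per shell, the summed DAPI and probe intensities are expressed as
percentages of their in-mask totals, and the normalized value is the ratio
probe% / DAPI%. Summed intensity (not thresholded pixel counts) is used
throughout. Background subtraction (the mode of the out-of-mask intensity,
estimated from a 256-bin histogram for continuous data, clipped at zero) is
available but off by default: the ratios are invariant to per-channel
scaling but not to additive offsets, so it matters when a camera pedestal
or autofluorescence floor is present. Normalized ratios are averaged as raw
ratios (not rescaled to percentages first); axes are labeled accordingly.

### Condition statistics

Per condition, the mean and SEM (sample SD / √n) of the normalized values
are computed across nuclei, shell by shell. Conditions are compared with
Welch's unpaired, unequal-variance, two-tailed *t*-test per shell
(Welch–Satterthwaite degrees of freedom). No multiple-testing correction is
applied across the five shells by default — matching the per-shell
*P* < 0.05 convention of erosion analyses — and a Bonferroni option exists.
Zero-variance degeneracies are resolved by convention: equal means → *P* = 1;
unequal means → *P* = 0, flagged as degenerate. Cohorts below 50 nuclei
trigger a warning (not an error), 50 being the conventional minimum for
this assay.

A mean profile is summarized by its shell center of mass
c = Σ k·mean[k] / Σ mean[k] and labeled peripheral (c ≤ 2.4), interior
(c ≥ 3.6) or intermediate. These thresholds are a package convention — no
published rule exists — and are configurable.

### 3D distance to the periphery

For z-stacks (axial step 0.2 μm by default, matching standard confocal
sampling of fibroblast nuclei), the nucleus is segmented volumetrically
with a single global Otsu threshold, per-slice hole filling and a 3D
largest-component step. Territories are segmented by Otsu on in-mask probe
intensities with 3D connected components; components under 20 voxels
(configurable) are discarded as speckle, and a deviation from the expected
count (2 for an autosome pair) warns.

Each territory's *geometric center* is the unweighted centroid of its voxel
set (not intensity-weighted), in μm. The periphery is the voxelized mask
boundary — mask voxels with a face-adjacent background neighbor — and the
distance is the exact minimum over boundary voxels of the anisotropic
Euclidean distance to the center. This minimum is evaluated directly
(vectorized over the boundary voxel list), so there is no
distance-transform resampling error; a plain-Python brute force serves as
the oracle in tests and agrees exactly.

Distances are reported raw and normalized by nucleus size: ÷ (major +
minor)/2 and ÷ major, where the axis lengths come from the moment-based
ellipse fit of the largest-area z-slice (the conventional 2D "major/minor
axis" reading; no 3D fit is attempted). Frequency-distribution curves are
histograms over distance bins (default width 0.5 μm raw, 0.05
dimensionless), one curve per condition.

## The synthetic scene generator

The generator emulates the statistical structure the analysis assumes — a
cohort of single-nucleus two-channel images with territories at a
controlled radial preference — so every downstream stage can be validated
against ground truth.

* **Nucleus.** An ellipse/ellipsoid (semi-axes in μm; default 10 × 7 μm in
  2D, 3.5 × 2.8 × 1.6 μm for the compact stacks used in 3D runs) with an
  optional low-order Fourier perturbation of the boundary radius
  (modes 2–4; amplitudes summing to `nucleus_irregularity`) to emulate
  non-elliptical, e.g. blebbed or herniated, nuclei. DAPI is a constant
  interior level with a sub-pixel linear roll-off at the rim, expressed as
  spatial distance to the boundary so segmentation recovers the analytic
  area to ~1–3%.
* **Radial coordinate.** A territory's position is drawn as a normalized
  radial coordinate r ∈ [0, 1] (0 = center, 1 = periphery) along a
  uniformly random direction; r is the *elliptical scale factor* — the
  point lies on the boundary contour shrunk by r — so it means the same
  thing along every direction, including for perturbed outlines.
* **Radial laws.** The named laws are Beta distributions on the enclosed
  *area fraction* q = r², because equal-area shells are uniform in q, which
  makes the names read directly in shell units: peripheral = Beta(8, 2) on
  q (shells 1–2), intermediate = Beta(5, 5) (around shell 3), interior =
  Beta(2, 8) (shells 4–5). A `("custom", α, β)` law is Beta on r itself,
  for direct control of the linear radial coordinate.
* **Territories.** Parametric blobs — isotropic Gaussian (σ =
  territory_radius/2, default radius 2.5 μm, a realistic paint-territory
  scale) or hard discs — two per nucleus by default (an autosome pair).
  Real territories are irregular; parametric blobs are sufficient to
  exercise shell assignment and distance measurement while keeping an exact
  ground truth.
* **Noise.** Additive Gaussian (default SD 5 against a DAPI level of 120
  and probe peak of 150, i.e. 8-bit-like levels with moderate noise),
  clipped at zero. Photon (Poisson) statistics, PSF convolution, chromatic
  shift and photobleaching are deliberately out of scope: the analysis
  consumes intensity ratios, not shot-noise-limited estimates. No published
  intensity statistics exist for these channels, so the levels are free
  parameters chosen once as above.
* **Reproducibility.** All randomness flows from `(seed, nucleus index)`
  through a counter-based generator: identical config + seed gives
  bit-identical rasters; territory placement is drawn before the noise
  field, so changing only `noise_sd` perturbs rasters but never the ground
  truth.

What passing tests on these scenes do **not** show: robustness to real
segmentation failure modes (touching cells, uneven illumination,
out-of-focus planes), to irregular territory shapes, or to chromatic
misregistration. The generator validates the measurement logic, not the
microscopy.

## Problem sizes and numerical choices

Synthetic validation runs use 50 nuclei per 2D condition and 20 stacks per
3D condition — the conventional cohort sizes for these assays — with
128 × 128 px 2D scenes (0.2 μm/px) and 32 × 96 × 96 stacks (0.2 μm axial,
0.1 μm lateral); these sizes make the full validation suite run in well
under a minute while keeping ≥ 1,000 mask pixels per shell. Partition
determinism rests on the (distance, row-major index) tie-break; the
equal-area property is exact by construction (≤ 1 px spread). Degenerate
inputs fail loudly with stage-specific exceptions: blank DAPI, masks
smaller than the shell count, zero probe signal, territory centroids
outside the mask, empty cohorts.

## Known limitations

* Single-nucleus inputs only; no multi-nucleus scene splitting.
* Automatic segmentation assumes a bimodal DAPI histogram; dim or highly
  textured nuclei may need the manual-mask bypass.
* The peripheral/intermediate/interior label thresholds (2.4 / 3.6 on the
  shell center of mass) are a convention of this package.
* The 3D periphery is the voxelized mask surface, not a smoothed contour;
  distances carry up to ~one voxel diagonal of discretization error.
* Shell counts other than 5 are supported but untested against any
  published convention.
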