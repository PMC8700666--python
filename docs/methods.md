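# Methods

This note describes the models, estimators and numerical choices behind
`icemorph`, and what its synthetic validation does and does not demonstrate.

## Problem setting

Frozen highly porous foods (the motivating system is a model sponge cake:
a starch matrix with ~60% air porosity, macropores up to ~1 mm) develop ice
in two distinct locations during freezing: as crystals embedded in the
matrix, and as a conformal layer on the pore walls where water vapor
condenses (evapo-condensation). Synchrotron micro-CT resolves air, ice and
starch as three well-separated grey-level modes, so the analysis chain is:

1. two-threshold segmentation into air / ice / starch;
2. morphological closing of the starch phase with a ball (default radius
   16 voxels) to build the *matrix* — the filled starch phase;
3. boolean localization of ice: `ice_inside = ice AND matrix`,
   `ice_outside = ice AND NOT matrix`;
4. morphometric descriptors: volume fractions, vertical profiles, specific
   surface area (SSA), local thickness, mean curvature, REV convergence.

The defining fractions are

    phi_air          = V_air / V_total
    phi_ice_in_solid = V_ice / (V_ice + V_starch)
    phi_ice_outside  = V_ice_outside / V_ice

computed from exact integer voxel counts. A 0/0 (e.g. the ice-outside share
of an unfrozen sample) is reported as absent, never as 0.

## Synthetic phantoms

No raw tomogram of the real product is publicly available, so all
quantitative validation runs on synthetic volumes with exact ground truth.
The generator composes, from a single seeded RNG in fixed draw order:

* **Pore space** — a Gaussian random field (white noise smoothed with a
  Gaussian of `pore_scale / (2·voxel_size)` voxels) thresholded at the
  empirical quantile of the target porosity. This gives a stationary,
  connected, multi-scale pore space whose air fraction matches the target to
  well under ±0.02, with one free correlation length (`pore_scale`, default
  100 µm at 2 µm/voxel in a 200³ domain — no quantitative pore-size
  distribution is available for the real product, so this is a realism
  choice, not a measurement).
* **Wall ice** — all air voxels within `round(thickness/voxel_size)` voxels
  (Euclidean distance) of the solid; a conformal shell, disjoint from the
  solid by construction. A thickness exceeding the local pore radius closes
  pores; this warns rather than fails, since it is physically meaningful.
* **Embedded crystals** — axis-aligned cuboids with per-axis edges uniform
  in a size range, centers uniform over the solid voxels, clipped to the
  solid eroded by 2 voxels. The margin makes the ground-truth label
  "ice inside" unambiguous: crystals never touch the pore space, which is
  what the closing-based localization can in principle recover. Real
  crystals partially breach pore walls; for such voxels the inside/outside
  dichotomy is itself ill-defined and no ground truth could adjudicate it.
* **Rendering** — per-phase mean grey value (air darkest, ice intermediate,
  starch brightest; both ice classes share one mean), additive Gaussian
  noise, optional Gaussian blur for the imaging point-spread.

Two presets fix the study conditions: **fast freezing** (4 µm wall film,
many small crystals, 20–45 µm) and **slow freezing** (25 µm wall layer —
the observed 20–30 µm range — fewer larger crystals, 30–60 µm). Crystal
*number density* is the preset constant; the count scales with domain volume
so reduced-size phantoms keep the same statistics. The slow-preset crystal
range is capped at 60 µm so that every crystal's smallest edge stays below
the closing ball diameter (64 µm at the default scale): the real prismatic
crystals are thin in at least one dimension relative to the closing ball,
and a phantom violating that would make the matrix construction fail by
design rather than test it.

What phantom tests demonstrate: the estimators recover known geometry and
composition through the full chain at realistic noise. What they do not
demonstrate: performance on real tomograms with reconstruction artifacts,
grey-level drift, partial-volume voxels at 0.65 µm, or nanoporosity below
the resolution limit.

## Segmentation

Default thresholds are the three-class within-class-variance minimizer
(multi-Otsu) on a 256-bin histogram. Before thresholding, modes are counted
on a smoothed histogram (Gaussian sigma 3 bins, 1% prominence); fewer than
three detectable modes raises a degenerate-histogram error directing the
user to manual thresholds — automatic two-threshold output on an unfrozen
(air/starch) volume would silently invent an ice phase. Threshold
boundaries are half-open, lower-inclusive on the brighter class (a voxel
exactly at a threshold joins the brighter phase); the convention is
arbitrary but fixed so results are bit-reproducible.

Closing uses a digitized Euclidean ball (voxel included iff its center is
within the radius), evaluated through the exact Euclidean distance
transform: dilation is `dist_to_set <= r`, erosion is `dist_to_complement
> r`. This is identical to Minkowski dilation/erosion with the explicit
ball (asserted against `scipy.ndimage` in the tests) and much faster at
radius 16. The volume is padded with background before dilation and cropped
after erosion, so no artificial matrix forms at the faces; the price is
that matrix bridges within one radius of a face erode, so analysis cubes
should be comfortably larger than the closing ball. Closing is extensive
and idempotent exactly; it is *not* perfectly monotone in radius — digitized
balls do not form a granulometry, and single-voxel exceptions occur (the
explicit-ball reference reproduces them identically).

The ice partition intersects ice with the **closed** starch phase. The raw
starch and ice phases are disjoint, so intersecting with unfilled starch
would always be empty; the closed phase is the only reading under which the
localization is meaningful.

## Specific surface area

SSA is interface area divided by total analysed volume (the cropped
analysis cube, not any larger parent scan), reported in mm⁻¹. Area is
estimated by a 13-direction Crofton/intercept formula: phase-pair
transitions are counted along the 3 axis, 6 face-diagonal and 4
body-diagonal direction classes and combined as
`sum_k w_k * T_k * v² / |d_k|`. The three direction-class weights are
calibrated by requiring (i) exact response for axis-aligned interface
normals, (ii) zero bias for isotropically oriented surfaces
(`sum w_k = 2`), and (iii) equal residual on the two diagonal normal
families. Classical tabulated 13-direction weights are isotropically
unbiased but under-measure axis-aligned planes by ~7%; this calibration
trades that for a ~8% under-response confined to exactly diagonal normals,
which integrates out on curved surfaces. Measured behavior: digitized
sphere (r = 20 vx) within 0.5% of 4πr², axis-aligned plane within 1.5% at
N = 100 (the residual is an O(1/N) border effect of finite test lines, not
bias). A marching-cubes mesh area serves as an independent cross-check in
the tests, never as the estimator.

## Local thickness

Local thickness at a foreground voxel is the diameter of the largest sphere
that fits in the foreground and covers the voxel. With `EDT(y)` the exact
Euclidean distance to background, the map is
`2 · max{ EDT(y) : |x−y| <= EDT(y) }`. Computing that by painting every
voxel's sphere is quadratic; instead, spheres contained in a 26-neighbor's
sphere are discarded first (containment `|y−z| + r_y <= r_z` decided in
exact integer arithmetic on squared distances — removal is transitive, so
this is lossless), and only the surviving distance-ridge voxels paint their
spheres, largest radius first. The result is bit-identical to the
exhaustive sphere-fitting oracle (property-tested on random ≤16³ masks) at
a small fraction of the cost (~15 s per phase on a 200³ volume). Thickness
distributions are cumulative and volume-weighted: the value at diameter d
is the percentage of foreground voxels with thickness ≤ d; bin width
defaults to one voxel.

## Mean curvature

The binary phase indicator (1 = material: ice and/or starch) is smoothed
with a Gaussian (`sigma_vx`, default 2 voxels — below ~1 voxel the
derivatives are noise-dominated and a warning is emitted); the interface is
the 0.5 iso-surface, triangulated by marching cubes. At each vertex the
gradient g and Hessian H of the smoothed field (central differences,
trilinearly interpolated) give

    C = -1/2 · (|g|² tr H − gᵀHg) / |g|³        (mean curvature)
    K = gᵀ adj(H) g / |g|⁴                      (Gaussian curvature)

with the sign fixed by the outward material normal −g/|g|: material bulging
into the air is positive, concave pore walls negative — a spherical air
pore of diameter 1 mm in solid has C = −2 mm⁻¹. Principal curvatures are
`C ∓ sqrt(C² − K)` and the reported mean is their average by construction.
Each vertex carries an area weight of one third of its incident triangles'
area; occurrence-ratio histograms weight by area and sum to 100% (default
bin 0.5 mm⁻¹). Accuracy on analytic shapes at default smoothing: sphere and
cylinder within ~2%, flat slab indistinguishable from zero; the complement
of a mask flips the sign pointwise. Interfaces that touch the volume faces
are kept; their derivative quality degrades within ~2 voxels of a face.

## REV analysis

For each requested cube edge, one centered sub-volume per replicate volume
is cropped and the phase fraction computed; the reference is the mean ± std
of the full-volume fractions across replicates. The smallest representative
size is the smallest edge from which the curve stays inside the tolerance
band (absolute, or the ± std band) through all larger sizes. Centered
placement mirrors one-point-per-size practice; it is the minimal reading of
an under-specified protocol, and the spread across replicate volumes (not
across placements) provides the uncertainty.

## Thermophysics

Closed forms, with validation limits: water content `(m0−mf)/m0·100`;
freezable water `ΔHw/(ΔHi·Tw)·100` with ΔHi = 334 J/g and **Tw a mass
fraction** — a percent entry is rejected, since only the fraction reading is
dimensionally consistent with the published result (124 J/g and 0.60 give
62%) — and values above 100% rejected as unphysical; mixture density by
harmonic mass-fraction mixing over components of known density (stabilizers
without density data are excluded from both sums); porosity
`(1 − ρ_apparent/ρ_theoretical)·100`. Converting freezable water to an ice
volume fraction requires density assumptions that are not available and is
deliberately not implemented.

## Aggregation and reporting

Condition statistics are arithmetic mean ± sample std of *per-volume*
fractions (never ratios of pooled voxel counts); std is absent for n = 1.
Headline location shares (e.g. "69% of the ice is inside the matrix") are
`100 · mean(numerator fraction) / mean(denominator fraction)` rounded to
the integer. ANOVA/multiple-comparison letters are out of scope; the
per-volume CSVs contain everything needed to run them externally.

## Problem sizes and determinism

Default phantom domain is 200³ voxels at 2 µm (a 0.4 mm cube); the test
suite runs phantom-based checks at 120³ with volume-scaled crystal counts,
and curvature/SSA analytic checks at 100³. All randomness flows from
per-spec seeds through `numpy.random.default_rng`; identical configs give
bit-identical volumes, labels and CSV outputs. Known limitations: no
reconstruction artifacts or intensity drift in the rendering model;
axis-aligned crystals only; curvature is undefined (and skipped) for masks
without an interface; SSA and curvature carry O(1/N) border effects on
interfaces that span the volume faces.
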