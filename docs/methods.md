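# Methods

This note documents the models inside `petlesionsim`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a user extending the package should know about.

## Digital head phantom

The phantom is analytic: nested ellipsoids form skin/scalp, a skull shell
and the brain, all on a configurable grid (default 128 × 128 × 16 voxels at
2 mm — a head "slab" whose every axial slice cuts the brain, so in-plane
physics is fully represented while the axial extent stays desk-scale). The
outer 8 mm of brain is a cortical ribbon split into named angular sectors
mimicking a FreeSurfer parcellation (15 ribbon sectors by default), plus one
deep gray region, the fusiform analogue, centered in the white matter. This
yields the two probe locations that matter for attenuation-correction
studies: `superior_frontal` touching the skull and `fusiform` far from it.

Tissue values:

- HU — air −1000 outside the skin; scalp drawn once per subject from
  U(20, 60); brain from U(25, 45); skull from U(700, 1200). The bone range
  deliberately spans the supra-break segment of the bilinear HU→LAC model.
- Emission — piecewise constant per region: white matter 1.0 (arbitrary
  Bq/mL scale), gray regions `gray_white_ratio ×` that. The default ratio
  4:1 is a conventional gray/white contrast for brain tracers; regional
  uptake of amyloid tracers varies with pathology, so this is a free
  parameter, not a claim about any tracer.
- The ground-truth attenuation map is exactly `hu_to_lac(ct)`.

Cohorts jitter head size (±5 %), skull thickness (±20 %) and per-region
activity (±10 %) per subject, with every draw reachable from one master
seed. `cohort(config, n, master_seed)` is a loop over
`derive_subject(config, master_seed, i)`, which returns the jittered
per-subject config *and* seed, so any subject can be regenerated in
isolation.

What the phantom does **not** emulate: realistic anatomy (gyri, CSF,
sinuses, heterogeneous marrow), MRI contrast, registration error between
modalities, or head motion. Tests passing on this phantom demonstrate the
pipeline's physics and statistics are correct; they do not certify any
specific clinical MRAC product.

## Attenuation maps

CT numbers convert to 511 keV linear attenuation coefficients with the
standard two-segment model: below the break (0 HU) a line through the air
(−1000 HU → 0) and water (0 HU → 0.096 cm⁻¹) anchors; above it a bone slope
of 5.1 × 10⁻⁵ cm⁻¹/HU, a conventional 120 kVp value. Both slopes, the break
and the 0.3 cm⁻¹ clip are configuration, since vendor constants are
kVp-specific and not standardized.

The four MRAC families are parametric degradations of the truth rather than
MRI simulations — what the downstream bias evaluation probes is bone
fidelity, so the emulations are designed to reproduce the clinically
established fidelity ranking (DIXON worst, then UTE, DIXONbone, DL-DIXON
best, measured as whole-volume LAC RMSE):

| method     | degradation                                                      | default |
|------------|------------------------------------------------------------------|---------|
| dixon      | skull voxels replaced by soft-tissue LAC (bone invisible)        | 0.096 cm⁻¹ |
| dixonbone  | continuous bone LAC scaled by `bone_scale`, outer table peeled by `bone_erosion_mm` | 0.9, 1 mm |
| ute        | binary bone compartment at one conservative LAC, `misclass_frac` of boundary voxels flipped (skull→soft on the bone side, scalp→bone outside) | 0.12 cm⁻¹, 5 % |
| dl_dixon   | truth + voxelwise Gaussian LAC noise                             | σ = 0.002 cm⁻¹ |

Two implementation details matter. The DIXONbone erosion peels only the
*outer* table of the skull (per-slice fill + in-plane erode): a plain
erosion would eat a thin shell from both faces and destroy it, and outer
under-segmentation is the realistic failure mode of model-based bone. The
UTE misclassification never touches brain voxels, so all segmentation-based
maps equal the truth exactly on brain interior — reconstruction differences
are attributable to bone handling alone.

## Projector and system model

The scanner is a generic multi-slice 2-D parallel-beam geometry: `n_radial`
signed offsets (default 1.5 × nx bins of one voxel pitch, centered on the
grid) × `n_angles` uniform views over [0, π) × one sinogram slice per image
slice. Rays are traced with an exact Siddon voxel-intersection-length
traversal, assembled once into a cached sparse matrix; back projection is
the literal transpose, so the forward/back pair is adjoint to machine
precision (the EM convergence guarantee depends on this). No oblique
planes, TOF, randoms, detector gaps or depth-dependent blurring are
modelled; the near-bone bias physics under study is geometry-agnostic.

Attenuation factors are `exp(−Σ μℓ)` with μ in cm⁻¹ and traced lengths
converted mm→cm. Normalization is a user-suppliable factor sinogram
(default uniform). The point-spread function is an isotropic image-space
Gaussian (default FWHM 4 mm) applied before projection; edge effects are
renormalized and the image total restored exactly, and a FWHM under half a
voxel is treated as the identity.

Scatter is a broad radial Gaussian blur (default FWHM 80 mm) of the trues
per view and slice, rescaled so scatter/(trues+scatter) equals the
configured scatter fraction (default 0.30) exactly. This reproduces the two
properties that matter downstream — a smooth additive background at a
controlled fraction — without a single-scatter simulation.

Calibration: expected counts = line integral (Bq/mL·mm) × attenuation ×
normalization × `sensitivity` × `duration_s`. Defaults (0.005 counts per
Bq/mL·mm·s, 600 s) put peak background bins near a few hundred counts, a
realistic static brain-PET noise level for the default phantom activities.

## Insertion and conditions

Lesions are binary masks (voxel-center sphere membership, or exact atlas
label equality) given absolute activity or a lesion-to-background ratio
(LBR × mean background inside the mask; default two 4 mm-radius LBR = 2
spheres at the `superior_frontal` and `fusiform` centroids). The chain up to
the Poisson draw is linear, so all lesions are projected in one pass, and
the identical expected-count sinogram feeds both merge modes:

- `with_background`: background counts + Poisson(lesion + scatter);
- `lesion_only`: Poisson(lesion + scatter) alone;
- `replace`: background zeroed on the lesion footprint (bins above 10⁻³ ×
  the sinogram maximum — the support threshold is a package choice) and the
  draw substituted there.

The evaluated conditions are `with_background`, `lesion_only`, and
`original` (the lesion-free background reconstructions scored with the same
ROI masks). All three run through the same scoring code path.

## Reconstruction

Classic OSEM with the multiplicative update

    x ← x · Pᵀ_S( f · y / (f · P_S x + s + ε) ) / Pᵀ_S f,   f = a·n·c

per angle-interleaved subset (angle i → subset i mod n_subsets). The
calibration constant c is folded into f, so the iterate is in activity
units. Defaults: 3 iterations × 21 subsets, 4 mm post-filter; 24 subsets
(the other commonly quoted configuration) is one config field away. Scatter
enters as a known additive term; ε = 10⁻¹² guards every division; voxels
with zero total sensitivity are frozen at 0, and voxels a single subset
cannot see keep their value for that sub-iteration. With one subset the
update is exact MLEM, whose Poisson log-likelihood ascent is asserted in the
tests.

`reconstruct_all` reconstructs the *same* count sinogram under all five
maps; only the attenuation factors differ.

## Statistics

Bias is reported in percent. Cohort summaries use linear-interpolation
quantiles. Method comparisons are two-sided paired t-tests (scipy) of
per-subject absolute bias against the reference method (default
`dl_dixon`), with Benjamini–Hochberg step-up adjustment (statsmodels); all
p-values produced in one call form a single BH family, and zero-variance
difference vectors get p = 1.0 with a warning. The test suite holds the BH
implementation against a brute-force step-up oracle.

## Problem sizes

The default experiment grid is 128 × 128 × 16 at 2 mm with 128 views (a
single subject runs in seconds on one CPU); the bundled smoke configuration
(64 × 64 × 8 at 3 mm, 48 views, 2 OSEM iterations, 5 subjects) drives the
cohort-level tests and the acceptance script. These sizes were chosen so the
full validation loop is interactive at a desk while keeping ≥ 2–3 voxels
across every modelled structure (skull 6 mm, ribbon 8 mm, 4 mm-radius
lesions).

## Known limitations

- Static acquisitions only; no dynamic-frame noise, decay, randoms or
  dead-time.
- Parallel-beam geometry: absolute count levels and noise correlations are
  not those of any specific cylindrical scanner.
- The MRAC emulations reproduce the *ordering and rough scale* of bone
  fidelity, not any vendor implementation; absolute bias magnitudes depend
  on the degradation parameters.
- Inputs consumed as user volumes must be pre-registered on a common grid;
  no registration is performed.
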