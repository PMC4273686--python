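# Methods

## Phantom geometry and voxelization

All phantoms are described analytically (spheres, spherical shells, unions
of balls) in a right-handed millimetre frame with the origin at the phantom
centre, then rasterised with a single digitization rule: a voxel belongs to
a region iff its centre lies inside the analytic surface (boundary
inclusive). This rule was chosen because it admits an exact independent
oracle — a brute-force per-voxel scan — used throughout the tests; the
voxelized volume of a sphere then differs from (4/3)π(d/2)³ by at most one
surface-shell volume and converges to it under grid refinement in the mean.

The NEMA IQ body is approximated as a 230 mm × 180 mm cylinder (the
interior dimensions of the torso shell); its six spheres sit on the
standard 57.2 mm-radius circle at 60° spacing with background 5.2 kBq/ml.
The synthetic cylinder (300 × 221 mm) carries its lesions on a 114.4 mm
radius ring around the central transaxial slice — the exact radial/angular
placement is not critical and is configurable; 114.4 mm clears the body
wall even for the 42 mm necrotic shells. Irregular lesions are seeded
unions of 3–7 overlapping balls with base radii log-spaced from 4 to 17 mm,
giving union volumes spanning roughly the 7–37 mm sphere-volume range;
uptake is uniform inside the union. This reproduces the qualitative
"the less spherical, the harder to delineate" behaviour without requiring
patient-derived contours.

## Image emulation

The emulator is deliberately an image-domain linear chain, not a sinogram
simulator:

1. trilinear resampling to the target matrix (200×200 at 4.073 mm or
   400×400 at 2.036 mm in-plane, 2.027 mm slices) when needed — ground
   truth is always re-voxelized analytically, never resampled;
2. isotropic Gaussian blur at the protocol's effective PSF FWHM;
3. Poisson noise: expected counts per voxel are the blurred activity times
   voxel volume scaled so the image total equals the requested true-count
   level; counts are drawn as `Poisson(λ/g²)·g²` so the relative noise is
   multiplied by the gain `g`; `g = 0` disables noise;
4. Gaussian post filter.

Protocol presets (`OP` 6.5/5.0 mm, `OP+TOF` 5.5/2.0 mm, `PSF` 4.5/2.0 mm,
`PSF+TOF` 4.0/2.0 mm PSF/post-filter FWHM) are emulation presets chosen to
span a clinically plausible resolution range and to order the
recovery-coefficient curves the way those reconstruction families order on
real scanners; they are not measured scanner values.

The default noise gain is √(8/3) ≈ 1.633, derived from the
noise-equivalent-count argument for an acquisition with randoms at 5/3 of
the true-coincidence rate (5.0·10⁷ randoms per 3.0·10⁷ trues, and the same
ratio at the doubled level): NEC = T²/(T+R) implies relative noise inflated
by √((T+R)/T). Randoms and scatter are folded into this single factor
rather than simulated. Replicate images are seeded from
`(base_seed, replicate_index)` and are bit-reproducible.

What the emulator does **not** model: attenuation, scatter gradients,
iterative-reconstruction noise correlation and edge overshoot (Gibbs
ringing from PSF modelling), axial sensitivity profiles, and motion.
Consequently absolute accuracies here are higher than on scanner data
(mean SI up to ~0.99 for large spheres versus ~0.83 reported on physical
phantoms) and passing directional tests says nothing about absolute
clinical performance — only about orderings and trends among methods under
partial-volume blur and Poisson noise.

## Delineation methods

All methods operate inside a bounding VOI enclosing exactly one object
(default: the ground-truth bounding box dilated by 3 voxels per axis).
Thresholds are inclusive (≥), and no connected-component filtering is
applied by default — a deliberately literal rule that reproduces the
characteristic background flooding of fixed thresholds on low-contrast
lesions; a largest-component option exists behind a flag.

* **T40/T50**: `T = f·SUVmax`.
* **AT40/AT50**: `T = f·(SUVmax − BG) + BG`, where BG is the mean of a
  spherical background ROI of 20 voxels diameter (index-space ball,
  centre-inclusion rule). If SUVmax ≤ BG the method warns and returns an
  empty mask.
* **CT (contrast thresholding)**: `T = a·mSUV70 + b·BG` with mSUV70 the
  mean over VOI voxels ≥ 0.7·SUVmax. The regression has no intercept.
  Calibration: for each phantom object with known ground truth, the optimal
  threshold is the one of 200 evenly spaced values between BG and SUVmax
  whose thresholded volume is closest to the true volume (ties resolve to
  the lower threshold — deterministic and resolution-independent); (a, b)
  then solve the intercept-free least squares over all calibration objects.
  An all-zero-background design is rank deficient; an a-only fallback is
  available behind a flag.
* **FLAB** is registered as unavailable: the registry lists it so harness
  runs record its tasks as `unavailable` rather than failing, and the stub
  raises an error pointing at the external implementation.

## Harmonisation (EQ.PET-style filtering)

Recovery coefficients are measured per sphere as
`RC = (max within the 1-voxel-dilated ground-truth region − background) /
(true activity − background)`; max-in-neighbourhood is used rather than
SUVpeak for simplicity and determinism. The harmonising filter for a
protocol is the FWHM in [0, 12] mm minimising the RMSE between its
(replicate-averaged) RC curve and a reference curve, found by bounded 1-D
minimisation to < 0.05 mm with both endpoints checked; ties resolve to the
weaker filter (relevant because sub-voxel FWHMs are numerically identity).
The reference is the RC curve of the lowest-resolution preset (`OP`),
mirroring harmonisation toward a common, less-resolved target. Filtering is
applied before delineation for all methods except CT, whose calibrated
parameters are already protocol-specific.

Because Gaussian blurs compose in quadrature, injecting a known extra blur
into the reference gives an exact recovery oracle (a 5 mm injection must be
recovered to ±0.3 mm), which the tests use.

## Validation and summaries

SI is Dice overlap; two empty masks score 1 (perfect agreement on absence)
and the case is flagged by construction since volumes are also reported.
%VE uses the analytic sphere volume as truth for the NEMA phantom and the
voxelized input-mask volume for synthetic phantoms. CV uses the sample SD
(n−1); the paper-style size groups are small (≤ 13 mm) versus large
(> 13 mm), applied to sphere diameter, necrotic-core diameter, or the
volume-equivalent diameter of irregular lesions. Confidence half-widths are
1.96·SD. Necrotic-core scoring extracts the core estimate as the
morphological hole of the delineation (binary fill minus the delineation) —
the package's interpretation, since no extraction rule is standard; an
exact shell therefore scores 1 on both targets and a solid ball scores 0 on
the core. Box-plot analogues are emitted as tidy quartile tables, not
rendered figures.

## Harness

The experiment grid expands deterministically (lesion → contrast →
protocol → counts → replicate → matrix). Per-condition seeds derive from a
single base seed through `numpy` `SeedSequence` spawning, are recorded in
the results table, and make `results.csv` byte-reproducible. CT calibration
and EQ.PET fitting are performed inside each run from NEMA-sphere
acquisitions simulated under the same protocol presets (per protocol and
matrix), mirroring how both would be commissioned from phantom scans in
practice. The default grid ships three count levels (3.0·10⁷, 4.5·10⁷,
6.0·10⁷ trues); only the outer two are physically specified — the middle
level is a placeholder completing the ×3 count factor of the full 2,880
object factorisation and can be replaced freely.

## Problem sizes used in the shipped tests

The reduced benchmark grid used by the directional tests is the seven-sphere
cylinder phantom at 4:1 and 8:1 contrast, all four protocol presets, one
count level (3.0·10⁷), three replicates, 200×200 matrix with 55 slices —
168 objects, ~1,500 delineations, about 20 s end to end. Unit-test phantoms
use coarser 4 mm lattices. These sizes were chosen to keep the whole suite
fast while leaving every factor of the full grid exercised; the full
2,880-object NEMA factorisation is expanded and counted but not simulated
in the tests.

## Known limitations

* Linear Gaussian resolution model: no PSF-reconstruction overshoot, so
  effects that depend on SUVmax overshoot on real scanners (e.g. strong
  volume underestimation by adaptive thresholds on large spheres) are
  attenuated here.
* White (voxel-independent) Poisson noise before the post filter; real
  OSEM noise is spatially correlated and object-dependent.
* Background is homogeneous; background-ROI placement variability, a known
  clinical issue for AT/CT, is not modelled.
* The NEMA torso shell and lung insert are simplified to a uniform
  cylinder.
* FLAB and gradient/watershed methods are out of scope; CT calibrated on
  the same conditions it is evaluated on is optimistic by construction,
  exactly as when a site calibrates on its own phantom scans.
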