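# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `fidreg`, in the package's own terms.

## Rigid-transform conventions

A rigid transform is `p → R (p − c) + c + t`: rotation `R` about an
explicit reference point `c`, then translation `t`.  Carrying `c` on the
transform (rather than fixing it at the origin) matters because isocenter
residuals are defined for transforms referenced to the machine isocenter;
`rereference` moves `c` without changing the mapping
(`t′ = t − (I − R)(c′ − c)`).

The 6D parameterization `(tx, ty, tz, rx, ry, rz)` uses millimeters and
degrees, with `R = Rz(rz) · Ry(ry) · Rx(rx)` about **fixed** room axes
(extrinsic x-y-z), right-handed, angles positive counter-clockwise
looking down the axis toward the origin.  `rx`/`ry`/`rz` are pitch, yaw
and roll about the couch lateral, vertical and longitudinal axes.  In
the ±3° regime of couch corrections the composition order is a
second-order effect, but one order must be pinned for reproducibility;
commercial platforms do not all document theirs, so cross-vendor per-axis
rotation components should be compared with that caveat in mind.  Euler
decomposition refuses inputs within 1e-6° of the |yaw| = 90° gimbal
singularity (never approached here); pitch and roll may reach a quarter
turn, yaw must stay below it, which keeps the parameterization bijective
where it is used.

## The point-match solver

The compute-group ("C") markers are paired **by id** between the two
frames — never by row order, so re-sorted marker files cannot silently
mispair.  The solver centers both clouds, takes the SVD of the
cross-covariance `H = A′ᵀB′ = U S Vᵀ`, and returns
`R = V diag(1, 1, det(VUᵀ)) Uᵀ`, `T = b̄ − R ā`.  Numerical choices:

- **Reflection correction.**  The unconstrained Procrustes optimum can be
  a reflection when noisy markers are nearly coplanar; the `diag(1,1,±1)`
  factor always returns the best *proper* rotation.  The test suite
  engineers mirrored near-coplanar clouds to exercise this branch.
- **Collinearity guard.**  Fitting requires the ratio of the second to
  the first singular value of the centered compute-group coordinates to
  exceed 1e-6 (scale-free).  Coplanar-but-not-collinear configurations
  are solvable and accepted by the solver itself; the stricter
  `MarkerCloud.validate` (both trailing singular values above 1e-6 of the
  leading one) is applied to generated layouts and file input, where a
  well-conditioned 3D spread is what a physicist should demand.
- **Weighting.**  All markers weigh equally; no per-marker weighting is
  offered.

Two independent solvers exist for verification only: Horn's quaternion
closed form (largest eigenvector of the 4×4 profile matrix) and a
vectorized exhaustive grid over Euler triples with centroid-matched
translation.  Tests require SVD/quaternion agreement to 1e-9 and that the
SVD cost never exceeds the grid minimum.

## Error metrics

- **FRE** (mm): `||R a_i + T − b_i||` over the fitted markers, summarized
  as rms.  It measures goodness of fit and is insensitive to marker
  configuration.
- **FLE** (mm): estimated as `sqrt(n/(n−2)) · FRE_rms` (Sibson's
  approximation).  The relation is between *expectations*; the sample rms
  stands in for the expectation, and the package's Monte-Carlo tests
  confirm the ratio `⟨FLE²⟩/⟨FRE²⟩ = n/(n−2)` to within 3% at 10,000
  replicates.  FLE is reported as a total 3D value; no per-axis
  decomposition is attempted.
- **TRE / rmsTRE** (mm): residuals at validation ("V") markers that never
  entered the fit, and their per-setup rms.  Any id overlap between the
  validation set and the fitted markers raises `LeakageError` — a hard
  failure, because leakage silently biases TRE low.  TRE is accepted for
  any number (≥1) of validation markers; only *fitting* needs three.
- **IRE** (mm / degrees): with both transforms re-referenced to the
  isocenter, the residual `Δ = method ∘ PM⁻¹` gives the signed per-axis
  translation at ISO (`Δ`'s translation is exactly the displacement of
  ISO), the per-axis Euler rotation residuals, and the axis-angle
  magnitude of `ΔR`.  This composition makes IRE exactly zero for a
  perfect method and reduces to plain differences for pure translations.
  IRE is invariant to the (common) reference point the two input
  transforms arrive with; the axis-angle magnitude is computed through a
  quaternion, which is well conditioned near identity.

The lever-arm effect ties the two views together: a rotation residual δ
about ISO displaces a point at perpendicular distance d by
`2 sin(δ/2) · d`, so surface markers far from ISO feel rotation errors
that the target near ISO does not — which is why rmsTRE (surface) and
IRE translation (ISO) can rank methods differently.

## The synthetic phantom experiment

The generator emulates the *design* of a two-phantom accuracy study:

| parameter | default | rationale |
|---|---|---|
| cranial markers | 13 = 8 C + 5 V on an ellipsoid shell (75/95/70 mm semi-axes) | head-phantom-sized surface, counts of the emulated study design |
| body markers | 8 = 5 C + 3 V on a cylinder shell (r = 140 mm, ±120 mm, anterior ±110°) | torso-sized surface reachable by markers |
| rotation limit | ±3° per axis, uniform | 6DoF couch correction range |
| translation box | ±10 mm per axis, uniform | typical setup displacement scale (the studied designs state only the rotation limit) |
| localization noise | total 3D σ = ⅓ × max voxel dimension, isotropic (per-axis σ = total/√3) | the empirical "FLE ≈ one third of the largest pixel dimension" rule |
| cranial voxels | planning CT 0.6×0.6×1.25 mm, CBCT 0.7×0.7×1 mm | high-resolution cranial protocol |
| body voxels | planning CT 0.8×0.8×2 mm, CBCT 0.9×0.9×1 mm | body protocol |
| isocenter | cranial (8, −25, −12) mm; body (0, −30, 45) mm | an interior point near the marker centroid, as in clinical target placement |

Layouts are drawn with a minimum marker spacing (25 mm cranial, 40 mm
body) and re-drawn until the second-moment tensor has all pairwise
eigenvalue gaps above 3% — a scale-free test that rejects reflective or
rotationally symmetric placements, which would make correspondence
ambiguous in a real workflow.  C/V assignment is a seeded permutation,
fixed per layout.  Noise can optionally be anisotropic
(σ_axis = fraction × voxel_axis), reflecting that slice thickness exceeds
pixel size; the isotropic default keeps the Sibson Monte-Carlo exactly
comparable to its closed form.  A `noise_free=True` flag — rather than a
zero fraction, which is rejected — produces exact clouds for calibration
runs.

Virtual platforms are parameterized error models (per-axis Gaussian σ and
bias for translation and rotation, applied about ISO on top of the ground
truth).  The real platforms a study of this kind measures are black
boxes; here their error magnitudes are *inputs*, so a simulation can
demonstrate the pipeline and the statistics but can never validate a
commercial platform.  The shipped `demo_platform_models()` are calibrated
to the order of accuracy reported for volumetric, stereoscopic-X-ray and
optical-surface registration of rigid phantoms (sub-half-mm /
a-few-tenths-more / ~1 mm with a systematic surface offset) and are
labeled as demonstration values.

What passing tests therefore show: the solver, metric definitions, error
propagation and statistics behave correctly under the stated noise model.
What they do not show: performance on real images, where localization
error is anisotropic and non-Gaussian, marker placement interacts with
anatomy, intensity- and surface-based algorithms fail in structured ways,
and machine-specific isocenter calibration adds systematic offsets none
of which are modeled here.

## Statistical comparison

Methods are compared to the point-match baseline with the two-sided
Wilcoxon signed-rank test on per-setup paired values: directly for scalar
metrics (rmsTRE), and — since isocenter residual components are already
method-minus-baseline differences — against zero for the per-axis IRE
components.  Zero differences are discarded before ranking (classic
Wilcoxon; the Pratt variant is available via `zero_method="pratt"`).  The
exact null distribution is used for ≤12 tie-free pairs, the normal
approximation with tie and continuity corrections otherwise; tests pin
the exact branch to a full 2ⁿ sign-pattern enumeration at 1e-10 and the
calibration of the approximate branch to a type-I error of 0.05 ± 0.015
at n = 16.  Summaries use the sample (n−1) standard deviation.  No
multiple-testing correction is applied across the six axes and several
methods — each comparison is judged at α = 0.05 on its own, which
inflates the family-wise error rate; treat isolated marginal
significances accordingly.

## Problem sizes

The test suite and acceptance script use 10,000-replicate Monte-Carlo
runs for distributional checks (Sibson ratio, Maxwell displacement
moments, platform σ recovery), 2,000 replicates for signed-rank
calibration, 2,000 + 20,000 setups for the simulation-vs-oracle
cross-check, and the 20 + 16 setup counts of the emulated study design
for end-to-end runs.  These sizes put the Monte-Carlo standard error
comfortably below the asserted tolerances (e.g. ≈0.5% for the type-I
rate, ≈1% for the Sibson ratio at 3% tolerance) while keeping the whole
suite around twenty seconds on one core.

## Known limitations

- Rigid motion only; no deformation, and no couch-mechanics error model.
- No image content: DRRs, CBCT reconstruction and surface rendering are
  outside scope; platforms enter only as parameterized error models.
- Sibson's FLE relation assumes identical, independent, isotropic
  localization error at every marker; anisotropic noise biases the
  estimate (the anisotropic option exists precisely to explore this).
- Fitzpatrick's spatial TRE-prediction formula (TRE as a function of
  target position and the fiducial covariance) is not implemented; TRE
  is always *measured* at validation markers.
- The Euler-angle convention is fixed internally; per-axis rotation
  residuals from systems using another convention differ at second order
  in the angles.
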