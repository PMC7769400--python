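# fidreg

**Fiducial point-match gold standard and 6D error metrics for image-guided
radiotherapy registration QA.**

Modern radiotherapy positions patients with in-room imaging — cone-beam CT,
stereoscopic X-rays, optical surface scanning — each of which reports a
six-degree-of-freedom (6D) rigid correction from an image registration.
Judging how accurate those registrations are requires an independent gold
standard.  `fidreg` implements the classic one: rigid registration of
external fiducial markers by the closed-form least-squares (point-match)
solution, together with the error-metric suite used to score other
registration methods against it, and a synthetic phantom experiment
generator so the entire pipeline can be exercised and validated without
any measured data.

The package is aimed at medical physicists and algorithm developers doing
registration QA: it is primarily a Python library (see `examples/`), with
a thin `fidreg` command-line wrapper for the common file-in/file-out tasks.

## The model

Given corresponding marker positions `a_i` (planning CT) and `b_i`
(setup image), the point-match problem is

```
min_{R, T}  Σ_i || R a_i + T − b_i ||²     subject to RᵀR = I, det R = +1
```

solved in closed form via the singular value decomposition: center both
clouds on their centroids, form the cross-covariance `H = A′ᵀ B′ = U S Vᵀ`,
take `R = V diag(1, 1, det(VUᵀ)) Uᵀ` and `T = b̄ − R ā`.  The determinant
correction guarantees a proper rotation even when noisy, nearly coplanar
markers would otherwise admit a reflection.  Two independent solvers — a
quaternion eigen-decomposition and an exhaustive small-angle grid search —
are shipped purely to cross-check the SVD route.

Accuracy is quantified by:

- **FRE** — fiducial registration error, `||R a_i + T − b_i||` at the
  fitted (compute-group, "C") markers;
- **FLE** — fiducial localization error, estimated from FRE via Sibson's
  relation `⟨FLE²⟩ = n/(n−2) · ⟨FRE²⟩`;
- **TRE / rmsTRE** — target registration error at held-out validation
  ("V") markers and its per-setup root mean square (any overlap between
  C and V marker ids is a hard error);
- **IRE** — isocenter registration error: the 6D residual
  `Δ = method ∘ PM⁻¹`, referenced to the machine isocenter, split into a
  signed translation at ISO and per-axis rotation residuals.

All transforms use a fixed convention: right-handed axes, degrees,
`R = Rz(roll) · Ry(yaw) · Rx(pitch)` about fixed room axes, with an
explicit reference point carried on every transform.

## Worked example

```python
from fidreg import (build_phantom, sample_setup, solve_point_match,
                    compute_fre, compute_tre)

phantom = build_phantom("cranial", seed=0)       # 13 markers: 8 C + 5 V
scenario = sample_setup(phantom, seed=42)        # random 6D setup, ±3°, ±10 mm
a, b = scenario.noisy_planning_cloud, scenario.noisy_setup_cloud

sol = solve_point_match(a, b, group="C")
fre = compute_fre(sol, a.subset("C"), b.subset("C"))
tre = compute_tre(sol, a.subset("V"), b.subset("V"))
print(f"FRE {fre.fre_rms:.3f} mm, FLE {fre.fle_estimate:.3f} mm, "
      f"rmsTRE {tre.rms_tre:.3f} mm")
```

prints

```
FRE 0.540 mm, FLE 0.624 mm, rmsTRE 0.438 mm
```

— the fit residual at the eight compute markers is about half a
millimeter (set by the CT-voxel-scaled localization noise), the implied
per-marker localization error is slightly larger (`√(8/6)` × FRE), and
the honest accuracy at the five held-out markers is in the same sub-mm
range.  `examples/` contains this and three more narrative scripts
(error metrics on constructed cases, the full two-phantom simulated
study, and the Wilcoxon method comparison); each prints the numbers it
computes and what they mean.

The same pipeline is available from a shell:

```bash
fidreg simulate --site cranial --n-setups 20 --seed 1 --out-dir out/
fidreg compare out/metrics.csv --out-dir out/
```

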