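# hybridreg

Hybrid deformable image registration for CT ↔ CBCT-like volume pairs:
a sparse cubic-B-spline free-form deformation (FFD) provides the initial
warp estimate, and a convolution-simplified viscous-fluid stage driven by a
mutual-information (MI) force refines it, inside a coarse-to-fine
multi-resolution pyramid. The package ships the complete evaluation battery
(centroid TRE, Dice, directed/symmetric Hausdorff, MI, NCC, mean absolute
difference, paired t-test) and a synthetic CT/CBCT phantom suite, so the
method is testable end-to-end without patient data.

## Method outline

1. **Pyramid** — Gaussian-smoothed, 2× downsampled per level (default 3 levels).
2. **FFD stage** — cubic B-spline control lattice, MI-ascent on the control
   displacements with Armijo backtracking (default: sparse control points on
   the coarsest two levels; 30 iterations/level).
3. **Fluid stage** — per iteration: MI force field → velocity by Gaussian
   convolution (no Navier–Stokes solve) → displacement increment with
   material-transport term → Gaussian smoothing of the field → re-warp and
   re-evaluate MI. Stops on the iteration cap or an MI plateau. A Jacobian
   monitor regrids (template reset + field composition) if `det(I+∇u)`
   approaches zero, so the total field stays invertible.
4. **ffd_only mode** — dense FFD baseline (5 mm control spacing at full
   resolution, doubled per coarser level) used for ablation comparisons.

All fields are backward warps in millimetres on the fixed-image grid:
`output(x) = moving(x + u(x))`.

## CLI

```bash
# generate a synthetic case (phantom + ground-truth warp + CBCT-like fixed)
hybridreg synth --seed 7 --shape 64,64,64 --max-disp-mm 6 --out case/

# register (hybrid or ffd baseline)
hybridreg register --fixed case/fixed.nii --moving case/moving.nii \
    --mode hybrid --levels 3 \
    --out-field warp.nii --out-image warped.nii \
    --out-report report.json --out-trace trace.csv

# score a warp field against annotations
hybridreg evaluate --fixed case/fixed.nii --warped warped.nii --field warp.nii \
    --masks-fixed case/masks_fixed --masks-moving case/masks_moving \
    --markers-fixed case/markers_fixed --markers-moving case/markers_moving \
    --out eval.json
```

`register --config cfg.json` accepts a strict JSON config mirroring
`PipelineConfig` (unknown keys are rejected); the fully resolved config and
its hash are embedded in every report.

Supported formats: NIfTI (`.nii`/`.nii.gz`) and uncompressed MetaImage
(`.mha`) volumes; displacement fields as 4-D NIfTI (3 components, mm);
landmarks as `label,x_mm,y_mm,z_mm` CSV.

## Library use

```python
from hybridreg import register_hybrid, PipelineConfig
from hybridreg.synthetic import make_case, PhantomSpec

case = make_case(spec=PhantomSpec(seed=1), max_disp_mm=6.0, seed=1)
field, warped, report = register_hybrid(case.fixed, case.moving,
                                        PipelineConfig(mode="hybrid"))
```
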