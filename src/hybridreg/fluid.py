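"""Viscous-fluid refinement stage.

Instead of solving the Navier-Stokes operator with successive
over-relaxation, the velocity is obtained by convolving the similarity
force field with a Gaussian kernel.  Each iteration then adds a
velocity-driven increment to the displacement field, Gaussian-smooths the
field to keep it continuous, re-warps the moving image and re-evaluates the
objective; iteration stops at the cap or when the objective plateaus.
A Jacobian-determinant monitor triggers regridding so the accumulated
deformation stays invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from . import similarity
from .image_model import (
    DisplacementField,
    GeometryError,
    Image3D,
    apply_warp,
    compose_fields,
    jacobian_determinant,
)
from .similarity import ForceField


@dataclass
class FluidConfig:
    """Free parameters of the fluid stage (all lengths in mm)."""

    # kernel widths chosen so the velocity stays several voxels wide even on
    # coarse pyramid levels; sub-voxel kernels degenerate to raw noisy force
    sigma_fluid_mm: float = 16.0   # force -> velocity kernel width
    sigma_field_mm: float = 4.0    # displacement-field smoothing width
    max_step_factor: float = 0.4   # max per-iteration step = factor * min(spacing)
    jac_min: float = 0.5           # regridding threshold
    max_iter: int = 30
    bins: int = 32
    parzen_sigma_bins: float = 1.0
    plateau_rel_tol: float = 1e-4
    plateau_patience: int = 5
    divergence_patience: int = 5   # consecutive MI drops before bailing out
    transport_term: bool = True    # include -J_u v (material transport)
    regrid: bool = True
    force: str = "mi"              # "mi" | "ssd"

    def __post_init__(self):
        if self.sigma_fluid_mm <= 0 or self.sigma_field_mm < 0:
            raise ValueError("kernel widths must be positive (field sigma may be 0)")
        if not (0 < self.jac_min < 1):
            raise ValueError(f"jac_min must be in (0,1), got {self.jac_min}")
        if self.max_step_factor <= 0 or self.max_iter < 0:
            raise ValueError("max_step_factor and max_iter must be positive")


@dataclass
class FluidTrace:
    """Per-iteration diagnostics, exportable as CSV rows."""

    mi: list = dc_field(default_factory=list)
    max_step_mm: list = dc_field(default_factory=list)
    min_jacobian: list = dc_field(default_factory=list)
    regridded: list = dc_field(default_factory=list)

    def rows(self):
        for i in range(len(self.mi)):
            yield {
                "iteration": i,
                "mi": self.mi[i],
                "max_step_mm": self.max_step_mm[i] if i < len(self.max_step_mm) else "",
                "min_jacobian": self.min_jacobian[i] if i < len(self.min_jacobian) else "",
                "regridded": self.regridded[i] if i < len(self.regridded) else "",
            }


def velocity_from_force(force: ForceField, sigma_fluid_mm: float, spacing) -> ForceField:
    """Componentwise convolution with a unit-sum Gaussian of physical width sigma."""
    if sigma_fluid_mm <= 0:
        raise ValueError(f"sigma_fluid_mm must be > 0, got {sigma_fluid_mm}")
    sigma_vox = sigma_fluid_mm / np.asarray(spacing, dtype=float)
    out = np.empty_like(force.vectors)
    for c in range(3):
        out[..., c] = ndimage.gaussian_filter(force.vectors[..., c], sigma_vox, mode="nearest")
    return ForceField(out, force.spacing, force.origin)


def _field_jacobian_matrix(u: np.ndarray, spacing) -> np.ndarray:
    """(nx,ny,nz,3,3) array of du_i/dx_j in mm/mm via np.gradient."""
    J = np.empty(u.shape[:3] + (3, 3))
    for comp in range(3):
        grads = np.gradient(u[..., comp], spacing[0], spacing[1], spacing[2])
        for axis in range(3):
            J[..., comp, axis] = grads[axis]
    return J


def fluid_increment(
    u: DisplacementField,
    v: ForceField,
    dt_effective: float,
    transport_term: bool = True,
) -> DisplacementField:
    """u_new = u + dt * (v - J_u v); the transport term can be disabled."""
    if u.shape != v.shape:
        raise GeometryError(f"field/velocity grids differ: {u.shape} vs {v.shape}")
    vel = v.vectors
    if transport_term:
        J = _field_jacobian_matrix(u.vectors, u.spacing)
        vel = vel - np.einsum("...ij,...j->...i", J, vel)
    new = u.vectors + dt_effective * vel
    if not np.all(np.isfinite(new)):
        raise FloatingPointError("fluid increment produced non-finite displacements")
    return u.with_vectors(new)


def smooth_field(u: DisplacementField, sigma_field_mm: float) -> DisplacementField:
    """Componentwise Gaussian smoothing in physical units; sigma 0 is a no-op."""
    if sigma_field_mm < 0:
        raise ValueError(f"sigma_field_mm must be >= 0, got {sigma_field_mm}")
    if sigma_field_mm == 0:
        return u
    sigma_vox = sigma_field_mm / np.asarray(u.spacing, dtype=float)
    out = np.empty_like(u.vectors)
    for c in range(3):
        out[..., c] = ndimage.gaussian_filter(u.vectors[..., c], sigma_vox, mode="nearest")
    return u.with_vectors(out)


def regrid_if_needed(
    u: DisplacementField,
    template: Image3D,
    jac_min: float,
) -> tuple[Image3D, DisplacementField, bool]:
    """Reset the template when the residual deformation nears folding.

    If ``min det(I + grad u) < jac_min`` the warped template becomes the new
    template and the residual field is reset to zero; the caller composes the
    consumed residual into its accumulated field.
    """
    min_jac = float(jacobian_determinant(u).voxels.min())
    if min_jac < jac_min:
        new_template = apply_warp(template, u)
        return new_template, DisplacementField.zeros_like(new_template), True
    return template, u, False


def fluid_stage(
    fixed: Image3D,
    moving: Image3D,
    u_init: DisplacementField | None,
    cfg: FluidConfig | None = None,
) -> tuple[DisplacementField, FluidTrace]:
    """Run the fluid refinement loop; returns the best-MI total field.

    The loop iterates force -> velocity -> increment -> smoothing ->
    re-warp -> MI.  Regridding (when enabled) keeps the per-template residual
    field invertible and composes consumed residuals into the accumulated
    field, so the returned field is always the total fixed-to-moving warp.
    """
    cfg = cfg or FluidConfig()
    if u_init is None:
        u_init = DisplacementField.zeros_like(fixed)
    if u_init.shape != fixed.shape:
        raise GeometryError(f"u_init grid {u_init.shape} differs from fixed grid {fixed.shape}")
    force_fn = similarity.mi_force if cfg.force == "mi" else similarity.ssd_force
    max_step_mm = cfg.max_step_factor * min(fixed.spacing)

    u_acc = u_init                      # consumed (composed) warp, fixed -> moving
    template = apply_warp(moving, u_init)
    u_res = DisplacementField.zeros_like(fixed)   # residual warp, fixed -> template

    def total_field(res: DisplacementField) -> DisplacementField:
        return compose_fields(u_acc, res)

    trace = FluidTrace()
    cur_mi = similarity.mi(fixed, template, bins=cfg.bins)
    trace.mi.append(cur_mi)
    trace.max_step_mm.append(0.0)
    trace.min_jacobian.append(float(jacobian_determinant(u_res).voxels.min()))
    trace.regridded.append(False)

    best_mi = cur_mi
    best_field = total_field(u_res)
    drops = 0

    for _ in range(cfg.max_iter):
        warped = apply_warp(template, u_res)
        force = force_fn(fixed, warped, bins=cfg.bins,
                         parzen_sigma_bins=cfg.parzen_sigma_bins)
        vel = velocity_from_force(force, cfg.sigma_fluid_mm, fixed.spacing)
        vmax = float(np.abs(vel.vectors).max())
        if vmax == 0:
            break
        dt_eff = max_step_mm / vmax
        u_new = fluid_increment(u_res, vel, dt_eff, transport_term=cfg.transport_term)
        u_new = smooth_field(u_new, cfg.sigma_field_mm)

        regridded = False
        if cfg.regrid:
            new_template, u_after, regridded = regrid_if_needed(u_new, template, cfg.jac_min)
            if regridded:
                u_acc = compose_fields(u_acc, u_new)
                template, u_res = new_template, u_after
            else:
                u_res = u_new
        else:
            u_res = u_new

        warped = apply_warp(template, u_res)
        cur_mi = similarity.mi(fixed, warped, bins=cfg.bins)
        trace.mi.append(cur_mi)
        trace.max_step_mm.append(float(dt_eff * vmax))
        trace.min_jacobian.append(float(jacobian_determinant(u_res).voxels.min()))
        trace.regridded.append(regridded)

        if cur_mi > best_mi:
            best_mi = cur_mi
            best_field = total_field(u_res)
            drops = 0
        else:
            drops += 1
            if drops >= cfg.divergence_patience:
                break
        w = cfg.plateau_patience
        if len(trace.mi) > w:
            prev = trace.mi[-1 - w]
            if trace.mi[-1] - prev < cfg.plateau_rel_tol * max(abs(prev), 1e-12):
                break
    return best_field, trace
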