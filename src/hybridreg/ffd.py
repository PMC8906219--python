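"""Cubic B-spline free-form deformation.

A sparse lattice of control-point displacements parameterises a dense
displacement field through the tensor-product cubic B-spline: the
displacement at any position is a weighted sum of the 4x4x4 surrounding
control displacements.  The same stage serves both as the hybrid method's
coarse initialisation and as the standalone FFD baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from . import similarity
from .image_model import DisplacementField, GeometryError, Image3D, apply_warp


@dataclass(frozen=True)
class ControlPointGrid:
    """Regular lattice of control displacements (mm).

    Lattice point ``k`` sits at physical position
    ``image_origin + (k - 1) * cp_spacing`` so the lattice pads one point
    beyond each image edge, as cubic support requires.
    """

    displacements: np.ndarray            # (Kx, Ky, Kz, 3), mm
    cp_spacing: tuple[float, float, float]
    image_origin: tuple[float, float, float]

    def __post_init__(self):
        disp = np.asarray(self.displacements, dtype=float)
        if disp.ndim != 4 or disp.shape[-1] != 3:
            raise GeometryError(f"control lattice must be (Kx,Ky,Kz,3), got {disp.shape}")
        sp = np.asarray(self.cp_spacing, dtype=float)
        if np.any(sp <= 0):
            raise GeometryError(f"cp_spacing must be positive, got {self.cp_spacing}")
        object.__setattr__(self, "displacements", disp)
        object.__setattr__(self, "cp_spacing", tuple(sp))
        object.__setattr__(self, "image_origin", tuple(float(o) for o in self.image_origin))

    @property
    def lattice_shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]

    def with_displacements(self, disp: np.ndarray) -> "ControlPointGrid":
        return ControlPointGrid(disp, self.cp_spacing, self.image_origin)


def make_control_grid(fixed: Image3D, cp_spacing) -> ControlPointGrid:
    """Zero-displacement lattice covering ``fixed`` plus cubic support margin."""
    sp = np.broadcast_to(np.asarray(cp_spacing, dtype=float), (3,))
    if np.any(sp <= 0):
        raise GeometryError(f"cp_spacing must be positive, got {cp_spacing}")
    extent = fixed.extent_mm
    if np.any(sp >= extent):
        raise GeometryError(
            f"cp_spacing {tuple(sp)} must be smaller than the image extent {tuple(extent)}"
        )
    K = np.ceil(extent / sp).astype(int) + 3
    return ControlPointGrid(np.zeros(tuple(K) + (3,)), tuple(sp), fixed.origin)


def _lattice_coords(grid: ControlPointGrid, fixed: Image3D) -> list[np.ndarray]:
    """Per-axis lattice array coordinates of the fixed-grid voxel centres."""
    coords = []
    for a in range(3):
        pos = fixed.origin[a] + np.arange(fixed.shape[a]) * fixed.spacing[a]
        # array index = physical offset / cp_spacing + 1 (one pad point below)
        c = (pos - grid.image_origin[a]) / grid.cp_spacing[a] + 1.0
        if c.min() < 1.0 - 1e-9 or c.max() > grid.lattice_shape[a] - 2 + 1e-9:
            raise GeometryError(
                f"lattice does not cover the image on axis {a}: "
                f"coords [{c.min():.3f}, {c.max():.3f}] vs lattice size {grid.lattice_shape[a]}"
            )
        coords.append(c)
    return coords


def evaluate_ffd(grid: ControlPointGrid, fixed: Image3D) -> DisplacementField:
    """Dense displacement field of the FFD on the fixed grid.

    The control displacements are the B-spline *coefficients*, so the
    tensor-product sum is exactly cubic B-spline interpolation without
    prefiltering.
    """
    cx, cy, cz = _lattice_coords(grid, fixed)
    mesh = np.meshgrid(cx, cy, cz, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh], axis=0)
    out = np.empty(fixed.shape + (3,))
    for comp in range(3):
        out[..., comp] = ndimage.map_coordinates(
            grid.displacements[..., comp], coords, order=3, prefilter=False, mode="nearest"
        ).reshape(fixed.shape)
    return DisplacementField(out, fixed.spacing, fixed.origin)


def bspline_weights(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis values (w0..w3) at fractional offsets t in [0,1]."""
    t = np.asarray(t, dtype=float)
    t2, t3 = t * t, t * t * t
    return np.stack([
        (1 - t) ** 3 / 6.0,
        (3 * t3 - 6 * t2 + 4) / 6.0,
        (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
        t3 / 6.0,
    ])


def scatter_to_lattice(grid: ControlPointGrid, fixed: Image3D,
                       voxel_vectors: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`evaluate_ffd`: aggregate per-voxel vectors onto the
    lattice with the same B-spline weights (the chain rule for dMI/dphi)."""
    cx, cy, cz = _lattice_coords(grid, fixed)
    acc = np.zeros_like(grid.displacements)
    ibase, weights = [], []
    for axis, c in enumerate((cx, cy, cz)):
        K = grid.lattice_shape[axis]
        i = np.clip(np.floor(c - 1.0).astype(int), 0, K - 4)  # cell base in lattice units
        t = (c - 1.0) - i  # in [0,1]; t=1 at the clipped top edge is still exact
        ibase.append(i)
        weights.append(bspline_weights(t))          # (4, n_axis)
    for a in range(4):
        wa = weights[0][a][:, None, None]
        ia = (ibase[0] + a)[:, None, None]
        for b in range(4):
            wb = weights[1][b][None, :, None]
            ib = (ibase[1] + b)[None, :, None]
            wab = wa * wb
            for c in range(4):
                w = wab * weights[2][c][None, None, :]
                ic = (ibase[2] + c)[None, None, :]
                np.add.at(acc, (ia, ib, ic), w[..., None] * voxel_vectors)
    return acc


@dataclass
class FFDConfig:
    cp_spacing_mm: float | tuple[float, float, float] | None = None  # None -> 4x voxel spacing
    max_iter: int = 30
    bins: int = 32
    parzen_sigma_bins: float = 1.0
    step0_factor: float = 0.4     # initial step = factor * min cp_spacing
    armijo_c1: float = 1e-4
    backtrack: float = 0.5
    min_step_mm: float = 1e-3
    plateau_rel_tol: float = 1e-4
    plateau_patience: int = 5
    force: str = "mi"             # "mi" | "ssd"
    bending_penalty: float = 0.0  # off by default


@dataclass
class FFDTrace:
    mi: list = dc_field(default_factory=list)
    step_mm: list = dc_field(default_factory=list)
    accepted: list = dc_field(default_factory=list)


def _bending_gradient(disp: np.ndarray, weight: float) -> np.ndarray:
    """Discrete bending-energy gradient on the lattice (optional penalty)."""
    lap = np.zeros_like(disp)
    for comp in range(3):
        lap[..., comp] = ndimage.laplace(disp[..., comp], mode="nearest")
    for comp in range(3):
        lap[..., comp] = ndimage.laplace(lap[..., comp], mode="nearest")
    return -weight * lap


def optimize_ffd_level(
    fixed: Image3D,
    moving: Image3D,
    grid: ControlPointGrid,
    max_iter: int | None = None,
    config: FFDConfig | None = None,
) -> tuple[ControlPointGrid, FFDTrace]:
    """Gradient ascent on MI over the control displacements.

    The MI gradient w.r.t. a control point is the B-spline-weighted
    aggregation of the per-voxel similarity force; steps use Armijo
    backtracking so accepted iterates never decrease MI beyond tolerance.
    Stops at ``max_iter`` or when the relative MI improvement over the
    patience window falls below ``plateau_rel_tol``.
    """
    cfg = config or FFDConfig()
    if max_iter is None:
        max_iter = cfg.max_iter
    if fixed.shape != moving.shape:
        raise GeometryError(f"image grids differ: {fixed.shape} vs {moving.shape}")
    force_fn = similarity.mi_force if cfg.force == "mi" else similarity.ssd_force

    def mi_of(g: ControlPointGrid) -> float:
        warped = apply_warp(moving, evaluate_ffd(g, fixed))
        return similarity.mi(fixed, warped, bins=cfg.bins)

    trace = FFDTrace()
    cur = grid
    cur_mi = mi_of(cur)
    trace.mi.append(cur_mi)
    step = cfg.step0_factor * min(cur.cp_spacing)

    for _ in range(max_iter):
        warped = apply_warp(moving, evaluate_ffd(cur, fixed))
        force = force_fn(fixed, warped, bins=cfg.bins, parzen_sigma_bins=cfg.parzen_sigma_bins)
        g = scatter_to_lattice(cur, fixed, force.vectors)
        if cfg.bending_penalty > 0:
            g = g + _bending_gradient(cur.displacements, cfg.bending_penalty)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite FFD gradient at iteration {len(trace.mi) - 1}; trace={trace.mi}"
            )
        gmax = np.abs(g).max()
        if gmax == 0:
            break
        direction = g / gmax  # max component = 1, so `step` is a length in mm

        accepted = False
        while step >= cfg.min_step_mm:
            cand = cur.with_displacements(cur.displacements + step * direction)
            cand_mi = mi_of(cand)
            # sufficient increase, scaled by how much of the gradient the step uses
            if cand_mi >= cur_mi + cfg.armijo_c1 * step * gmax:
                cur, cur_mi, accepted = cand, cand_mi, True
                break
            step *= cfg.backtrack
        trace.mi.append(cur_mi)
        trace.step_mm.append(step)
        trace.accepted.append(accepted)
        if not accepted:
            break
        step /= cfg.backtrack  # allow the step to grow back
        step = min(step, cfg.step0_factor * min(cur.cp_spacing))
        # plateau: relative improvement over the patience window
        w = cfg.plateau_patience
        if len(trace.mi) > w:
            prev = trace.mi[-1 - w]
            if trace.mi[-1] - prev < cfg.plateau_rel_tol * max(abs(prev), 1e-12):
                break
    return cur, trace
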