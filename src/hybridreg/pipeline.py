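"""Multi-resolution orchestration of the hybrid registration.

Coarse-to-fine: at each pyramid level the control-point stage (on the
coarsest levels) provides the initial estimate, then the fluid stage refines
it; the field is upsampled between levels.  ``ffd_only`` mode runs the
control-point stage at every level and serves as the ablation baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from . import similarity
from .evaluation import RegistrationReport
from .ffd import FFDConfig, evaluate_ffd, make_control_grid, optimize_ffd_level
from .fluid import FluidConfig, fluid_stage
from .image_model import (
    DisplacementField,
    GeometryError,
    Image3D,
    apply_warp,
    compose_fields,
    resample_to_grid,
)


@dataclass
class PipelineConfig:
    levels: int = 3
    mode: str = "hybrid"                      # "hybrid" | "ffd_only"
    ffd: FFDConfig = dc_field(default_factory=FFDConfig)
    fluid: FluidConfig = dc_field(default_factory=FluidConfig)
    ffd_on_levels: tuple[int, ...] | None = None    # None -> mode default
    fluid_on_levels: tuple[int, ...] | None = None  # None -> mode default
    seed: int = 0
    metric_bins: int = 64

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if self.mode not in ("hybrid", "ffd_only"):
            raise ValueError(f"mode must be 'hybrid' or 'ffd_only', got {self.mode!r}")

    def resolved_ffd_levels(self) -> tuple[int, ...]:
        if self.ffd_on_levels is not None:
            return tuple(self.ffd_on_levels)
        if self.mode == "ffd_only":
            return tuple(range(self.levels))          # every level, NiftyReg-style
        return tuple(range(max(0, self.levels - 2), self.levels))  # coarsest two

    def resolved_fluid_levels(self) -> tuple[int, ...]:
        if self.mode == "ffd_only":
            return ()
        if self.fluid_on_levels is not None:
            return tuple(self.fluid_on_levels)
        return tuple(range(self.levels))


def build_pyramid(img: Image3D, levels: int) -> list[Image3D]:
    """Gaussian pyramid: level 0 = full resolution, each next level smoothed
    and downsampled by 2 per axis (spacing doubled)."""
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    coarsest = np.array(img.shape) // (2 ** (levels - 1))
    if np.any(coarsest < 8):
        raise GeometryError(
            f"image shape {img.shape} too small for {levels} pyramid levels "
            f"(coarsest would be {tuple(coarsest)}, need >= 8 per axis)"
        )
    pyr = [img]
    for _ in range(levels - 1):
        prev = pyr[-1]
        sm = ndimage.gaussian_filter(np.asarray(prev.voxels, dtype=float), sigma=1.0,
                                     mode="nearest")
        down = sm[::2, ::2, ::2]
        pyr.append(Image3D(down, tuple(2 * s for s in prev.spacing), prev.origin))
    return pyr


def upsample_field(u: DisplacementField, target: Image3D) -> DisplacementField:
    """Trilinear transfer of a displacement field onto a finer grid.

    Vector values stay in mm; only the support grid changes.
    """
    tgt_pos = [np.asarray(target.origin)[a] + np.arange(target.shape[a]) * target.spacing[a]
               for a in range(3)]
    coords_1d = [(tgt_pos[a] - u.origin[a]) / u.spacing[a] for a in range(3)]
    mesh = np.meshgrid(*coords_1d, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh], axis=0)
    out = np.empty(target.shape + (3,))
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            u.vectors[..., c], coords, order=1, mode="nearest", prefilter=False
        ).reshape(target.shape)
    return DisplacementField(out, target.spacing, target.origin)


#: standalone-FFD baseline control-point spacing at full resolution (mm);
#: doubled per coarser pyramid level, the usual multi-resolution FFD schedule
BASELINE_CP_SPACING_MM = 5.0


def _level_ffd_config(cfg: PipelineConfig, level: int,
                      coarsest_img: Image3D) -> tuple[FFDConfig, tuple]:
    """Control-point spacing for a pyramid level.

    The hybrid stage keeps its control points sparse (4x the coarsest-level
    voxel spacing, constant in mm across levels) — its job is only the
    initial estimate.  The ffd_only baseline emulates a dense FFD:
    ``BASELINE_CP_SPACING_MM`` at full resolution, doubled per level.
    """
    ffd_cfg = cfg.ffd
    if ffd_cfg.cp_spacing_mm is not None:
        cp = np.broadcast_to(np.asarray(ffd_cfg.cp_spacing_mm, dtype=float), (3,))
        return ffd_cfg, tuple(cp)
    if cfg.mode == "ffd_only":
        return ffd_cfg, tuple(BASELINE_CP_SPACING_MM * 2.0**level for _ in range(3))
    return ffd_cfg, tuple(4.0 * s for s in coarsest_img.spacing)


def register_hybrid(
    fixed: Image3D,
    moving: Image3D,
    cfg: PipelineConfig | None = None,
) -> tuple[DisplacementField, Image3D, RegistrationReport]:
    """Full coarse-to-fine registration of ``moving`` onto ``fixed``.

    Returns the final full-resolution backward field, the warped moving
    image, and a report with before/after similarity metrics and the
    per-level traces.
    """
    cfg = cfg or PipelineConfig()
    if not fixed.same_grid(moving):
        warnings.warn("moving image grid differs from fixed; resampling onto the fixed grid")
        moving = resample_to_grid(moving, fixed)

    pyr_fixed = build_pyramid(fixed, cfg.levels)
    pyr_moving = build_pyramid(moving, cfg.levels)
    ffd_levels = set(cfg.resolved_ffd_levels())
    fluid_levels = set(cfg.resolved_fluid_levels())

    traces: dict[str, object] = {}
    u: DisplacementField | None = None
    for level in range(cfg.levels - 1, -1, -1):
        fx, mv = pyr_fixed[level], pyr_moving[level]
        u = DisplacementField.zeros_like(fx) if u is None else upsample_field(u, fx)

        if level in ffd_levels:
            warped = apply_warp(mv, u)
            ffd_cfg, cp = _level_ffd_config(cfg, level, pyr_fixed[-1])
            try:
                grid = make_control_grid(fx, cp)
            except GeometryError:
                # spacing too coarse for this level's extent: shrink to fit
                cp = tuple(min(c, 0.45 * e) for c, e in zip(cp, fx.extent_mm))
                grid = make_control_grid(fx, cp)
            grid, ftrace = optimize_ffd_level(fx, warped, grid, config=ffd_cfg)
            u_ffd = evaluate_ffd(grid, fx)
            u = compose_fields(u, u_ffd)
            traces[f"level{level}_ffd"] = ftrace
        if level in fluid_levels:
            u, vtrace = fluid_stage(fx, mv, u, cfg.fluid)
            traces[f"level{level}_fluid"] = vtrace
        if not np.all(np.isfinite(u.vectors)):
            raise FloatingPointError(f"non-finite displacement field at level {level}")

    warped = apply_warp(moving, u)
    bins = cfg.metric_bins
    report = RegistrationReport(
        metrics_before={
            "mi": similarity.mi(fixed, moving, bins=bins),
            "ncc": similarity.ncc(fixed, moving),
            "mean_abs_diff": similarity.mean_abs_diff(fixed, moving),
        },
        metrics_after={
            "mi": similarity.mi(fixed, warped, bins=bins),
            "ncc": similarity.ncc(fixed, warped),
            "mean_abs_diff": similarity.mean_abs_diff(fixed, warped),
        },
        traces=traces,
    )
    return u, warped, report


def pre_translate(
    fixed: Image3D,
    moving: Image3D,
    window_voxels: int = 10,
) -> tuple[Image3D, tuple[int, int, int]]:
    """Integer-voxel translation of ``moving`` maximising NCC with ``fixed``.

    Exhaustive search over shifts in ``[-window, window]^3``; a simple
    stand-in for the rigid pre-alignment the pipeline otherwise assumes.
    Returns the shifted image and the applied shift (voxels).
    """
    if not fixed.same_grid(moving):
        raise GeometryError(f"grids differ: {fixed.shape} vs {moving.shape}")
    shape = fixed.shape
    if any(2 * window_voxels >= s for s in shape):
        raise ValueError(f"search window ±{window_voxels} exceeds image shape {shape}")
    f = np.asarray(fixed.voxels, dtype=float)
    m = np.asarray(moving.voxels, dtype=float)
    if f.std() == 0 or m.std() == 0:
        warnings.warn("constant image(s): translation search is degenerate, returning zero shift")
        return moving, (0, 0, 0)

    def overlap_ncc(shift):
        src, dst = [], []
        for a, s in enumerate(shift):
            n = shape[a]
            if s >= 0:
                dst.append(slice(s, n))
                src.append(slice(0, n - s))
            else:
                dst.append(slice(0, n + s))
                src.append(slice(-s, n))
        fa, ma = f[tuple(dst)], m[tuple(src)]
        fc, mc = fa - fa.mean(), ma - ma.mean()
        denom = np.sqrt((fc**2).sum() * (mc**2).sum())
        if denom == 0:
            return -np.inf
        return float((fc * mc).sum() / denom)

    best_shift, best_val = (0, 0, 0), overlap_ncc((0, 0, 0))
    rng = range(-window_voxels, window_voxels + 1)
    for sx in rng:
        for sy in rng:
            for sz in rng:
                v = overlap_ncc((sx, sy, sz))
                if v > best_val + 1e-12:
                    best_val, best_shift = v, (sx, sy, sz)
    out = np.full(shape, float(m.min()))
    dst, src = [], []
    for a, s in enumerate(best_shift):
        n = shape[a]
        if s >= 0:
            dst.append(slice(s, n))
            src.append(slice(0, n - s))
        else:
            dst.append(slice(0, n + s))
            src.append(slice(-s, n))
    out[tuple(dst)] = m[tuple(src)]
    return Image3D(out, moving.spacing, moving.origin), best_shift
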