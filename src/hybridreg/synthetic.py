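"""Digital head-and-neck-like phantoms with ground-truth warps.

The generator stands in for patient data: a bright vertebral column in soft
tissue with an air cavity, five labelled "organ" masks, five marker discs on
the column, a smooth invertible B-spline ground-truth deformation, and a
CBCT-like intensity degradation (monotone remap + shading + noise) that
breaks direct intensity comparison so MI is genuinely needed.  Everything is
a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .ffd import evaluate_ffd, make_control_grid
from .image_model import (
    BinaryMask,
    DisplacementField,
    Image3D,
    LandmarkSet,
    apply_warp,
    jacobian_determinant,
    resample_to_grid,
    warp_mask,
)

ORGAN_LABELS = ("larynx", "cord", "oral_cavity", "mandible", "parotid")
MARKER_LABELS = ("P1", "P2", "P3", "P4", "P5")

# planning-CT and treatment-CBCT voxel geometries used as full-scale defaults
CT_SPACING_MM = (1.27, 1.27, 3.0)
CBCT_SPACING_MM = (0.51, 0.51, 1.99)


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # CI default; CT_SPACING_MM for full scale
    seed: int = 0
    background: float = -1000.0
    air: float = -800.0
    soft: float = 40.0
    bone: float = 700.0
    jitter_voxels: float = 1.5     # seeded placement jitter of the organs
    smooth_sigma_voxels: float = 0.8

    def __post_init__(self):
        if min(self.shape) < 16:
            raise ValueError(f"phantom shape must be >= 16 per axis, got {self.shape}")
        if not (self.bone > self.soft > self.air >= self.background):
            raise ValueError("need bone > soft > air >= background intensities")


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[Image3D, dict[str, BinaryMask], LandmarkSet]:
    """Deterministic phantom volume, organ/marker masks, and marker landmarks.

    Masks: the five organ labels, ``body`` (soft-tissue support), ``bone``
    (vertebral column), and one small disc per marker label.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    vol = np.full(spec.shape, spec.background)

    body = _ellipsoid(spec.shape, (nx / 2, ny / 2, nz / 2),
                      (0.42 * nx, 0.40 * ny, 0.55 * nz))
    vol[body] = spec.soft

    # vertebral column: stacked bright blocks (with disc gaps) slightly posterior
    bone_mask = np.zeros(spec.shape, dtype=bool)
    cx, cy = int(nx * 0.5), int(ny * 0.64)
    half = max(2, int(round(0.055 * nx)))
    block = max(3, int(round(nz / 12)))
    gap = max(1, block // 3)
    z = int(0.06 * nz)
    while z + block < int(0.94 * nz):
        bone_mask[cx - half:cx + half + 1, cy - half:cy + half + 1, z:z + block] = True
        z += block + gap
    bone_mask &= body
    vol[bone_mask] = spec.bone

    # airway: anterior low-intensity tube
    airway = _ellipsoid(spec.shape, (nx / 2, ny * 0.36, nz / 2),
                        (0.06 * nx, 0.06 * ny, 0.5 * nz))
    airway &= body & ~bone_mask
    vol[airway] = spec.air

    # organs: ellipsoids at anatomically-inspired relative positions, jittered
    rel = {
        "larynx": ((0.50, 0.40, 0.30), (0.08, 0.07, 0.10)),
        "cord": ((0.50, 0.76, 0.50), (0.045, 0.045, 0.42)),
        "oral_cavity": ((0.50, 0.38, 0.74), (0.13, 0.09, 0.10)),
        "mandible": ((0.50, 0.52, 0.78), (0.20, 0.05, 0.05)),
        "parotid": ((0.76, 0.55, 0.68), (0.07, 0.08, 0.09)),
    }
    organ_offsets = {"larynx": -25.0, "cord": 15.0, "oral_cavity": -40.0,
                     "mandible": 320.0, "parotid": 25.0}
    masks: dict[str, np.ndarray] = {}
    occupied = bone_mask | airway
    for label, (c_rel, a_rel) in rel.items():
        jit = rng.uniform(-spec.jitter_voxels, spec.jitter_voxels, size=3)
        center = np.array(c_rel) * spec.shape + jit
        semi = np.maximum(np.array(a_rel) * spec.shape, 1.5)
        m = _ellipsoid(spec.shape, center, semi) & body & ~occupied
        if not m.any():
            raise ValueError(f"organ {label!r} does not fit the requested shape {spec.shape}")
        masks[label] = m
        occupied |= m
        vol[m] = spec.soft + organ_offsets[label]

    if spec.smooth_sigma_voxels > 0:
        vol = ndimage.gaussian_filter(vol, spec.smooth_sigma_voxels, mode="nearest")

    img = Image3D(vol, spec.spacing, (0.0, 0.0, 0.0))
    out_masks = {lbl: BinaryMask(m.astype(np.uint8), spec.spacing, (0, 0, 0))
                 for lbl, m in masks.items()}
    out_masks["body"] = BinaryMask(body.astype(np.uint8), spec.spacing, (0, 0, 0))
    out_masks["bone"] = BinaryMask(bone_mask.astype(np.uint8), spec.spacing, (0, 0, 0))

    # markers: one small disc per vertebral block region, on the column
    block_zs = []
    z = int(0.06 * nz)
    while z + block < int(0.94 * nz):
        zc = z + block // 2
        # keep markers away from the volume edge, where any registration is
        # intrinsically less constrained
        if 0.15 * nz <= zc <= 0.85 * nz:
            block_zs.append(zc)
        z += block + gap
    pick = np.linspace(0, len(block_zs) - 1, num=5).round().astype(int)
    points = []
    for k, (label, bi) in enumerate(zip(MARKER_LABELS, pick)):
        zc = block_zs[bi]
        xoff = (-half + 1) if k % 2 == 0 else (half - 1)  # alternate left/right of the column
        disc = np.zeros(spec.shape, dtype=bool)
        # 3 voxels in-plane ("small circle"), 3 slices thick so the marker
        # survives nearest-neighbour propagation under clinical-scale warps
        disc[cx + xoff - 1:cx + xoff + 2, cy - 1:cy + 2, zc - 1:zc + 2] = True
        disc &= bone_mask
        if not disc.any():
            disc[cx, cy, zc] = True
        out_masks[label] = BinaryMask(disc.astype(np.uint8), spec.spacing, (0, 0, 0))
        idx = np.argwhere(disc).mean(axis=0)
        points.append((label, tuple(idx * np.asarray(spec.spacing))))
    return img, out_masks, LandmarkSet(tuple(points))


def make_ground_truth_warp(
    fixed: Image3D,
    cp_spacing_mm: float = 32.0,
    max_disp_mm: float = 6.0,
    seed: int = 0,
    max_redraws: int = 10,
) -> DisplacementField:
    """Random cubic-B-spline field, redrawn until numerically diffeomorphic.

    Control displacements are uniform in [-max_disp, max_disp]^3; the
    B-spline convex-combination bound keeps |u| <= max_disp everywhere, and
    ``max_disp <= 0.4 cp_spacing`` guards invertibility before the explicit
    Jacobian check.
    """
    if max_disp_mm < 0:
        raise ValueError("max_disp_mm must be >= 0")
    if max_disp_mm > 0.4 * cp_spacing_mm:
        raise ValueError(
            f"max_disp_mm={max_disp_mm} exceeds the diffeomorphism guard "
            f"0.4*cp_spacing = {0.4 * cp_spacing_mm}"
        )
    if max_disp_mm == 0:
        return DisplacementField.zeros_like(fixed)
    rng = np.random.default_rng(seed)
    grid = make_control_grid(fixed, cp_spacing_mm)
    for _ in range(max_redraws):
        disp = rng.uniform(-max_disp_mm, max_disp_mm, size=grid.displacements.shape)
        fld = evaluate_ffd(grid.with_displacements(disp), fixed)
        if jacobian_determinant(fld).voxels.min() > 0:
            return fld
    raise RuntimeError(f"no diffeomorphic draw within {max_redraws} attempts")


@dataclass(frozen=True)
class DegradeConfig:
    """CBCT-like degradation: monotone remap, shading, noise."""

    # defaults picked so NCC(clean, degraded) lands in [0.6, 0.9]: strong
    # enough to defeat direct intensity comparison, weak enough for MI
    gamma: float = 3.0                 # exponent of the monotone intensity remap
    shading_amplitude: float = 0.25    # multiplicative low-frequency field, +/- fraction
    shading_sigma_voxels: float = 12.0
    noise_sigma_fraction: float = 0.05  # of the intensity range

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0 (monotone remap)")


def degrade_to_cbct(img: Image3D, seed: int = 0,
                    cfg: DegradeConfig | None = None) -> Image3D:
    """Apply the CBCT-like degradation; identity parameters leave the image unchanged."""
    cfg = cfg or DegradeConfig()
    rng = np.random.default_rng(seed)
    vox = np.asarray(img.voxels, dtype=float)
    lo, hi = float(vox.min()), float(vox.max())
    rngspan = hi - lo if hi > lo else 1.0
    t = (vox - lo) / rngspan
    t = t ** cfg.gamma
    if cfg.shading_amplitude > 0:
        noise = rng.standard_normal(img.shape)
        shade = ndimage.gaussian_filter(noise, cfg.shading_sigma_voxels, mode="nearest")
        peak = np.abs(shade).max()
        if peak > 0:
            shade = shade / peak
        t = t * (1.0 + cfg.shading_amplitude * shade)
    out = lo + rngspan * t
    if cfg.noise_sigma_fraction > 0:
        out = out + rng.standard_normal(img.shape) * cfg.noise_sigma_fraction * rngspan
    return img.with_voxels(out)


@dataclass
class RegistrationCase:
    """A complete synthetic benchmark case.

    ``fixed`` is the degraded, ground-truth-warped phantom (CBCT-like);
    ``moving`` is the clean phantom (pCT-like); ``gt_field`` is the backward
    field that resamples moving into fixed space.
    """

    fixed: Image3D
    moving: Image3D
    gt_field: DisplacementField
    masks_fixed: dict[str, BinaryMask] = dc_field(default_factory=dict)
    masks_moving: dict[str, BinaryMask] = dc_field(default_factory=dict)
    markers_fixed: dict[str, BinaryMask] = dc_field(default_factory=dict)
    markers_moving: dict[str, BinaryMask] = dc_field(default_factory=dict)
    landmarks_fixed: LandmarkSet | None = None
    landmarks_moving: LandmarkSet | None = None

    @property
    def body_fixed(self) -> BinaryMask:
        return self.masks_fixed["body"]


def make_case(
    spec: PhantomSpec | None = None,
    cp_spacing_mm: float = 32.0,
    max_disp_mm: float = 6.0,
    degrade: DegradeConfig | None = None,
    seed: int = 0,
    cbct_grid: Image3D | None = None,
    min_marker_disp_mm: float = 0.0,
) -> RegistrationCase:
    """Build a full case: phantom, ground-truth warp, degraded fixed image.

    ``cbct_grid`` optionally resamples the fixed side onto a different
    (e.g. CBCT-resolution) grid; by default both images share the phantom grid.
    ``min_marker_disp_mm > 0`` redraws the warp until every marker is
    displaced by at least that much, so each marker genuinely exercises the
    registration.
    """
    from .evaluation import marker_centroid  # local import avoids a cycle

    spec = spec or PhantomSpec(seed=seed)
    moving, masks_mv, lms_mv = make_phantom(spec)
    gt = None
    for attempt in range(20):
        cand = make_ground_truth_warp(moving, cp_spacing_mm, max_disp_mm,
                                      seed=seed + 1 + 1000 * attempt)
        if min_marker_disp_mm <= 0:
            gt = cand
            break
        disp = [np.linalg.norm(marker_centroid(warp_mask(masks_mv[lbl], cand))
                               - marker_centroid(masks_mv[lbl]))
                for lbl in MARKER_LABELS]
        if min(disp) >= min_marker_disp_mm:
            gt = cand
            break
    if gt is None:
        raise RuntimeError(
            f"no draw displaced all markers by >= {min_marker_disp_mm} mm in 20 attempts"
        )

    fixed_clean = apply_warp(moving, gt)
    fixed = degrade_to_cbct(fixed_clean, seed=seed + 2, cfg=degrade)

    masks_fx = {lbl: warp_mask(m, gt) for lbl, m in masks_mv.items()}
    if cbct_grid is not None:
        fixed = resample_to_grid(fixed, cbct_grid)
        # masks/field stay on the phantom grid deliberately: scoring happens there

    markers_mv = {lbl: masks_mv[lbl] for lbl in MARKER_LABELS}
    markers_fx = {lbl: masks_fx[lbl] for lbl in MARKER_LABELS}
    lms_fx = LandmarkSet(tuple(
        (lbl, tuple(marker_centroid(markers_fx[lbl]))) for lbl in MARKER_LABELS
    ))
    return RegistrationCase(
        fixed=fixed,
        moving=moving,
        gt_field=gt,
        masks_fixed={k: v for k, v in masks_fx.items() if k not in MARKER_LABELS},
        masks_moving={k: v for k, v in masks_mv.items() if k not in MARKER_LABELS},
        markers_fixed=markers_fx,
        markers_moving=markers_mv,
        landmarks_fixed=lms_fx,
        landmarks_moving=lms_mv,
    )
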