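"""Core geometric types shared by every registration stage.

All images live on axis-aligned grids: voxel index ``i`` (0-based) maps to the
physical position ``origin + i * spacing`` in millimetres.  Displacement
fields are stored in millimetres on the fixed-image grid and are *backward*
fields: they give, for each fixed-grid position ``x``, the position
``x + u(x)`` at which the moving image is sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Raised when image/field geometries are inconsistent."""


@dataclass(frozen=True)
class Image3D:
    """A 3-D scalar volume with physical voxel spacing and origin (mm)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise GeometryError(f"expected a 3-D array, got ndim={vox.ndim}")
        if min(vox.shape) < 1:
            raise GeometryError(f"degenerate shape {vox.shape}")
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise GeometryError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(sp))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size (mm) spanned by voxel centres, per axis."""
        return (np.array(self.shape) - 1) * np.array(self.spacing)

    def same_grid(self, other: "Image3D | DisplacementField") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_voxels(self, voxels: np.ndarray) -> "Image3D":
        return Image3D(voxels, self.spacing, self.origin)

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (…,3) voxel indices to physical mm positions."""
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    def physical_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Map (…,3) physical mm positions to fractional voxel indices."""
        return (np.asarray(pos) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass(frozen=True)
class DisplacementField:
    """Per-voxel displacement vectors (mm) on a fixed-image grid.

    ``vectors`` has shape ``(nx, ny, nz, 3)``; component order matches the
    array axis order.
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vec = np.asarray(self.vectors, dtype=float)
        if vec.ndim != 4 or vec.shape[-1] != 3:
            raise GeometryError(f"field must have shape (nx,ny,nz,3), got {vec.shape}")
        if not np.all(np.isfinite(vec)):
            raise GeometryError("displacement field contains non-finite values")
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise GeometryError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "vectors", vec)
        object.__setattr__(self, "spacing", tuple(sp))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    @classmethod
    def zeros_like(cls, img: Image3D) -> "DisplacementField":
        return cls(np.zeros(img.shape + (3,)), img.spacing, img.origin)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def with_vectors(self, vectors: np.ndarray) -> "DisplacementField":
        return DisplacementField(vectors, self.spacing, self.origin)


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} segmentation on an image grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise GeometryError(f"mask must be 3-D, got ndim={vox.ndim}")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, got {uniq[:10]}")
        object.__setattr__(self, "voxels", vox.astype(np.uint8))
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise GeometryError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "spacing", tuple(sp))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def volume_voxels(self) -> int:
        return int(self.voxels.sum())

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def as_image(self) -> Image3D:
        return Image3D(self.voxels.astype(float), self.spacing, self.origin)


@dataclass(frozen=True)
class LandmarkSet:
    """Labelled physical-space points (mm)."""

    points: tuple[tuple[str, tuple[float, float, float]], ...]

    def __post_init__(self):
        pts = tuple((str(lbl), tuple(float(c) for c in pos)) for lbl, pos in self.points)
        labels = [lbl for lbl, _ in pts]
        if len(set(labels)) != len(labels):
            raise ValueError("landmark labels must be unique")
        for lbl, pos in pts:
            if len(pos) != 3 or not all(np.isfinite(pos)):
                raise ValueError(f"landmark {lbl!r} has invalid position {pos}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def labels(self) -> list[str]:
        return [lbl for lbl, _ in self.points]

    def position(self, label: str) -> np.ndarray:
        for lbl, pos in self.points:
            if lbl == label:
                return np.array(pos)
        raise KeyError(label)

    @classmethod
    def from_dict(cls, d: dict[str, Iterable[float]]) -> "LandmarkSet":
        return cls(tuple((k, tuple(v)) for k, v in d.items()))


def voxel_diagonal(spacing: Iterable[float]) -> float:
    """Euclidean length (mm) of one voxel's space diagonal."""
    sp = np.asarray(list(spacing), dtype=float)
    if sp.shape != (3,) or np.any(sp <= 0):
        raise ValueError(f"spacing must be 3 positive floats, got {spacing}")
    return float(np.sqrt(np.sum(sp**2)))


# ---------------------------------------------------------------------------
# warping / resampling
# ---------------------------------------------------------------------------

_ORDERS = {"linear": 1, "nearest": 0}


def _check_field_on_grid(field: DisplacementField, target_shape, what: str) -> None:
    if field.shape != tuple(target_shape):
        raise GeometryError(
            f"{what}: field grid {field.shape} does not match target grid {tuple(target_shape)}"
        )


def _sample_moving(
    moving: Image3D,
    positions_mm: np.ndarray,
    order: int,
    background: float,
) -> np.ndarray:
    """Sample ``moving`` at (…,3) physical positions with constant padding."""
    idx = moving.physical_to_index(positions_mm)
    coords = np.moveaxis(idx, -1, 0)
    return ndimage.map_coordinates(
        np.asarray(moving.voxels, dtype=float),
        coords,
        order=order,
        mode="constant",
        cval=background,
        prefilter=False,
    )


def _grid_positions_mm(shape, spacing, origin) -> np.ndarray:
    axes = [np.asarray(origin)[a] + np.arange(shape[a]) * np.asarray(spacing)[a] for a in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack(grid, axis=-1)


def apply_warp(
    moving: Image3D,
    fld: DisplacementField,
    interpolation: str = "linear",
    background: float | None = None,
) -> Image3D:
    """Backward-warp ``moving`` onto the field's (fixed) grid.

    ``output(x) = moving(x + u(x))`` with ``x`` a fixed-grid position;
    out-of-extent samples take ``background`` (default: moving's minimum).
    """
    if interpolation not in _ORDERS:
        raise ValueError(f"interpolation must be one of {sorted(_ORDERS)}")
    if background is None:
        background = float(np.min(moving.voxels))
    pos = _grid_positions_mm(fld.shape, fld.spacing, fld.origin) + fld.vectors
    out = _sample_moving(moving, pos, _ORDERS[interpolation], background)
    return Image3D(out, fld.spacing, fld.origin)


def warp_mask(
    mask: BinaryMask,
    fld: DisplacementField,
    method: str = "nearest",
) -> BinaryMask:
    """Propagate a binary mask through a displacement field.

    ``method='nearest'`` preserves binarity directly; ``method='linear'``
    resamples linearly then thresholds at 0.5.
    """
    if method not in ("nearest", "linear"):
        raise ValueError("mask warping method must be 'nearest' or 'linear'")
    img = Image3D(mask.voxels.astype(float), mask.spacing, mask.origin)
    warped = apply_warp(img, fld, interpolation=method, background=0.0)
    vox = warped.voxels >= 0.5 if method == "linear" else warped.voxels > 0.5
    return BinaryMask(vox.astype(np.uint8), fld.spacing, fld.origin)


def resample_to_grid(img: Image3D, target: Image3D, interpolation: str = "linear",
                     background: float | None = None) -> Image3D:
    """Trilinearly resample ``img`` onto ``target``'s grid (spacing/origin/shape)."""
    if min(target.shape) < 1:
        raise GeometryError(f"degenerate target shape {target.shape}")
    if background is None:
        background = float(np.min(img.voxels))
    pos = _grid_positions_mm(target.shape, target.spacing, target.origin)
    out = _sample_moving(img, pos, _ORDERS[interpolation], background)
    return Image3D(out, target.spacing, target.origin)


def jacobian_determinant(fld: DisplacementField) -> Image3D:
    """Per-voxel ``det(I + ∇u)`` with gradients in physical units (mm/mm).

    Central differences in the interior, one-sided at the boundary
    (``np.gradient`` convention).
    """
    if min(fld.shape) < 2:
        raise GeometryError(f"field shape {fld.shape} too small for differentiation")
    sp = fld.spacing
    J = np.empty(fld.shape + (3, 3))
    for comp in range(3):
        grads = np.gradient(fld.vectors[..., comp], sp[0], sp[1], sp[2])
        for axis in range(3):
            J[..., comp, axis] = grads[axis]
    J[..., 0, 0] += 1.0
    J[..., 1, 1] += 1.0
    J[..., 2, 2] += 1.0
    det = np.linalg.det(J)
    return Image3D(det, fld.spacing, fld.origin)


def compose_fields(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Compose two backward warps: result(x) = inner(x) + outer(x + inner(x)).

    Warping with the result is equivalent (up to interpolation) to warping
    with ``outer`` first and then warping that intermediate with ``inner``.
    """
    if outer.shape != inner.shape:
        raise GeometryError(f"cannot compose fields of shapes {outer.shape} and {inner.shape}")
    pos = _grid_positions_mm(inner.shape, inner.spacing, inner.origin) + inner.vectors
    idx = (pos - np.asarray(outer.origin)) / np.asarray(outer.spacing)
    coords = np.moveaxis(idx, -1, 0)
    sampled = np.empty_like(inner.vectors)
    for c in range(3):
        sampled[..., c] = ndimage.map_coordinates(
            outer.vectors[..., c], coords, order=1, mode="nearest", prefilter=False
        )
    return DisplacementField(inner.vectors + sampled, inner.spacing, inner.origin)


def field_displaced_positions(fld: DisplacementField) -> np.ndarray:
    """Physical sampling positions x + u(x), shape (nx,ny,nz,3)."""
    return _grid_positions_mm(fld.shape, fld.spacing, fld.origin) + fld.vectors
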