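"""Intensity similarity metrics and the mutual-information force field.

Mutual information is reported in nats (natural log).  The force field is
the per-voxel derivative of a Parzen-smoothed pointwise MI contribution with
respect to the moving intensity, multiplied by the spatial gradient of the
warped moving image — the similarity term that drives both the control-point
and the fluid stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_model import BinaryMask, GeometryError, Image3D


@dataclass(frozen=True)
class JointHistogram:
    """Hard-binned joint intensity counts with their bin edges."""

    counts: np.ndarray        # (bins_fixed, bins_moving)
    edges_fixed: np.ndarray
    edges_moving: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def marginal_fixed(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def marginal_moving(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transposed(self) -> "JointHistogram":
        return JointHistogram(self.counts.T.copy(), self.edges_moving, self.edges_fixed)


def _region_values(fixed: Image3D, moving: Image3D, mask: BinaryMask | None):
    if fixed.shape != moving.shape:
        raise GeometryError(f"image grids differ: {fixed.shape} vs {moving.shape}")
    f = np.asarray(fixed.voxels, dtype=float)
    m = np.asarray(moving.voxels, dtype=float)
    if mask is not None:
        if mask.shape != fixed.shape:
            raise GeometryError(f"mask grid {mask.shape} differs from image grid {fixed.shape}")
        sel = mask.voxels.astype(bool)
        if not sel.any():
            raise ValueError("evaluation mask is empty")
        return f[sel], m[sel]
    return f.ravel(), m.ravel()


def _edges(values: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        hi = lo + 1.0  # constant image: widen the degenerate range by one unit
    return np.linspace(lo, hi, bins + 1)


def joint_histogram(
    fixed: Image3D,
    moving_warped: Image3D,
    bins: int = 64,
    mask: BinaryMask | None = None,
) -> JointHistogram:
    """Hard-binned joint histogram over the mask (or the whole grid)."""
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    f, m = _region_values(fixed, moving_warped, mask)
    ef, em = _edges(f, bins), _edges(m, bins)
    counts, _, _ = np.histogram2d(f, m, bins=(ef, em))
    return JointHistogram(counts, ef, em)


def entropy_marginal(h: JointHistogram, which: str) -> float:
    p = (h.marginal_fixed() if which == "fixed" else h.marginal_moving()) / h.n
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def mutual_information(h: JointHistogram) -> float:
    """MI in nats: sum over nonzero cells of p(f,m) ln[p(f,m)/(p(f)p(m))].

    Accumulated with ``math.fsum`` so the result is invariant to summation
    order — MI(A,B) equals MI(B,A) bit-for-bit under histogram transpose.
    """
    import math

    n = h.n
    if n <= 0:
        raise ValueError("joint histogram is empty")
    pjoint = h.counts / n
    pf = pjoint.sum(axis=1, keepdims=True)
    pm = pjoint.sum(axis=0, keepdims=True)
    nz = pjoint > 0
    terms = pjoint[nz] * (np.log(pjoint[nz]) - np.log((pf * pm)[nz]))
    return math.fsum(terms)


def mi(fixed: Image3D, moving_warped: Image3D, bins: int = 64,
       mask: BinaryMask | None = None) -> float:
    """Convenience: MI of the hard-binned joint histogram."""
    return mutual_information(joint_histogram(fixed, moving_warped, bins, mask))


def ncc(fixed: Image3D, moving_warped: Image3D, mask: BinaryMask | None = None) -> float:
    """Pearson correlation of intensities over the evaluation region."""
    f, m = _region_values(fixed, moving_warped, mask)
    fc, mc = f - f.mean(), m - m.mean()
    sf, sm = np.sqrt(np.sum(fc**2)), np.sqrt(np.sum(mc**2))
    if sf == 0 or sm == 0:
        raise ValueError("NCC undefined: at least one image is constant on the region")
    return float(np.clip(np.sum(fc * mc) / (sf * sm), -1.0, 1.0))


def mean_abs_diff(fixed: Image3D, moving_warped: Image3D,
                  mask: BinaryMask | None = None) -> float:
    """Mean absolute intensity difference over the region."""
    f, m = _region_values(fixed, moving_warped, mask)
    return float(np.mean(np.abs(f - m)))


def clamp_percentiles(img: Image3D, lo_pct: float = 0.5, hi_pct: float = 99.5) -> Image3D:
    """Clamp intensities to a percentile window (stabilises histogram bins)."""
    lo, hi = np.percentile(img.voxels, [lo_pct, hi_pct])
    return img.with_voxels(np.clip(np.asarray(img.voxels, dtype=float), lo, hi))


# ---------------------------------------------------------------------------
# MI-derived force field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceField:
    """Per-voxel similarity force vectors on the fixed grid (arb. units)."""

    vectors: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        vec = np.asarray(self.vectors, dtype=float)
        if vec.ndim != 4 or vec.shape[-1] != 3:
            raise GeometryError(f"force must have shape (nx,ny,nz,3), got {vec.shape}")
        if not np.all(np.isfinite(vec)):
            raise GeometryError("force field contains non-finite values")
        object.__setattr__(self, "vectors", vec)

    @property
    def shape(self):
        return self.vectors.shape[:3]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


def _spatial_gradient(values: np.ndarray, spacing) -> np.ndarray:
    g = np.gradient(values, spacing[0], spacing[1], spacing[2])
    return np.stack(g, axis=-1)


def mi_force(
    fixed: Image3D,
    moving_warped: Image3D,
    bins: int = 64,
    parzen_sigma_bins: float = 1.0,
    mask: BinaryMask | None = None,
) -> ForceField:
    """MI ascent force: F(x) = L'(f(x), m(x)) * ∇m(x).

    ``L(f,m) = ln[p(f,m) / (p(f) p(m))]`` on a Parzen-smoothed (Gaussian,
    ``parzen_sigma_bins`` wide) joint histogram; ``L'`` is its derivative
    along the moving-intensity axis, looked up per voxel by bin.  Displacing
    a voxel's sampling position along F locally increases MI.
    """
    if bins < 8:
        raise ValueError(f"force computation requires bins >= 8, got {bins}")
    if fixed.shape != moving_warped.shape:
        raise GeometryError(f"image grids differ: {fixed.shape} vs {moving_warped.shape}")
    h = joint_histogram(fixed, moving_warped, bins, mask)
    counts = ndimage.gaussian_filter(h.counts, sigma=parzen_sigma_bins, mode="constant")
    eps = 1e-10
    pjoint = counts / max(counts.sum(), eps) + eps
    pf = pjoint.sum(axis=1, keepdims=True)
    pm = pjoint.sum(axis=0, keepdims=True)
    L = np.log(pjoint) - np.log(pf) - np.log(pm)

    bw_f = h.edges_fixed[1] - h.edges_fixed[0]
    bw_m = h.edges_moving[1] - h.edges_moving[0]
    dL_dm = np.gradient(L, axis=1) / bw_m  # per intensity unit

    # continuous lookup at sub-bin precision: evaluating the derivative at
    # the true intensity pair (not the bin centre) makes the force vanish on
    # the Parzen ridge for perfectly registered images
    fvals = np.asarray(fixed.voxels, dtype=float)
    mvals = np.asarray(moving_warped.voxels, dtype=float)
    cf = (fvals - h.edges_fixed[0]) / bw_f - 0.5
    cm = (mvals - h.edges_moving[0]) / bw_m - 0.5
    coeff = ndimage.map_coordinates(
        dL_dm, [cf.ravel(), cm.ravel()], order=1, mode="nearest"
    ).reshape(fvals.shape)

    grad_m = _spatial_gradient(mvals, moving_warped.spacing)  # intensity / mm
    vec = coeff[..., None] * grad_m
    if mask is not None:
        vec = vec * mask.voxels.astype(bool)[..., None]
    return ForceField(vec, fixed.spacing, fixed.origin)


def ssd_force(fixed: Image3D, moving_warped: Image3D,
              mask: BinaryMask | None = None, **_ignored) -> ForceField:
    """Sum-of-squared-difference descent force, for mono-modal tests.

    F(x) = (f(x) - m(x)) * ∇m(x): displacing the sampling position along F
    decreases (f - m)^2 pointwise.
    """
    if fixed.shape != moving_warped.shape:
        raise GeometryError(f"image grids differ: {fixed.shape} vs {moving_warped.shape}")
    fvals = np.asarray(fixed.voxels, dtype=float)
    mvals = np.asarray(moving_warped.voxels, dtype=float)
    grad_m = _spatial_gradient(mvals, moving_warped.spacing)
    vec = (fvals - mvals)[..., None] * grad_m
    scale = np.abs(vec).max()
    if scale > 0:
        vec = vec / scale
    if mask is not None:
        vec = vec * mask.voxels.astype(bool)[..., None]
    return ForceField(vec, fixed.spacing, fixed.origin)
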