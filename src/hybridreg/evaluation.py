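"""Warp-based and statistical evaluation: DSC, Hausdorff distance, centroid
TRE, paired t-test, and per-case report assembly."""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.special import betainc

from .image_model import BinaryMask, DisplacementField, GeometryError, warp_mask


def dsc(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) on voxel counts."""
    if a.shape != b.shape:
        raise GeometryError(f"mask grids differ: {a.shape} vs {b.shape}")
    na, nb = a.volume_voxels(), b.volume_voxels()
    if na + nb == 0:
        raise ValueError("DSC undefined: both masks are empty")
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def surface_voxels(mask: BinaryMask) -> np.ndarray:
    """(n,3) indices of member voxels with at least one non-member 6-neighbour."""
    vox = mask.voxels.astype(bool)
    eroded = ndimage.binary_erosion(vox, structure=ndimage.generate_binary_structure(3, 1),
                                    border_value=0)
    return np.argwhere(vox & ~eroded)


def _surface_points_mm(mask: BinaryMask) -> np.ndarray:
    idx = surface_voxels(mask)
    if len(idx) == 0:
        raise ValueError("mask is empty")
    return np.asarray(mask.origin) + idx * np.asarray(mask.spacing)


def hausdorff_directed(a: BinaryMask, b: BinaryMask) -> float:
    """max over A-surface points of the distance (mm) to the nearest B-surface point."""
    pa, pb = _surface_points_mm(a), _surface_points_mm(b)
    d, _ = cKDTree(pb).query(pa, k=1)
    return float(d.max())


def hausdorff_symmetric(a: BinaryMask, b: BinaryMask) -> float:
    return max(hausdorff_directed(a, b), hausdorff_directed(b, a))


def marker_centroid(mask: BinaryMask) -> np.ndarray:
    """Unweighted mean physical position (mm) of the member voxels."""
    idx = np.argwhere(mask.voxels)
    if len(idx) == 0:
        raise ValueError("cannot take the centroid of an empty mask")
    return np.asarray(mask.origin) + idx.mean(axis=0) * np.asarray(mask.spacing)


def tre(
    marker_moving: BinaryMask,
    marker_fixed: BinaryMask,
    fld: DisplacementField | None,
    warp_method: str = "linear",
) -> float:
    """Centroid target registration error (mm).

    The moving-side marker is propagated through the field onto the fixed
    grid and its centroid compared with the fixed-side marker's centroid.
    ``fld=None`` evaluates the unregistered (identity) error.
    """
    if marker_fixed.volume_voxels() == 0 or marker_moving.volume_voxels() == 0:
        raise ValueError("marker masks must be nonempty")
    if fld is None:
        warped = marker_moving
    else:
        warped = warp_mask(marker_moving, fld, method=warp_method)
        if warped.volume_voxels() == 0:
            raise ValueError("warped marker is empty: degenerate warp field")
    return float(np.linalg.norm(marker_centroid(warped) - marker_centroid(marker_fixed)))


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Classic paired t on d = x - y; returns (t, two-sided p) with n-1 df.

    p computed from the regularised incomplete beta function:
    ``P(|T| > t) = I_{df/(df+t^2)}(df/2, 1/2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 2:
        raise ValueError(f"need n >= 2 pairs, got {n}")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of the paired differences: t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(betainc(df / 2.0, 0.5, df / (df + t * t)))
    return t, p


@dataclass
class RegistrationReport:
    """Per-case record: intensity metrics, per-structure overlap, per-point TRE."""

    metrics_before: dict = dc_field(default_factory=dict)
    metrics_after: dict = dc_field(default_factory=dict)
    structures: dict = dc_field(default_factory=dict)   # label -> {dsc, hd_*}
    points: dict = dc_field(default_factory=dict)       # label -> {tre_mm, ...}
    traces: dict = dc_field(default_factory=dict)
    meta: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, Mapping):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if hasattr(obj, "mi") and hasattr(obj, "rows"):
                return list(obj.rows())
            if hasattr(obj, "mi"):
                return {"mi": list(obj.mi)}
            return obj
        return {
            "metrics_before": clean(self.metrics_before),
            "metrics_after": clean(self.metrics_after),
            "structures": clean(self.structures),
            "points": clean(self.points),
            "traces": clean(self.traces),
            "meta": clean(self.meta),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_case(
    fixed_masks: Mapping[str, BinaryMask],
    moving_masks: Mapping[str, BinaryMask],
    fixed_markers: Mapping[str, BinaryMask],
    moving_markers: Mapping[str, BinaryMask],
    fld: DisplacementField,
    report: RegistrationReport | None = None,
) -> RegistrationReport:
    """Propagate moving-side structures/markers through the field and score
    them against the fixed-side annotations.

    Structures or markers present on only one side are flagged in the report
    instead of aborting the whole evaluation.
    """
    rep = report or RegistrationReport()
    for label in sorted(set(fixed_masks) | set(moving_masks)):
        if label not in fixed_masks or label not in moving_masks:
            rep.structures[label] = {"error": "missing on one side"}
            continue
        try:
            warped = warp_mask(moving_masks[label], fld)
            rep.structures[label] = {
                "dsc": dsc(fixed_masks[label], warped),
                "hd_mm": hausdorff_symmetric(fixed_masks[label], warped),
                "hd_directed_fixed_to_warped_mm": hausdorff_directed(fixed_masks[label], warped),
                "hd_directed_warped_to_fixed_mm": hausdorff_directed(warped, fixed_masks[label]),
            }
        except ValueError as exc:
            rep.structures[label] = {"error": f"{label}: {exc}"}
    for label in sorted(set(fixed_markers) | set(moving_markers)):
        if label not in fixed_markers or label not in moving_markers:
            rep.points[label] = {"error": "missing on one side"}
            continue
        try:
            rep.points[label] = {
                "tre_mm": tre(moving_markers[label], fixed_markers[label], fld),
                "tre_before_mm": tre(moving_markers[label], fixed_markers[label], None),
            }
        except ValueError as exc:
            rep.points[label] = {"error": f"{label}: {exc}"}
    return rep
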