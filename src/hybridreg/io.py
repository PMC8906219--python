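"""Readers/writers for volumes (NIfTI, MetaImage), displacement fields,
landmark CSVs, and JSON run configs.

Conventions on disk: volumes float32, masks uint8, displacement components
always millimetres.  The index->world affine is diagonal (spacing) plus the
origin; no reorientation is performed — inputs are assumed co-registered.
"""

from __future__ import annotations

import csv
import json
from dataclasses import fields as dc_fields
from pathlib import Path

import nibabel as nib
import numpy as np

from .ffd import FFDConfig
from .fluid import FluidConfig
from .image_model import BinaryMask, DisplacementField, Image3D, LandmarkSet
from .pipeline import PipelineConfig

_NIFTI_EXTS = (".nii", ".nii.gz")
_META_EXTS = (".mha", ".mhd")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _geometry_from_affine(aff: np.ndarray):
    spacing = tuple(float(np.linalg.norm(aff[:3, a])) for a in range(3))
    origin = tuple(float(o) for o in aff[:3, 3])
    return spacing, origin


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_EXTS)


def _is_meta(path: Path) -> bool:
    return path.suffix in _META_EXTS


# -- MetaImage (uncompressed, local-data .mha) --------------------------------

_MET_TYPES = {
    "MET_FLOAT": np.float32, "MET_DOUBLE": np.float64,
    "MET_UCHAR": np.uint8, "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16, "MET_SHORT": np.int16,
    "MET_UINT": np.uint32, "MET_INT": np.int32,
}


def _write_mha(path: Path, vox: np.ndarray, spacing, origin) -> None:
    vox = np.ascontiguousarray(vox)
    met = {np.dtype(np.float32): "MET_FLOAT", np.dtype(np.uint8): "MET_UCHAR"}[vox.dtype]
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        "TransformMatrix = 1 0 0 0 1 0 0 0 1\n"
        f"Offset = {origin[0]} {origin[1]} {origin[2]}\n"
        f"ElementSpacing = {spacing[0]} {spacing[1]} {spacing[2]}\n"
        f"DimSize = {vox.shape[0]} {vox.shape[1]} {vox.shape[2]}\n"
        f"ElementType = {met}\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(vox.tobytes(order="F"))  # first index fastest, MetaImage convention


def _read_mha(path: Path):
    with open(path, "rb") as fh:
        header: dict[str, str] = {}
        while True:
            line = fh.readline().decode("ascii")
            if not line:
                raise ValueError(f"{path}: truncated MetaImage header")
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
            if key.strip() == "ElementDataFile":
                break
        if header.get("ElementDataFile") != "LOCAL":
            raise ValueError(f"{path}: only LOCAL-data .mha files are supported")
        if header.get("CompressedData", "False") == "True":
            raise ValueError(f"{path}: compressed MetaImage is not supported")
        shape = tuple(int(v) for v in header["DimSize"].split())
        dtype = _MET_TYPES[header["ElementType"]]
        raw = fh.read()
    vox = np.frombuffer(raw, dtype=dtype, count=int(np.prod(shape))).reshape(shape, order="F")
    spacing = tuple(float(v) for v in header.get("ElementSpacing", "1 1 1").split())
    origin = tuple(float(v) for v in header.get("Offset", "0 0 0").split())
    return vox.copy(), spacing, origin


# -- volumes ------------------------------------------------------------------

def read_volume(path) -> Image3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        vox = np.asarray(img.dataobj, dtype=np.float64)
        if vox.ndim != 3:
            raise ValueError(f"{path}: expected a 3-D scalar volume, got shape {vox.shape}")
        spacing, origin = _geometry_from_affine(img.affine)
        return Image3D(vox, spacing, origin)
    if _is_meta(path):
        vox, spacing, origin = _read_mha(path)
        return Image3D(vox.astype(np.float64), spacing, origin)
    raise ValueError(f"unknown volume extension: {path.name} (use .nii/.nii.gz/.mha)")


def write_volume(img: Image3D, path, dtype=np.float32) -> None:
    path = Path(path)
    vox = np.asarray(img.voxels).astype(dtype)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(vox, _affine(img.spacing, img.origin)), str(path))
        return
    if _is_meta(path):
        _write_mha(path, vox, img.spacing, img.origin)
        return
    raise ValueError(f"unknown volume extension: {path.name} (use .nii/.nii.gz/.mha)")


def read_mask(path) -> BinaryMask:
    img = read_volume(path)
    return BinaryMask((np.asarray(img.voxels) > 0.5).astype(np.uint8), img.spacing, img.origin)


def write_mask(mask: BinaryMask, path) -> None:
    write_volume(mask.as_image(), path, dtype=np.uint8)


# -- displacement fields ------------------------------------------------------

def write_field(fld: DisplacementField, path) -> None:
    """Store as a 4-D NIfTI (nx,ny,nz,3); components in mm along array axes."""
    path = Path(path)
    if not _is_nifti(path):
        raise ValueError(f"fields are stored as NIfTI; got {path.name}")
    img = nib.Nifti1Image(fld.vectors.astype(np.float32), _affine(fld.spacing, fld.origin))
    img.header["descrip"] = b"displacement mm; components = array axes x,y,z"
    nib.save(img, str(path))


def read_field(path) -> DisplacementField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"field not found: {path}")
    img = nib.load(str(path))
    vec = np.asarray(img.dataobj, dtype=np.float64)
    if vec.ndim == 5 and vec.shape[3] == 1:  # tolerate the NIfTI vector convention
        vec = vec[:, :, :, 0, :]
    if vec.ndim != 4 or vec.shape[-1] != 3:
        raise ValueError(f"{path}: expected a 3-component vector volume, got shape {vec.shape}")
    spacing, origin = _geometry_from_affine(img.affine)
    return DisplacementField(vec, spacing, origin)


# -- landmarks ----------------------------------------------------------------

_LANDMARK_HEADER = ["label", "x_mm", "y_mm", "z_mm"]


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"landmark file not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _LANDMARK_HEADER:
            raise ValueError(f"{path}: expected header {','.join(_LANDMARK_HEADER)}")
        points = []
        for row in reader:
            if not row:
                continue
            label = row[0].strip()
            try:
                pos = tuple(float(v) for v in row[1:4])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric coordinates for {label!r}") from exc
            points.append((label, pos))
    return LandmarkSet(tuple(points))


def write_landmarks(lms: LandmarkSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LANDMARK_HEADER)
        for label, pos in lms.points:
            writer.writerow([label, *(f"{c:.6f}" for c in pos)])


# -- run configuration --------------------------------------------------------

def _build_dataclass(cls, data: dict, where: str):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) under {where}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    """Strict JSON-dict -> PipelineConfig (unknown keys rejected)."""
    data = dict(data)
    ffd_cfg = _build_dataclass(FFDConfig, data.pop("ffd", {}), "ffd")
    fluid_cfg = _build_dataclass(FluidConfig, data.pop("fluid", {}), "fluid")
    for key in ("ffd_on_levels", "fluid_on_levels"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    cfg = _build_dataclass(PipelineConfig, data, "<root>")
    cfg.ffd, cfg.fluid = ffd_cfg, fluid_cfg
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    out = {f.name: getattr(cfg, f.name) for f in dc_fields(cfg) if f.name not in ("ffd", "fluid")}
    out["ffd"] = {f.name: getattr(cfg.ffd, f.name) for f in dc_fields(cfg.ffd)}
    out["fluid"] = {f.name: getattr(cfg.fluid, f.name) for f in dc_fields(cfg.fluid)}
    return out


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(json.load(fh))
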