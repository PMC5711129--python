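"""NRRD / MetaImage volume I/O.

NRRD is the primary on-disk format; MetaImage (.mha/.mhd) is also accepted.
Headers carry spacing and origin in mm. Scalar volumes are stored as the
image payload; masks as uint8 (0/1) volumes; vector fields as 3-component
images whose components are (x, y, z) displacements in mm. DICOM is
deliberately unsupported.

Internally arrays are indexed ``[x, y, z]``; SimpleITK's array view is
``[z, y, x]``, so every read/write transposes.
"""

from __future__ import annotations

import os

import numpy as np
import SimpleITK as sitk

from .grid import Grid3D, ScalarVolume, StructureMask, VectorField

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_vector_field",
    "write_vector_field",
]

_EXTENSIONS = (".nrrd", ".nhdr", ".mha", ".mhd")


def _check_path(path: str, for_read: bool):
    if not str(path).lower().endswith(_EXTENSIONS):
        raise ValueError(
            f"unsupported volume format for {path!r}; expected one of {_EXTENSIONS}"
        )
    if for_read and not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")


def _grid_from_image(img: sitk.Image, path: str) -> Grid3D:
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: payload is {img.GetDimension()}D, expected 3D")
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive spacing {spacing}")
    size = img.GetSize()  # (x, y, z)
    return Grid3D(shape=tuple(size), spacing=tuple(spacing), origin=tuple(img.GetOrigin()))


def _image_from_grid(arr_xyz: np.ndarray, grid: Grid3D, vector: bool = False) -> sitk.Image:
    if vector:
        arr_zyx = np.ascontiguousarray(np.transpose(arr_xyz, (2, 1, 0, 3)))
        img = sitk.GetImageFromArray(arr_zyx, isVector=True)
    else:
        arr_zyx = np.ascontiguousarray(np.transpose(arr_xyz, (2, 1, 0)))
        img = sitk.GetImageFromArray(arr_zyx)
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    return img


def read_volume(path: str, kind: str = "dimensionless") -> ScalarVolume:
    """Read a 3D scalar volume; ``kind`` tags the unit (HU, Gy, dimensionless)."""
    _check_path(path, for_read=True)
    img = sitk.ReadImage(str(path))
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(f"{path}: expected scalar payload, got "
                         f"{img.GetNumberOfComponentsPerPixel()} components")
    grid = _grid_from_image(img, path)
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0)).astype(np.float64)
    return ScalarVolume(grid, arr, unit=kind)


def write_volume(vol: ScalarVolume, path: str):
    _check_path(path, for_read=False)
    sitk.WriteImage(_image_from_grid(vol.values, vol.grid), str(path))


def read_mask(path: str, name: str = "") -> StructureMask:
    _check_path(path, for_read=True)
    img = sitk.ReadImage(str(path))
    grid = _grid_from_image(img, path)
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return StructureMask(grid, arr > 0, name=name or os.path.basename(path))


def write_mask(mask: StructureMask, path: str):
    _check_path(path, for_read=False)
    arr = mask.member.astype(np.uint8)
    sitk.WriteImage(_image_from_grid(arr, mask.grid), str(path))


def read_vector_field(path: str) -> VectorField:
    """Read a 3-component displacement field (components in mm, pull-back)."""
    _check_path(path, for_read=True)
    img = sitk.ReadImage(str(path))
    if img.GetNumberOfComponentsPerPixel() != 3:
        raise ValueError(f"{path}: expected 3-component field, got "
                         f"{img.GetNumberOfComponentsPerPixel()}")
    grid = _grid_from_image(img, path)
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0, 3)).astype(np.float64)
    return VectorField(grid, arr)


def write_vector_field(field: VectorField, path: str):
    _check_path(path, for_read=False)
    sitk.WriteImage(_image_from_grid(field.displacements, field.grid, vector=True), str(path))
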