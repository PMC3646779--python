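"""Image stacks, border masks, acquisition geometry, and file I/O.

Conventions used throughout the package:

* the slice axis is axis 0; in-plane axes are (row, col); indexing is 0-based;
* intensities are kept in their native units — nothing is rescaled on read,
  because the downstream quantizer is adaptive and silent rescaling would
  break reproducibility;
* 1 mm^3 == 1 µL, so voxel volumes are reported in microlitres directly.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile
import yaml

logger = logging.getLogger("fibroquant")

__all__ = [
    "ImageGeometry",
    "LungStack",
    "BorderMask",
    "GEOMETRY_PRESETS",
    "get_preset",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "load_config",
]


@dataclass(frozen=True)
class ImageGeometry:
    """Acquisition geometry converting pixel counts to physical areas/volumes.

    Parameters
    ----------
    matrix_size : int
        In-plane matrix size (square acquisition matrix), pixels per axis.
    field_of_view_mm : float
        In-plane field of view (square), millimetres.
    slice_thickness_mm : float
        Slice thickness, millimetres.
    n_slices : int
        Number of axial slices covering the lung.
    """

    matrix_size: int
    field_of_view_mm: float
    slice_thickness_mm: float
    n_slices: int

    def __post_init__(self) -> None:
        if self.matrix_size < 2:
            raise ValueError("matrix_size must be >= 2")
        if self.field_of_view_mm <= 0:
            raise ValueError("field_of_view_mm must be positive")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")

    @property
    def pixel_size_mm(self) -> float:
        return self.field_of_view_mm / self.matrix_size

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_size_mm ** 2

    @property
    def voxel_volume_ul(self) -> float:
        """Voxel volume in µL (1 mm^3 = 1 µL)."""
        return self.pixel_area_mm2 * self.slice_thickness_mm

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_slices, self.matrix_size, self.matrix_size)

    def to_dict(self) -> dict:
        return {
            "matrix_size": self.matrix_size,
            "field_of_view_mm": self.field_of_view_mm,
            "slice_thickness_mm": self.slice_thickness_mm,
            "n_slices": self.n_slices,
        }


#: Named acquisition presets for the 4.7 T UTE protocols (mouse and rat).
GEOMETRY_PRESETS: dict[str, ImageGeometry] = {
    "mouse47t": ImageGeometry(192, 30.0, 1.4, 10),
    "rat47t": ImageGeometry(192, 60.0, 2.0, 18),
}


def get_preset(name: str) -> ImageGeometry:
    try:
        return GEOMETRY_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown geometry preset {name!r}; "
            f"available: {sorted(GEOMETRY_PRESETS)}"
        ) from None


@dataclass
class LungStack:
    """A 3D lung MR intensity stack plus its acquisition geometry.

    ``voxels`` has shape ``(n_slices, matrix, matrix)`` and non-negative,
    finite intensities in native (arbitrary) units.
    """

    voxels: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("stack must be 3D (slice, row, col)")
        if self.voxels.shape != self.geometry.shape:
            raise ValueError(
                f"stack shape {self.voxels.shape} inconsistent with geometry "
                f"shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack contains non-finite intensities")
        if np.any(self.voxels < 0):
            raise ValueError("stack contains negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BorderMask:
    """Per-slice binary lung-border region constraining the segmentation.

    Replaces the interactively drawn per-slice lung borders of the original
    workflow. Slices without any in-border pixel are flagged (``empty_slices``)
    and excluded from analysis rather than treated as an error.
    """

    mask: np.ndarray
    empty_slices: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (slice, row, col)")
        self.empty_slices = tuple(
            int(i) for i in range(self.mask.shape[0]) if not self.mask[i].any()
        )
        for i in self.empty_slices:
            logger.warning("mask slice %d has no lung region", i)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def check_matches(self, stack: LungStack) -> None:
        if self.mask.shape != stack.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match stack shape "
                f"{stack.shape}"
            )


# ---------------------------------------------------------------------------
# Stack I/O


def _geometry_from_nifti(img: nib.Nifti1Image) -> ImageGeometry:
    shape = img.shape
    zooms = img.header.get_zooms()[:3]
    if shape[0] != shape[1]:
        raise ValueError("in-plane matrix must be square")
    if not np.isclose(zooms[0], zooms[1]):
        raise ValueError("anisotropic in-plane voxels are not supported")
    return ImageGeometry(
        matrix_size=int(shape[0]),
        field_of_view_mm=float(zooms[0]) * int(shape[0]),
        slice_thickness_mm=float(zooms[2]),
        n_slices=int(shape[2]),
    )


def read_stack(path: str | os.PathLike,
               geometry_override: ImageGeometry | None = None) -> LungStack:
    """Read a 3D stack from NIfTI (.nii/.nii.gz) or multi-page TIFF.

    For NIfTI the geometry is derived from the header voxel sizes unless
    ``geometry_override`` is given. TIFF carries no geometry and is refused
    without an override.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected 3D data, got {data.ndim}D")
        geometry = geometry_override or _geometry_from_nifti(img)
        # stored as (row, col, slice); package convention is slice-first
        voxels = np.ascontiguousarray(np.transpose(data, (2, 0, 1)))
    elif name.endswith((".tif", ".tiff")):
        if geometry_override is None:
            raise ValueError("geometry required: TIFF stacks carry no geometry")
        voxels = tifffile.imread(str(path))
        if voxels.ndim != 3:
            raise ValueError(f"expected 3D data, got {voxels.ndim}D")
        geometry = geometry_override
    else:
        raise ValueError(f"unsupported stack format: {path.name}")
    return LungStack(voxels=voxels, geometry=geometry)


def write_stack(stack: LungStack, path: str | os.PathLike) -> None:
    """Write a stack to NIfTI or multi-page TIFF (lossless round-trip)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        g = stack.geometry
        affine = np.diag([g.pixel_size_mm, g.pixel_size_mm,
                          g.slice_thickness_mm, 1.0])
        data = np.transpose(stack.voxels, (1, 2, 0))
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms((g.pixel_size_mm, g.pixel_size_mm,
                              g.slice_thickness_mm))
        nib.save(img, str(path))
    elif name.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), stack.voxels, photometric="minisblack")
    else:
        raise ValueError(f"unsupported stack format: {path.name}")


# ---------------------------------------------------------------------------
# Mask I/O


def read_mask(path: str | os.PathLike, stack: LungStack) -> BorderMask:
    """Read a border mask from a multi-page TIFF, a per-slice PNG/TIFF file
    set (directory), or a single-slice image. Nonzero pixels are inside the
    border. The mask must match the stack shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise ValueError(f"no mask images found in {path}")
        planes = [np.asarray(iio.imread(f)) for f in files]
        planes = [p[..., 0] if p.ndim == 3 else p for p in planes]
        data = np.stack(planes, axis=0)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
    elif path.suffix.lower() == ".png":
        plane = np.asarray(iio.imread(path))
        if plane.ndim == 3:
            plane = plane[..., 0]
        data = plane[None]
    else:
        raise ValueError(f"unsupported mask format: {path.name}")
    mask = BorderMask(mask=data != 0)
    mask.check_matches(stack)
    if not mask.mask.any():
        logger.warning("mask is entirely empty: all slices flagged")
    return mask


def write_mask(mask: BorderMask, path: str | os.PathLike) -> None:
    """Write a mask as a per-slice 8-bit PNG set (directory) or a TIFF stack."""
    path = Path(path)
    data = (mask.mask.astype(np.uint8)) * 255
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), data, photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i in range(data.shape[0]):
            iio.imwrite(path / f"mask_{i:03d}.png", data[i])


# ---------------------------------------------------------------------------
# Configuration


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML pipeline configuration (geometry presets, stain bounds,
    segmentation parameters)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def geometry_from_config(cfg: dict) -> ImageGeometry:
    g = cfg.get("geometry", cfg)
    if isinstance(g, str):
        return get_preset(g)
    return ImageGeometry(
        matrix_size=int(g["matrix_size"]),
        field_of_view_mm=float(g["field_of_view_mm"]),
        slice_thickness_mm=float(g["slice_thickness_mm"]),
        n_slices=int(g["n_slices"]),
    )
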