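"""Volumes, label maps, NIfTI I/O, isotropic resampling and CT windowing.

All geometry is physical: voxel indices are 0-based and the physical position
of voxel ``(i, j, k)`` is ``origin + index * spacing`` (mm).  Array axes are
``(x, y, z)`` = (left-right, anterior-posterior, caudo-cranial), so an axial
slice is ``data[:, :, k]``.

CT volumes and label maps are interpolated to a common isotropic grid
(default 1.25 mm) with 3rd-order spline and nearest-neighbour interpolation
respectively, so the network filters see equal physical extents in every
orthogonal plane.
"""

from __future__ import annotations

import dataclasses
import os

import nibabel as nib
import numpy as np
from scipy import ndimage

DEFAULT_SPACING_MM = 1.25
N_CLASSES = 6  # background + lymph-node levels I-V


@dataclasses.dataclass
class Volume:
    """A 3D scalar intensity grid (HU) with physical spacing and origin in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclasses.dataclass
class LabelMap:
    """Integer grid aligned to a :class:`Volume`; 0 = background, 1-5 = levels I-V."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_classes: int = N_CLASSES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label data must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label data must be integer-valued")
            self.data = np.round(self.data).astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        vmax = int(self.data.max(initial=0))
        if vmax >= self.n_classes or int(self.data.min(initial=0)) < 0:
            raise ValueError(
                f"labels must lie in [0, {self.n_classes - 1}], found max {vmax}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def foreground(self) -> np.ndarray:
        """Binary mask of the combined level I-V structure."""
        return self.data > 0

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclasses.dataclass(frozen=True)
class WindowSetting:
    """CT display/normalization window: center C_C and width C_W in HU."""

    center: float = 0.0
    width: float = 700.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be > 0")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_volume(vol: Volume, path: str | os.PathLike) -> str:
    img = nib.Nifti1Image(np.asarray(vol.data, np.float32), _affine(vol.spacing, vol.origin))
    nib.save(img, os.fspath(path))
    return os.fspath(path)


def write_labels(lab: LabelMap, path: str | os.PathLike) -> str:
    img = nib.Nifti1Image(np.asarray(lab.data, np.uint8), _affine(lab.spacing, lab.origin))
    nib.save(img, os.fspath(path))
    return os.fspath(path)


def _load(path):
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin


def read_volume(path: str | os.PathLike) -> Volume:
    data, spacing, origin = _load(path)
    return Volume(np.asarray(data, np.float32), spacing, origin)


def read_labels(path: str | os.PathLike, n_classes: int = N_CLASSES) -> LabelMap:
    data, spacing, origin = _load(path)
    return LabelMap(np.asarray(np.round(data), np.uint8), spacing, origin, n_classes)


def resample_isotropic(vol: Volume, target_spacing: float = DEFAULT_SPACING_MM) -> Volume:
    """Resample intensities to isotropic spacing with 3rd-order spline interpolation."""
    if target_spacing <= 0:
        raise ValueError("target_spacing must be > 0")
    zoom = np.asarray(vol.spacing) / target_spacing
    if np.allclose(zoom, 1.0):
        return Volume(vol.data.copy(), (target_spacing,) * 3, vol.origin)
    out = ndimage.zoom(np.asarray(vol.data, np.float64), zoom, order=3,
                       mode="nearest", grid_mode=True)
    return Volume(out.astype(np.float32), (target_spacing,) * 3, vol.origin)


def resample_labels(lab: LabelMap, target_spacing: float = DEFAULT_SPACING_MM) -> LabelMap:
    """Resample a label map with nearest-neighbour interpolation (labels never mix)."""
    if target_spacing <= 0:
        raise ValueError("target_spacing must be > 0")
    zoom = np.asarray(lab.spacing) / target_spacing
    if np.allclose(zoom, 1.0):
        return LabelMap(lab.data.copy(), (target_spacing,) * 3, lab.origin, lab.n_classes)
    out = ndimage.zoom(lab.data, zoom, order=0, mode="nearest", grid_mode=True)
    return LabelMap(out.astype(lab.data.dtype), (target_spacing,) * 3, lab.origin, lab.n_classes)


def apply_window(vol: Volume, w: WindowSetting = WindowSetting()) -> Volume:
    """Map HU through the linear clamp window to [0, 1].

    Intensities at or below ``center - width/2`` map to 0, at or above
    ``center + width/2`` to 1, linearly in between.
    """
    lo = w.center - w.width / 2.0
    out = np.clip((np.asarray(vol.data, np.float32) - lo) / w.width, 0.0, 1.0)
    return Volume(out.astype(np.float32), vol.spacing, vol.origin)
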