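"""Synthetic neck phantoms for exercising the full segmentation pipeline.

A phantom is a CT-like volume (HU) with a paired label map containing
bilateral "lymph-node level" structures I-V stacked cranio-caudally inside a
soft-tissue neck cylinder with a bone-like spine landmark and an air
background.  Geometry mimics the clinically hard features of the task:

* levels II, III and IV are stacked slabs that never share an axial slice
  when the phantom is not angulated (the slice-based contouring assumption);
* level I sits anterior-cranially and level V posteriorly, each attached to
  the II-IV column so the combined I-V structure is one 26-connected
  component per side;
* optional pitch/tilt angulation breaks the axial-exclusivity rule exactly
  the way patient angulation does.

Level tissue is rendered slightly hyperdense (default +30 HU) relative to
the soft-tissue background so that the default 0/700 HU window produces a
learnable but noisy contrast.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volume_io import LabelMap, Volume

__all__ = ["PhantomSpec", "generate_phantom", "angulate"]

MAX_ANGLE_DEG = 20.0


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of the synthetic neck phantom (all lengths in mm)."""

    shape: tuple[int, int, int] = (128, 128, 160)
    spacing: tuple[float, float, float] = (1.25, 1.25, 1.25)
    #: cranio-caudal span per level I-V
    level_extents: dict[int, float] = dataclasses.field(
        default_factory=lambda: {1: 35.0, 2: 40.0, 3: 35.0, 4: 35.0, 5: 85.0})
    lateral_offset: float = 12.0   # medial gap between midline and level column
    band_width: float = 28.0       # lateral width of the level column
    noise_sd: float = 15.0
    tissue_hu: float = 40.0
    level_hu: float = 70.0
    bone_hu: float = 700.0
    air_hu: float = -1000.0
    pitch_deg: float = 0.0
    tilt_deg: float = 0.0
    #: inter-patient variability: fractional range of the random rigid
    #: anatomy shift, cranio-caudal placement shift and level-extent scaling
    #: drawn per seed (0 = every phantom has identical geometry)
    anatomy_jitter: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if any(e <= 0 for e in self.level_extents.values()):
            raise ValueError("level extents must be positive")
        if sorted(self.level_extents) != [1, 2, 3, 4, 5]:
            raise ValueError("level_extents must define levels 1-5")
        z_mm = self.shape[2] * self.spacing[2]
        e = self.level_extents
        if e[2] + e[3] + e[4] > 0.85 * z_mm or e[5] > 0.85 * z_mm:
            raise ValueError("level extents exceed the cranio-caudal grid span")
        if self.lateral_offset + self.band_width > 0.5 * self.shape[0] * self.spacing[0]:
            raise ValueError("level column extends beyond the lateral grid span")

    @classmethod
    def tiny(cls, seed: int = 0, **kw) -> "PhantomSpec":
        """A half-scale phantom for desk-scale training and tests."""
        defaults = dict(
            shape=(64, 64, 80),
            level_extents={1: 18.0, 2: 20.0, 3: 18.0, 4: 18.0, 5: 44.0},
            lateral_offset=6.0,
            band_width=14.0,
            seed=seed,
        )
        defaults.update(kw)
        return cls(**defaults)


def _box(xc, yc, zc, x_lo, x_hi, y_lo, y_hi, z_lo, z_hi):
    return ((xc >= x_lo) & (xc < x_hi) & (yc >= y_lo) & (yc < y_hi)
            & (zc >= z_lo) & (zc < z_hi))


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Render the phantom; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    X, Y, Z = nx * sx, ny * sy, nz * sz

    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    z = (np.arange(nz) + 0.5) * sz
    xc, yc, zc = np.meshgrid(x, y, z, indexing="ij")

    # per-case anatomical variability: rigid in-plane shift, cranio-caudal
    # placement shift and a mild common scale of the level extents
    j = spec.anatomy_jitter
    dx = rng.uniform(-j, j) * X
    dy = rng.uniform(-j, j) * Y
    dz_top = rng.uniform(-j, j) * Z
    e_scale = 1.0 + rng.uniform(-j, j)

    cx, cy = X / 2.0 + dx, Y / 2.0 + dy
    rx, ry = 0.44 * X, 0.44 * Y
    body = ((xc - cx) / rx) ** 2 + ((yc - cy) / ry) ** 2 <= 1.0

    bone_r = 0.055 * min(X, Y)
    bone = ((xc - cx) ** 2 + (yc - (cy + 0.09 * Y)) ** 2) <= bone_r ** 2

    e = {lvl: ext * e_scale for lvl, ext in spec.level_extents.items()}
    z_top = min(0.925 * Z + dz_top, 0.97 * Z)
    z2_lo, z3_lo = z_top - e[2], z_top - e[2] - e[3]
    z4_lo = z3_lo - e[4]
    z5_lo = z4_lo
    z5_hi = min(z5_lo + e[5], z_top)
    z1_lo = z_top - e[1]

    labels = np.zeros(spec.shape, np.uint8)
    lat, band = spec.lateral_offset, spec.band_width
    for s in (+1, -1):
        xb = sorted((cx + s * lat, cx + s * (lat + band)))
        xb_i = sorted((cx + s * (lat - 0.15 * band), cx + s * (lat + 0.7 * band)))
        slab_y = (cy - 0.12 * Y, cy + 0.09 * Y)
        # paint order lets the II-IV column overwrite the small attachment
        # overlaps of levels I and V, keeping II/III/IV axially exclusive
        lvl_boxes = [
            (1, xb_i[0], xb_i[1], 0.25 * Y + dy, slab_y[0] + 0.04 * Y, z1_lo, z_top),
            (5, xb[0], xb[1], slab_y[1] - 0.05 * Y, 0.72 * Y + dy, z5_lo, z5_hi),
            (2, xb[0], xb[1], slab_y[0], slab_y[1], z2_lo, z_top),
            (3, xb[0], xb[1], slab_y[0], slab_y[1], z3_lo, z2_lo),
            (4, xb[0], xb[1], slab_y[0], slab_y[1], z4_lo, z3_lo),
        ]
        for lvl, x0, x1, y0, y1, zlo, zhi in lvl_boxes:
            m = _box(xc, yc, zc, x0, x1, y0, y1, zlo, zhi) & body & ~bone
            labels[m] = lvl

    for lvl in range(1, 6):
        if not np.any(labels == lvl):  # pragma: no cover - guarded by __post_init__
            raise ValueError(f"level {lvl} absent from generated phantom")

    data = np.full(spec.shape, spec.air_hu, np.float32)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)
    data[body] = spec.tissue_hu + noise[body]
    fg = labels > 0
    data[fg] = spec.level_hu + noise[fg]
    data[bone & body] = spec.bone_hu + 0.5 * noise[bone & body]

    vol = Volume(data, spec.spacing)
    lab = LabelMap(labels, spec.spacing)
    if spec.pitch_deg or spec.tilt_deg:
        vol, lab = angulate(vol, lab, spec.pitch_deg, spec.tilt_deg)
    return vol, lab


def angulate(vol: Volume, lab: LabelMap, pitch_deg: float,
             tilt_deg: float) -> tuple[Volume, LabelMap]:
    """Rigidly rotate a phantom about its center (patient angulation).

    Pitch rotates in the sagittal (y-z) plane, tilt in the coronal (x-z)
    plane.  Intensities use 3rd-order spline, labels nearest-neighbour.
    """
    for a in (pitch_deg, tilt_deg):
        if abs(a) > MAX_ANGLE_DEG:
            raise ValueError(f"|angle| must be <= {MAX_ANGLE_DEG} deg, got {a}")
    vdata = np.asarray(vol.data, np.float32)
    ldata = lab.data
    for angle, axes in ((pitch_deg, (1, 2)), (tilt_deg, (0, 2))):
        if angle:
            vdata = ndimage.rotate(vdata, angle, axes=axes, reshape=False,
                                   order=3, mode="nearest")
            ldata = ndimage.rotate(ldata, angle, axes=axes, reshape=False,
                                   order=0, mode="nearest")
    return (Volume(vdata, vol.spacing, vol.origin),
            LabelMap(ldata, lab.spacing, lab.origin, lab.n_classes))
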