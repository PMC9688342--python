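"""Unilateral ROIs, Gaussian patch sampling and stochastic augmentation.

Training patches are drawn from two pre-defined unilateral regions of
interest (one per side of the neck, default 280 x 200 x 280 mm).  Patch
centers follow a per-axis truncated normal law whose mean/sd are the
across-case moments of the combined level I-V center of mass, so patches
concentrate on the structure while remaining entirely inside the ROI — this
keeps the Dice-loss denominator away from zero for nearly-empty patches.

Augmentation (same policy for every model): left-right flip with p = 0.5,
in-plane rotation (sagittal or transversal, angle uniform in +-5 deg) with
p = 0.4, and contrast adaptation with p = 0.4 which re-draws the CT window
center/width from N(0, 21 HU) and N(700, 21 HU) (21 HU = 3% x 700).  Raw HU
patches are kept until augmentation so the sampled window is the one that
produces the normalized network input.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, special

from .volume_io import LabelMap, Volume, WindowSetting, apply_window

__all__ = [
    "ROIBox", "GaussianPatchSampler", "AugmentationPolicy", "PatchPair",
    "default_rois", "fit_center_distribution", "sample_patch", "augment",
]

DEFAULT_ROI_EXTENT_MM = (280.0, 200.0, 280.0)
DEFAULT_PATCH_SIZE = 64


@dataclasses.dataclass(frozen=True)
class ROIBox:
    """A unilateral axis-aligned region of interest, in physical mm."""

    side: str                       # "left" | "right"
    anchor: tuple[float, float, float]   # physical corner (mm)
    extent: tuple[float, float, float] = DEFAULT_ROI_EXTENT_MM

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if any(e <= 0 for e in self.extent):
            raise ValueError("ROI extent must be positive")

    def clamped(self, vol: Volume) -> "ROIBox":
        """Clamp the box to the physical bounds of `vol` (keeps the extent
        where possible, shrinks at the border otherwise)."""
        lo, hi = [], []
        for a in range(3):
            vmax = vol.origin[a] + vol.shape[a] * vol.spacing[a]
            l = min(max(self.anchor[a], vol.origin[a]), vmax)
            h = min(l + self.extent[a], vmax)
            lo.append(l)
            hi.append(h)
        return ROIBox(self.side, tuple(lo), tuple(h - l for l, h in zip(lo, hi)))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.anchor, float)
        return lo, lo + np.asarray(self.extent, float)

    def contains_mask(self, lab: LabelMap) -> np.ndarray:
        """Boolean voxel mask of label-map voxels whose centers lie in the box."""
        lo, hi = self.bounds()
        idx = [np.arange(n) * s + o for n, s, o in
               zip(lab.shape, lab.spacing, lab.origin)]
        m = [(ix >= l) & (ix < h) for ix, l, h in zip(idx, lo, hi)]
        return m[0][:, None, None] & m[1][None, :, None] & m[2][None, None, :]


def default_rois(vol: Volume, extent=DEFAULT_ROI_EXTENT_MM) -> tuple[ROIBox, ROIBox]:
    """One ROI per lateral half of the volume, centered and clamped."""
    out = []
    cx = vol.origin[0] + vol.shape[0] * vol.spacing[0] / 2.0
    for side in ("right", "left"):  # right = lower x half
        half_lo = vol.origin[0] if side == "right" else cx
        anchor = [half_lo + (vol.shape[0] * vol.spacing[0] / 2.0 - extent[0]) / 2.0]
        for a in (1, 2):
            c = vol.origin[a] + vol.shape[a] * vol.spacing[a] / 2.0
            anchor.append(c - extent[a] / 2.0)
        out.append(ROIBox(side, tuple(anchor), tuple(extent)).clamped(vol))
    return tuple(out)


@dataclasses.dataclass
class GaussianPatchSampler:
    """Truncated-normal patch-center sampler confined to one ROI."""

    mean: np.ndarray                 # per-axis patch-center mean (mm)
    sd: np.ndarray                   # per-axis standard deviation (mm)
    roi: ROIBox
    patch_size: int = DEFAULT_PATCH_SIZE    # voxels per axis
    spacing: tuple[float, float, float] = (1.25, 1.25, 1.25)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.sd = np.asarray(self.sd, float)
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")

    def center_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Admissible patch-center interval so the patch stays inside the ROI."""
        half = self.patch_size / 2.0 * np.asarray(self.spacing)
        lo, hi = self.roi.bounds()
        return lo + half, hi - half


@dataclasses.dataclass(frozen=True)
class AugmentationPolicy:
    p_flip: float = 0.5
    p_rotate: float = 0.4
    p_contrast: float = 0.4
    angle_range_deg: tuple[float, float] = (-5.0, 5.0)
    window_mu_center: float = 0.0
    window_sd_center: float = 0.03 * 700.0
    window_mu_width: float = 700.0
    window_sd_width: float = 0.03 * 700.0

    def __post_init__(self):
        for p in (self.p_flip, self.p_rotate, self.p_contrast):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.angle_range_deg[0] != -self.angle_range_deg[1]:
            raise ValueError("angle range must be symmetric")

    def draw(self, rng: np.random.Generator) -> dict:
        """Draw one augmentation event set.

        All variates are consumed in a fixed order regardless of which events
        fire, so event outcomes are independent and reproducible.
        """
        u = rng.random(3)
        plane = "sagittal" if rng.random() < 0.5 else "transversal"
        angle = rng.uniform(*self.angle_range_deg)
        center = rng.normal(self.window_mu_center, self.window_sd_center)
        width = rng.normal(self.window_mu_width, self.window_sd_width)
        return {
            "flip": bool(u[0] < self.p_flip),
            "rotate": bool(u[1] < self.p_rotate),
            "contrast": bool(u[2] < self.p_contrast),
            "plane": plane,
            "angle_deg": float(angle),
            "window": WindowSetting(float(center), float(max(width, 1.0))),
        }


@dataclasses.dataclass
class PatchPair:
    """An image patch (raw HU or normalized) with its aligned label patch."""

    image: np.ndarray
    labels: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise ValueError("image/label patch shapes differ")


def _case_centroid_mm(lab: LabelMap, roi_mask: np.ndarray) -> np.ndarray:
    m = lab.foreground() & roi_mask
    if not np.any(m):
        raise ValueError("combined I-V structure empty inside the ROI")
    com = ndimage.center_of_mass(m)
    return np.asarray(com) * np.asarray(lab.spacing) + np.asarray(lab.origin)


def fit_center_distribution(labelmaps, roi: ROIBox,
                            patch_size: int = DEFAULT_PATCH_SIZE) -> GaussianPatchSampler:
    """Fit the per-axis patch-center law from combined-structure centroids.

    The mean and (population) standard deviation of the x, y, z coordinates
    are computed from the center of mass of the combined binary level I-V
    structure of each case, restricted to the ROI.
    """
    labelmaps = list(labelmaps)
    if not labelmaps:
        raise ValueError("no label maps given")
    roi_mask = None
    cents = []
    for lab in labelmaps:
        if roi_mask is None or roi_mask.shape != lab.shape:
            roi_mask = roi.contains_mask(lab)
        cents.append(_case_centroid_mm(lab, roi_mask))
    cents = np.asarray(cents)
    return GaussianPatchSampler(
        mean=cents.mean(axis=0),
        sd=cents.std(axis=0, ddof=0),
        roi=roi,
        patch_size=patch_size,
        spacing=labelmaps[0].spacing,
    )


def _truncnorm_ppf(u, mu, sd, lo, hi):
    """Inverse CDF of N(mu, sd) truncated to [lo, hi] (sd = 0 degenerates)."""
    if hi < lo:
        raise ValueError("empty truncation interval: ROI smaller than the patch")
    if sd == 0.0 or hi == lo:
        return min(max(mu, lo), hi)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    fa, fb = special.ndtr(a), special.ndtr(b)
    return mu + sd * special.ndtri(fa + u * (fb - fa))


def sample_patch(sampler: GaussianPatchSampler, vol: Volume, lab: LabelMap,
                 rng: np.random.Generator | int) -> PatchPair:
    """Draw one raw-HU patch pair with a truncated-Gaussian center."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    lo, hi = sampler.center_bounds()
    if np.any(hi < lo):
        raise ValueError("ROI is smaller than the patch on some axis")
    u = rng.random(3)
    center_mm = np.array([
        _truncnorm_ppf(u[a], sampler.mean[a], sampler.sd[a], lo[a], hi[a])
        for a in range(3)])
    sp = np.asarray(vol.spacing)
    org = np.asarray(vol.origin)
    p = sampler.patch_size
    start = np.round((center_mm - org) / sp - p / 2.0).astype(int)
    start = np.clip(start, 0, np.asarray(vol.shape) - p)
    sl = tuple(slice(s, s + p) for s in start)
    return PatchPair(np.ascontiguousarray(vol.data[sl], np.float32),
                     lab.data[sl].copy(), normalized=False)


def augment(pair: PatchPair, policy: AugmentationPolicy,
            rng: np.random.Generator | int,
            default_window: WindowSetting = WindowSetting()) -> PatchPair:
    """Apply the stochastic augmentation policy and window to [0, 1].

    Input must be a raw-HU pair; the returned pair is normalized through
    either the default window or, when the contrast event fires, the sampled
    one.  Images use 3rd-order spline interpolation for rotations, labels
    nearest-neighbour; flips are left-right (x axis) only.
    """
    if pair.normalized:
        raise ValueError("augment expects a raw-HU patch pair")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    ev = policy.draw(rng)
    img, labels = pair.image, pair.labels
    if ev["flip"]:
        img = img[::-1, :, :]
        labels = labels[::-1, :, :]
    if ev["rotate"] and ev["angle_deg"] != 0.0:
        axes = (1, 2) if ev["plane"] == "sagittal" else (0, 1)
        img = ndimage.rotate(img, ev["angle_deg"], axes=axes, reshape=False,
                             order=3, mode="nearest")
        labels = ndimage.rotate(labels, ev["angle_deg"], axes=axes,
                                reshape=False, order=0, mode="nearest")
    window = ev["window"] if ev["contrast"] else default_window
    spacing = (1.25, 1.25, 1.25)
    norm = apply_window(Volume(np.ascontiguousarray(img, np.float32), spacing), window).data
    return PatchPair(norm, np.ascontiguousarray(labels), normalized=True)
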