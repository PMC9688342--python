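"""Full-volume prediction: sliding-window UNet, masked MV classification,
ensemble fusion and the three end-to-end pipeline configurations.

A trained patch-UNet is applied by sliding its field of view over the image
with a stride of half the window and scoring only the central half-window
voxels, so every voxel of the volume is classified exactly once.  The volume
is edge-padded by a quarter window (plus whatever rounds each axis up to a
multiple of the stride) so the central tiles exactly cover it.

The three configurations:

* ``C1`` — a 6-class patch-UNet ensemble segments background and levels I-V
  directly.
* ``C2`` — a 6-class multi-view ensemble classifies voxels inside a mask
  built by a uniform 15 mm expansion of the manual reference.
* ``C3`` — a 2-class UNet ensemble segments the combined I-V foreground,
  which is post-processed (hole fill, largest component) and then relabelled
  voxel-by-voxel into levels I-V by a 5-class multi-view ensemble.  The MV
  stage can only relabel: the foreground voxel set of the output equals the
  UNet stage's post-processed foreground exactly.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .networks import MVNet, UNet3D, extract_views_batch
from .training import Ensemble
from .volume_io import LabelMap, Volume, WindowSetting, apply_window

__all__ = [
    "ProbabilityMap", "EvaluationMask", "sliding_window_predict",
    "expand_mask", "classify_masked_voxels", "ensemble_fuse",
    "run_configuration",
]

N_LABELS = 6


@dataclasses.dataclass
class ProbabilityMap:
    """Per-voxel class probabilities aligned to a volume: data (X, Y, Z, M)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("probability map must be 4D (x, y, z, class)")

    @property
    def n_classes(self) -> int:
        return self.data.shape[-1]

    def argmax_labels(self) -> LabelMap:
        return LabelMap(self.data.argmax(-1).astype(np.uint8), self.spacing,
                        self.origin, n_classes=max(self.n_classes, N_LABELS))


@dataclasses.dataclass
class EvaluationMask:
    """Binary grid of voxels eligible for multi-view classification."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)


def sliding_window_predict(model: UNet3D, vol: Volume) -> ProbabilityMap:
    """Tile a volume with the UNet window, scoring central crops once each.

    Window = ``patch_size`` (64 by default), stride = window/2, scored
    center = the central (window/2)^3 voxels.  Borders are handled by
    edge-replication padding of window/4 plus round-up to a stride multiple.
    """
    w = model.spec.patch_size
    stride, quarter = w // 2, w // 4
    shape = np.asarray(vol.shape)
    if np.any(shape < 1):
        raise ValueError("empty volume")
    tiles = np.ceil(shape / stride).astype(int)
    padded = tiles * stride + stride
    pad_before = np.full(3, quarter)
    pad_after = padded - shape - pad_before
    data = np.pad(np.asarray(vol.data, np.float32),
                  list(zip(pad_before, pad_after)), mode="edge")
    m = model.spec.n_classes
    out = np.empty(tuple(shape) + (m,), np.float32)
    for i in range(tiles[0]):
        for j in range(tiles[1]):
            for k in range(tiles[2]):
                s = np.array([i, j, k]) * stride
                patch = data[s[0]:s[0] + w, s[1]:s[1] + w, s[2]:s[2] + w]
                probs = model.predict_proba(patch[None])[0]
                center = probs[quarter:quarter + stride,
                               quarter:quarter + stride,
                               quarter:quarter + stride]
                o_lo = s  # center tile start in original coordinates
                o_hi = np.minimum(o_lo + stride, shape)
                n = o_hi - o_lo
                out[o_lo[0]:o_hi[0], o_lo[1]:o_hi[1], o_lo[2]:o_hi[2]] = \
                    center[:n[0], :n[1], :n[2]]
    return ProbabilityMap(out, vol.spacing, vol.origin)


def expand_mask(lab: LabelMap | np.ndarray, margin_mm: float = 15.0,
                spacing=None, origin=(0.0, 0.0, 0.0)) -> EvaluationMask:
    """Uniform Euclidean expansion (in mm) of a binary structure.

    A voxel is included iff its center lies within ``margin_mm`` of the
    input structure (exact Euclidean distance transform with anisotropic
    sampling support).
    """
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if isinstance(lab, LabelMap):
        fg = lab.foreground()
        spacing, origin = lab.spacing, lab.origin
    else:
        fg = np.asarray(lab).astype(bool)
        if spacing is None:
            raise ValueError("spacing required for raw-array input")
    if margin_mm == 0 or not fg.any():
        return EvaluationMask(fg.copy(), spacing, origin)
    dist = ndimage.distance_transform_edt(~fg, sampling=spacing)
    return EvaluationMask(dist <= margin_mm, spacing, origin)


def classify_masked_voxels(model: MVNet, vol: Volume, mask: EvaluationMask, *,
                           class_labels=None, batch_size: int = 256,
                           windowed: bool = True) -> ProbabilityMap:
    """Classify every voxel inside the mask with the multi-view network.

    ``class_labels`` maps the model's output channels to label values
    (default ``0..M-1``; the 5-class sequential stage uses ``1..5``).
    Returns a 6-channel probability map over the full geometry; voxels
    outside the mask carry background probability 1.  Runtime is
    proportional to the mask size.
    """
    m = model.spec.n_classes
    labels = list(range(m)) if class_labels is None else list(class_labels)
    if len(labels) != m:
        raise ValueError("one label per model class required")
    out = np.zeros(tuple(vol.shape) + (N_LABELS,), np.float32)
    out[..., 0] = 1.0
    centers = np.argwhere(mask.data)
    if centers.size == 0:
        warnings.warn("empty evaluation mask: returning all-background map")
        return ProbabilityMap(out, vol.spacing, vol.origin)
    data = np.asarray(vol.data, np.float32)
    probs = np.empty((len(centers), m), np.float32)
    for s in range(0, len(centers), batch_size):
        chunk = centers[s:s + batch_size]
        views = extract_views_batch(data, chunk, model.spec)
        probs[s:s + batch_size] = model.predict_proba(views)
    out[centers[:, 0], centers[:, 1], centers[:, 2], :] = 0.0
    for ch, lbl in enumerate(labels):
        out[centers[:, 0], centers[:, 1], centers[:, 2], lbl] = probs[:, ch]
    return ProbabilityMap(out, vol.spacing, vol.origin)


def ensemble_fuse(maps: list[ProbabilityMap]) -> LabelMap:
    """Fuse members by the highest summed in-class probability.

    Ties break toward the lowest class index (background wins against any
    foreground class), deterministically.
    """
    if not maps:
        raise ValueError("no probability maps to fuse")
    shape = maps[0].data.shape
    if any(m.data.shape != shape for m in maps):
        raise ValueError("probability maps disagree in geometry or class count")
    total = np.zeros(shape, np.float64)
    for m in maps:
        total += m.data
    labels = total.argmax(-1).astype(np.uint8)
    return LabelMap(labels, maps[0].spacing, maps[0].origin,
                    n_classes=max(shape[-1], N_LABELS))


def _as_members(ens) -> list:
    if isinstance(ens, Ensemble):
        return list(ens.members)
    if isinstance(ens, (list, tuple)):
        return list(ens)
    return [ens]


def run_configuration(cfg: str, vol: Volume, *, unet_ensemble=None,
                      mv_ensemble=None, reference: LabelMap | None = None,
                      mask_margin_mm: float = 15.0,
                      window: WindowSetting = WindowSetting(),
                      stages: dict | None = None) -> LabelMap:
    """Run one of the three end-to-end pipeline configurations on a raw volume.

    C1 needs a 6-class UNet ensemble; C2 a 6-class MV ensemble plus the
    reference label map for its 15 mm evaluation mask; C3 a 2-class UNet
    ensemble plus a 5-class MV ensemble.  Pass a dict as ``stages`` to
    receive intermediate artifacts (member probability maps; for C3 also
    the post-processed UNet foreground stage).
    """
    from .postprocess import postprocess_combined

    cfg = cfg.upper()
    win = apply_window(vol, window)
    if cfg == "C1":
        members = _as_members(unet_ensemble)
        if members[0].spec.n_classes != 6:
            raise ValueError("C1 requires a 6-class UNet ensemble")
        maps = [sliding_window_predict(mdl, win) for mdl in members]
        return postprocess_combined(ensemble_fuse(maps), keep_components=2)
    if cfg == "C2":
        members = _as_members(mv_ensemble)
        if members[0].spec.n_classes != 6:
            raise ValueError("C2 requires a 6-class MV ensemble")
        if reference is None:
            raise ValueError("C2 requires the reference label map for its mask")
        mask = expand_mask(reference, mask_margin_mm)
        maps = [classify_masked_voxels(mdl, vol, mask) for mdl in members]
        fused = postprocess_combined(ensemble_fuse(maps), keep_components=2)
        # hole filling may not escape the evaluation mask
        fused.data[~mask.data] = 0
        return fused
    if cfg == "C3":
        u_members = _as_members(unet_ensemble)
        m_members = _as_members(mv_ensemble)
        if u_members[0].spec.n_classes != 2:
            raise ValueError("C3 requires a 2-class UNet ensemble")
        if m_members[0].spec.n_classes != 5:
            raise ValueError("C3 requires a 5-class MV ensemble")
        maps = [sliding_window_predict(mdl, win) for mdl in u_members]
        fg_lab = postprocess_combined(ensemble_fuse(maps), keep_components=2)
        if stages is not None:
            stages["unet_maps"] = maps
            stages["unet_foreground"] = fg_lab
        mask = EvaluationMask(fg_lab.data > 0, vol.spacing, vol.origin)
        if not mask.data.any():
            warnings.warn("UNet stage produced empty foreground")
            return LabelMap(np.zeros(vol.shape, np.uint8), vol.spacing,
                            vol.origin, N_LABELS)
        mv_maps = [classify_masked_voxels(mdl, vol, mask,
                                          class_labels=[1, 2, 3, 4, 5])
                   for mdl in m_members]
        total = np.zeros(tuple(vol.shape) + (N_LABELS,), np.float64)
        for m in mv_maps:
            total += m.data
        # inside the mask only foreground channels carry probability, so the
        # argmax relabels without ever adding or removing foreground
        labels = np.zeros(vol.shape, np.uint8)
        fg = mask.data
        labels[fg] = 1 + total[fg][:, 1:].argmax(-1).astype(np.uint8)
        return LabelMap(labels, vol.spacing, vol.origin, N_LABELS)
    raise ValueError(f"unknown configuration {cfg!r} (expected C1, C2 or C3)")
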