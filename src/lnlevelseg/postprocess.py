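"""Post-processing of multi-class segmentations and PTV derivation.

The combined level I-V structure is cleaned by volumetric (3D) hole filling
followed by keeping only the largest 26-connected component.  Individual
level labels are retained wherever the cleaned combined mask survives;
voxels added by hole filling take the majority label of their
26-neighbourhood (propagated iteratively for deep holes).

Planning target volumes are derived by expanding the union of selected
levels by a Euclidean margin in mm (default 4 mm), e.g. PI-PV from levels
I-V and PII-PIV from levels II-IV.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .inference import expand_mask
from .volume_io import LabelMap

__all__ = ["postprocess_combined", "expand_ptv"]

_S26 = np.ones((3, 3, 3), int)


def postprocess_combined(lab: LabelMap, keep_components: int = 1) -> LabelMap:
    """Hole-fill the combined I-V structure and keep its largest component(s).

    ``keep_components`` is the number of largest 26-connected components
    retained.  Whole-volume bilateral segmentations use 2 (the combined
    structure occurs once per side of the neck, mirroring the unilateral
    per-ROI processing of the pipeline); the default operates on a single
    structure.
    """
    fg = lab.foreground()
    if not fg.any():
        warnings.warn("empty foreground: post-processing is a no-op")
        return LabelMap(lab.data.copy(), lab.spacing, lab.origin, lab.n_classes)
    filled = ndimage.binary_fill_holes(fg)
    comp, n = ndimage.label(filled, structure=_S26)
    if n > keep_components:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, range(1, n + 1))
        top = np.argsort(sizes)[::-1][:keep_components] + 1
        keep = np.isin(comp, top)
    else:
        keep = filled
    out = np.where(keep, lab.data, 0).astype(lab.data.dtype)
    # assign filled-hole voxels the majority label of their 26-neighbourhood
    holes = keep & (out == 0)
    while holes.any():
        counts = np.stack([
            ndimage.correlate((out == c).astype(np.float32), _S26.astype(np.float32),
                              mode="constant")
            for c in range(1, lab.n_classes)], axis=-1)
        assignable = holes & (counts.sum(-1) > 0)
        if not assignable.any():  # pragma: no cover - keep cannot be labelless
            break
        out[assignable] = counts[assignable].argmax(-1) + 1
        holes = keep & (out == 0)
    return LabelMap(out, lab.spacing, lab.origin, lab.n_classes)


def expand_ptv(lab: LabelMap, levels, margin_mm: float = 4.0) -> np.ndarray:
    """PTV mask: union of the selected levels dilated by a Euclidean margin."""
    levels = sorted(set(int(l) for l in levels))
    if not levels:
        raise ValueError("levels must be non-empty")
    bad = [l for l in levels if not 1 <= l < lab.n_classes]
    if bad:
        raise ValueError(f"unknown level label {bad[0]}")
    union = np.isin(lab.data, levels)
    return expand_mask(union, margin_mm, spacing=lab.spacing, origin=lab.origin).data
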