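"""Spatial and volumetric agreement metrics for segmentation evaluation.

* DSC = 2|A∩B| / (|A| + |B|); both-empty pairs score 1, one-empty 0.
* Hausdorff distance (HD, mm): the exact (100th percentile) symmetric
  maximum of surface-to-surface Euclidean distances; HD95 available as an
  option.  Surfaces are the 6-connectivity-exposed border voxels.
* Mean surface distance (MSD, mm): mean of the two directed mean surface
  distances.
* Volume outside the reference: |pred \\ ref| x voxel volume, in mL.
* ICC(3,1): two-way mixed effects, single measurement, consistency form,
  from the two-way ANOVA decomposition.

The per-case report covers the individual levels I-V, the combined I-V
structure and the two planning target volumes PI-PV and PII-PIV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .postprocess import expand_ptv
from .volume_io import LabelMap

__all__ = [
    "dsc", "hausdorff", "msd", "surface_voxels", "volume_outside",
    "icc_consistency", "evaluate_case",
]

_S6 = ndimage.generate_binary_structure(3, 1)


def _binary(a):
    return np.asarray(a).astype(bool)


def dsc(a, b) -> float:
    """Dice similarity coefficient of two binary masks."""
    a, b = _binary(a), _binary(b)
    if a.shape != b.shape:
        raise ValueError("mask geometries differ")
    sa, sb = int(a.sum()), int(b.sum())
    if sa == 0 and sb == 0:
        return 1.0
    if sa == 0 or sb == 0:
        return 0.0
    return 2.0 * int(np.logical_and(a, b).sum()) / (sa + sb)


def surface_voxels(mask) -> np.ndarray:
    """Border voxels of a binary mask (6-connectivity exposure)."""
    mask = _binary(mask)
    interior = ndimage.binary_erosion(mask, structure=_S6, border_value=0)
    return mask & ~interior


def _directed_distances(surf_from, surf_to, spacing):
    dist_to = ndimage.distance_transform_edt(~surf_to, sampling=spacing)
    return dist_to[surf_from]


def _surface_dists(a, b, spacing):
    a, b = _binary(a), _binary(b)
    if a.shape != b.shape:
        raise ValueError("mask geometries differ")
    if not a.any() or not b.any():
        return None
    sa, sb = surface_voxels(a), surface_voxels(b)
    return (_directed_distances(sa, sb, spacing),
            _directed_distances(sb, sa, spacing))

def hausdorff(a, b, spacing=(1.0, 1.0, 1.0), percentile: float = 100.0) -> float:
    """Symmetric (percentile-)Hausdorff surface distance in mm.

    Undefined for an empty mask (returns NaN, reported as missing).
    """
    d = _surface_dists(a, b, spacing)
    if d is None:
        return float("nan")
    if percentile >= 100.0:
        return float(max(d[0].max(), d[1].max()))
    return float(max(np.percentile(d[0], percentile),
                     np.percentile(d[1], percentile)))


def msd(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric mean surface distance in mm (mean of the directed means)."""
    d = _surface_dists(a, b, spacing)
    if d is None:
        return float("nan")
    return float((d[0].mean() + d[1].mean()) / 2.0)


def volume_outside(pred, ref, spacing) -> float:
    """Predicted volume outside the reference contour, in mL."""
    pred, ref = _binary(pred), _binary(ref)
    if pred.shape != ref.shape:
        raise ValueError("mask geometries differ")
    voxel_ml = float(np.prod(spacing)) / 1000.0
    return float(np.logical_and(pred, ~ref).sum()) * voxel_ml


def icc_consistency(v1, v2) -> float:
    """ICC(3,1): two-way mixed effects, single measurement, consistency.

    ICC = (MS_rows - MS_error) / (MS_rows + (k - 1) MS_error) with k = 2
    raters, from the two-way ANOVA sums of squares.  Undefined (NaN) for
    constant inputs.
    """
    x = np.column_stack([np.asarray(v1, float), np.asarray(v2, float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 paired cases")
    if np.allclose(x, x.flat[0]):
        return float("nan")
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom == 0:
        return float("nan")
    return float((ms_rows - ms_err) / denom)


_STRUCTURES = ("I", "II", "III", "IV", "V", "I-V", "PI-PV", "PII-PIV")


def _structure_masks(lab: LabelMap):
    yield from (((roman, lab.data == i + 1) for i, roman in
                 enumerate(_STRUCTURES[:5])))
    yield "I-V", lab.foreground()
    yield "PI-PV", expand_ptv(lab, [1, 2, 3, 4, 5])
    yield "PII-PIV", expand_ptv(lab, [2, 3, 4])


def evaluate_case(pred: LabelMap, ref: LabelMap,
                  hd_percentile: float = 100.0) -> pd.DataFrame:
    """Per-structure agreement report for one case.

    One row per structure (levels I-V, combined I-V, PI-PV, PII-PIV) with
    DSC, HD, MSD, predicted/reference volumes (mL) and predicted volume
    outside the reference (mL).
    """
    if pred.shape != ref.shape:
        raise ValueError("prediction/reference geometries differ")
    sp = ref.spacing
    voxel_ml = float(np.prod(sp)) / 1000.0
    rows = []
    for (name, pm), (_, rm) in zip(_structure_masks(pred), _structure_masks(ref)):
        rows.append({
            "structure": name,
            "dsc": dsc(pm, rm),
            "hd_mm": hausdorff(pm, rm, sp, hd_percentile),
            "msd_mm": msd(pm, rm, sp),
            "pred_volume_ml": float(pm.sum()) * voxel_ml,
            "ref_volume_ml": float(rm.sum()) * voxel_ml,
            "volume_outside_ml": volume_outside(pm, rm, sp),
        })
    return pd.DataFrame(rows).set_index("structure")
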