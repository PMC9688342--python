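"""Dice losses, class weights and categorical cross-entropy.

The multi-class segmentation loss is a class-weighted sum of per-foreground
soft Dice losses,

    DSC_loss = sum_{m=1..M} W_m * DL_m,      DL_m = 1 - 2|A_m ∩ B_m| / (|A_m| + |B_m|)

with A_m the predicted soft mask of class m and B_m the binary reference.
For binary segmentation the sum reduces to the single-class Dice loss.  The
denominator is not constrained away from zero for (nearly) empty patches; we
stabilize it with a small epsilon added to the denominator only, which keeps
DL = 1 for disjoint non-empty masks (configurable via ``eps``).

Class weights follow inverse-frequency "balanced" weighting over foreground
voxels: W_m = N_fg / (M_fg * N_m).

The voxel-classification loss is the categorical cross-entropy

    H(p, q) = - sum_m sum_a p(a, m) log q(a, m)

summed over observations, with q clipped to [1e-7, 1 - 1e-7] before the log.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "compute_class_weights", "dice_loss", "dice_loss_grad",
    "multiclass_dice_loss", "multiclass_dice_loss_grad",
    "categorical_cross_entropy", "categorical_cross_entropy_grad",
]

DICE_EPS = 1e-5
CCE_CLIP = 1e-7


def compute_class_weights(labelmaps, n_classes: int = 6) -> np.ndarray:
    """Inverse-frequency weights for foreground classes 1..n_classes-1.

    Returns an array of length ``n_classes - 1`` (class m at index m-1).
    Raises if any foreground class is absent from the whole collection.
    """
    counts = np.zeros(n_classes, np.int64)
    for lab in labelmaps:
        data = lab.data if hasattr(lab, "data") else np.asarray(lab)
        counts += np.bincount(data.ravel().astype(np.int64), minlength=n_classes)[:n_classes]
    fg = counts[1:]
    missing = np.nonzero(fg == 0)[0]
    if missing.size:
        raise ValueError(f"foreground class {missing[0] + 1} absent from the data")
    m_fg = n_classes - 1
    return (fg.sum() / (m_fg * fg)).astype(np.float64)


def _dice_terms(pred, ref, eps):
    pred = np.asarray(pred, np.float64)
    ref = np.asarray(ref, np.float64)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {ref.shape}")
    inter = float((pred * ref).sum())
    denom = float(pred.sum() + ref.sum()) + eps
    return pred, ref, inter, denom


def dice_loss(pred, ref, eps: float = DICE_EPS) -> float:
    """Soft binary Dice loss, 1 - 2|A∩B| / (|A| + |B| + eps)."""
    _, _, inter, denom = _dice_terms(pred, ref, eps)
    return 1.0 - 2.0 * inter / denom


def dice_loss_grad(pred, ref, eps: float = DICE_EPS) -> tuple[float, np.ndarray]:
    """Dice loss and its gradient with respect to the soft prediction."""
    pred, ref, inter, denom = _dice_terms(pred, ref, eps)
    loss = 1.0 - 2.0 * inter / denom
    grad = -2.0 * (ref * denom - inter) / denom ** 2
    return loss, grad


def multiclass_dice_loss(probs, ref, weights, eps: float = DICE_EPS) -> float:
    """Weighted sum of per-foreground-class soft Dice losses.

    probs: (..., M) class probabilities; ref: integer labels in [0, M-1];
    weights: length M-1 array for classes 1..M-1.
    """
    return multiclass_dice_loss_grad(probs, ref, weights, eps)[0]


def multiclass_dice_loss_grad(probs, ref, weights,
                              eps: float = DICE_EPS) -> tuple[float, np.ndarray]:
    probs = np.asarray(probs)
    ref = np.asarray(ref)
    m = probs.shape[-1]
    weights = np.asarray(weights, np.float64)
    if weights.shape != (m - 1,):
        raise ValueError(f"expected {m - 1} foreground weights, got {weights.shape}")
    if probs.shape[:-1] != ref.shape:
        raise ValueError("probability/label shapes differ")
    total = 0.0
    # the per-class gradient is affine in the reference mask,
    # grad_c = w * (-2/S) * ref + w * 2 I / S^2, so one pass per class suffices
    grad = np.empty(probs.shape, np.float32)
    grad[..., 0] = 0.0
    for cls in range(1, m):
        refm = ref == cls
        pc = probs[..., cls]
        s_ref = float(np.count_nonzero(refm))
        s_pred = float(pc.sum(dtype=np.float64))
        inter = float(np.einsum("i,i->", pc.ravel(),
                                refm.reshape(-1), dtype=np.float64))
        denom = s_pred + s_ref + eps
        w = float(weights[cls - 1])
        total += w * (1.0 - 2.0 * inter / denom)
        gc = np.multiply(refm, np.float32(-2.0 * w / denom))
        gc += np.float32(2.0 * w * inter / denom ** 2)
        grad[..., cls] = gc
    return total, grad


def _check_rows(q):
    q = np.asarray(q, np.float64)
    rows = q.sum(axis=-1)
    if not np.allclose(rows, 1.0, atol=1e-4):
        raise ValueError("probability rows must sum to 1")
    return q


def categorical_cross_entropy(p, q, clip: float = CCE_CLIP) -> float:
    """H(p, q) = -sum_m sum_a p(a,m) log q(a,m), summed over observations."""
    p = np.asarray(p, np.float64)
    q = _check_rows(q)
    if p.shape != q.shape:
        raise ValueError("p and q must have identical shapes")
    qc = np.clip(q, clip, 1.0 - clip)
    return float(-(p * np.log(qc)).sum())


def categorical_cross_entropy_grad(p, q, clip: float = CCE_CLIP) -> tuple[float, np.ndarray]:
    """CCE and gradient w.r.t. q (before the softmax backward)."""
    p = np.asarray(p, np.float64)
    qc = np.clip(np.asarray(q, np.float64), clip, 1.0 - clip)
    loss = float(-(p * np.log(qc)).sum())
    grad = -p / qc
    return loss, grad
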