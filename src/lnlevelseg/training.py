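"""Training orchestration: optimizer schedule, folds, epochs, ensembles.

Optimization uses Adam (lr0 = 0.001, beta1 = 0.9, beta2 = 0.999,
eps = 1e-7) with an exponential decay of 5% per epoch floored at 1e-4.
Cases are split by 5-fold cross-validation (48/12 for 60 cases).  UNet
training draws a fixed budget of augmented patch pairs per epoch (an "epoch"
in a patch-based setting is a convention, not a pass over the data); the
multi-view network trains on a fresh random subset of at most 20% of the
voxel pool per epoch, with minority classes oversampled to balance.  Only
the best checkpoint by validation DSC is kept.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import losses as L
from .networks import MVNet, MVSpec, UNet3D, UNetSpec, build_mv, build_unet, extract_views_batch
from .nn import Adam
from .sampling import (AugmentationPolicy, default_rois, fit_center_distribution,
                       sample_patch)
from .volume_io import LabelMap, Volume, WindowSetting, apply_window

__all__ = [
    "OptimizerConfig", "FoldPlan", "Ensemble", "lr_schedule", "make_folds",
    "sample_epoch_subset", "train_model", "train_unet", "train_mv",
    "train_ensemble",
]


@dataclasses.dataclass(frozen=True)
class OptimizerConfig:
    kind: str = "adam"
    lr0: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    decay_rate: float = 0.95
    lr_floor: float = 1e-4

    def __post_init__(self):
        if not (0.0 < self.lr_floor <= self.lr0):
            raise ValueError("require 0 < lr_floor <= lr0")
        if not (0.0 < self.decay_rate < 1.0):
            raise ValueError("decay_rate must be in (0, 1)")


def lr_schedule(epoch: int, cfg: OptimizerConfig = OptimizerConfig()) -> float:
    """Exponentially decayed learning rate, clamped at the floor."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return max(cfg.lr0 * cfg.decay_rate ** epoch, cfg.lr_floor)


@dataclasses.dataclass
class FoldPlan:
    k: int
    assignments: dict  # case id -> fold index

    def test_cases(self, fold: int) -> list:
        return [c for c, f in self.assignments.items() if f == fold]

    def train_cases(self, fold: int) -> list:
        return [c for c, f in self.assignments.items() if f != fold]


def make_folds(case_ids, k: int = 5, seed: int = 0) -> FoldPlan:
    """Deterministic near-equal partition into k test folds."""
    case_ids = list(case_ids)
    if k > len(case_ids):
        raise ValueError("more folds than cases")
    order = np.random.default_rng(seed).permutation(len(case_ids))
    assignments = {case_ids[j]: int(i % k) for i, j in enumerate(order)}
    return FoldPlan(k=k, assignments=assignments)


def sample_epoch_subset(voxel_pool: dict, max_fraction: float = 0.20,
                        rng: np.random.Generator | int = 0,
                        budget_cap: int | None = None) -> dict:
    """Balanced per-epoch subset of a per-class sample pool.

    ``voxel_pool`` maps class -> sequence of items.  The subset holds at most
    ``max_fraction`` of the pooled items (optionally further capped), split
    equally (+-1) across classes; minority classes are oversampled with
    replacement.  Returns class -> integer indices into that class's pool.
    """
    classes = sorted(voxel_pool)
    sizes = {c: len(voxel_pool[c]) for c in classes}
    if any(s == 0 for s in sizes.values()):
        empty = [c for c, s in sizes.items() if s == 0]
        raise ValueError(f"empty sample pool for class {empty[0]}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    total = sum(sizes.values())
    budget = int(max_fraction * total)
    if budget_cap is not None:
        budget = min(budget, budget_cap)
    n = len(classes)
    base, rem = divmod(budget, n)
    out = {}
    for i, c in enumerate(classes):
        want = base + (1 if i < rem else 0)
        if want <= sizes[c]:
            out[c] = rng.choice(sizes[c], size=want, replace=False)
        else:
            out[c] = rng.choice(sizes[c], size=want, replace=True)
    return out


@dataclasses.dataclass
class Ensemble:
    """Ordered, identically-specified models fused by summed class probability."""

    members: list

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        s0 = self.members[0].spec
        if any(m.spec != s0 for m in self.members):
            raise ValueError("ensemble members must share one spec")

    @property
    def spec(self):
        return self.members[0].spec

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


# ----------------------------------------------------------------------
# helpers

def _snapshot(model):
    return [p.value.copy() for p in model.params()]


def _restore(model, snap):
    for p, v in zip(model.params(), snap):
        p.value[...] = v


def _hard_dice(pred_labels, ref_labels, classes) -> float:
    """Mean hard DSC over the given classes (those present in the reference)."""
    vals = []
    for c in classes:
        a, b = pred_labels == c, ref_labels == c
        if not b.any():
            continue
        vals.append(2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum()))
    return float(np.mean(vals)) if vals else 0.0


def _check_finite(loss, epoch, step):
    if not np.isfinite(loss):
        raise RuntimeError(
            f"non-finite training loss {loss!r} at epoch {epoch}, step {step}")


# ----------------------------------------------------------------------
# UNet training

def train_unet(spec: UNetSpec, cases, val_cases, cfg: OptimizerConfig = OptimizerConfig(), *,
               epochs: int = 100, pairs_per_epoch: int = 4096, batch_size: int = 2,
               class_weights=None, policy: AugmentationPolicy = AugmentationPolicy(),
               window: WindowSetting = WindowSetting(), roi_extent=None,
               val_patches: int = 16, seed: int = 0) -> UNet3D:
    """Train a patch-based residual UNet with (weighted multi-class) Dice loss.

    ``cases``/``val_cases`` are sequences of ``(Volume, LabelMap)`` pairs at
    the model's working spacing.  With ``spec.n_classes == 2`` the label maps
    are binarized to the combined foreground structure.
    """
    rng = np.random.default_rng(seed)
    model = build_unet(spec, seed=seed)
    binary = spec.n_classes == 2
    labs = [lab for _, lab in cases]
    if class_weights is None:
        if binary:
            class_weights = np.ones(1)
        else:
            class_weights = L.compute_class_weights(labs, spec.n_classes)
    class_weights = np.asarray(class_weights, float)

    # one truncated-Gaussian sampler per unilateral ROI
    kw = {} if roi_extent is None else {"extent": roi_extent}
    rois = default_rois(cases[0][0], **kw)
    samplers = [fit_center_distribution(labs, roi, patch_size=spec.patch_size)
                for roi in rois]

    opt = Adam([p for p in model.params() if p.trainable],
               beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.epsilon)
    best, best_snap = -np.inf, None
    model.train_log = []

    def draw_pair(case_rng, case_list, augmented=True):
        vol, lab = case_list[case_rng.integers(len(case_list))]
        sampler = samplers[case_rng.integers(len(samplers))]
        pair = sample_patch(sampler, vol, lab, case_rng)
        if augmented:
            from .sampling import augment
            pair = augment(pair, policy, case_rng, default_window=window)
            img = pair.image
        else:
            img = apply_window(Volume(pair.image, vol.spacing), window).data
        y = (pair.labels > 0).astype(np.int64) if binary else pair.labels.astype(np.int64)
        return img, y

    n_steps = max(pairs_per_epoch // batch_size, 1)
    for epoch in range(epochs):
        lr = lr_schedule(epoch, cfg)
        ep_losses = []
        for step in range(n_steps):
            imgs, ys = zip(*(draw_pair(rng, cases) for _ in range(batch_size)))
            x = np.stack(imgs)
            y = np.stack(ys)
            probs = model.forward(x, train=True)
            loss, gprob = L.multiclass_dice_loss_grad(probs, y, class_weights)
            _check_finite(loss, epoch, step)
            opt.zero_grad()
            model.backward(gprob)
            opt.step(lr)
            ep_losses.append(loss)
        # validation DSC on sampled patches (no augmentation)
        vrng = np.random.default_rng(np.random.SeedSequence([seed, 7, epoch]))
        vx, vy = zip(*(draw_pair(vrng, val_cases, augmented=False)
                       for _ in range(val_patches)))
        vp = np.concatenate([model.predict_proba(np.stack(vx[i:i + batch_size]))
                             for i in range(0, len(vx), batch_size)])
        val_dsc = _hard_dice(vp.argmax(-1), np.stack(vy), range(1, spec.n_classes))
        model.train_log.append({"epoch": epoch, "lr": lr, "seed": seed,
                                "train_loss": float(np.mean(ep_losses)),
                                "val_dsc": val_dsc})
        if val_dsc > best:
            best, best_snap = val_dsc, _snapshot(model)
    _restore(model, best_snap)
    model.best_metric = best
    return model


# ----------------------------------------------------------------------
# multi-view training

def build_voxel_pool(cases, n_classes: int, mask_margin_mm: float = 15.0):
    """Per-class pools of (case index, x, y, z) query voxels.

    For the standalone 6-class network, eligible voxels are those within a
    ``mask_margin_mm`` expansion of the reference foreground (background
    voxels get class 0).  For the 5-class sequential stage, only foreground
    voxels are eligible, with class = level - 1.
    """
    from .inference import expand_mask

    pool = {c: [] for c in range(n_classes)}
    for ci, (_, lab) in enumerate(cases):
        if n_classes == 5:
            eligible = lab.foreground()
            targets = lab.data.astype(int) - 1
        else:
            eligible = expand_mask(lab, mask_margin_mm).data
            targets = lab.data.astype(int)
        idx = np.argwhere(eligible)
        cls = targets[eligible]
        for c in range(n_classes):
            sel = idx[cls == c]
            if sel.size:
                pool[c].append(np.column_stack([np.full(len(sel), ci), sel]))
    return {c: (np.concatenate(v) if v else np.empty((0, 4), int))
            for c, v in pool.items()}


def _mv_batch_views(volumes, entries, spec: MVSpec):
    entries = np.asarray(entries)
    views = np.empty((len(entries), spec.n_scales, 3,
                      spec.in_plane_samples, spec.in_plane_samples), np.float32)
    for ci in np.unique(entries[:, 0]):
        m = entries[:, 0] == ci
        views[m] = extract_views_batch(volumes[ci], entries[m, 1:], spec)
    return views


def train_mv(spec: MVSpec, cases, val_cases, cfg: OptimizerConfig = OptimizerConfig(), *,
             epochs: int = 1000, batch_size: int = 32, max_fraction: float = 0.20,
             pairs_cap: int | None = None, mask_margin_mm: float = 15.0,
             policy: AugmentationPolicy = AugmentationPolicy(),
             window: WindowSetting = WindowSetting(),
             val_voxels: int = 256, seed: int = 0) -> MVNet:
    """Train the multi-view voxel classifier with categorical cross-entropy.

    Views are extracted from raw-HU volumes and normalized through the
    (possibly contrast-augmented) window; the left-right flip augmentation
    mirrors the view patches.  In-plane rotation augmentation is not applied
    to view sets (rotating the full volume per sample is disproportionate to
    its benefit at patch level); see the methods note.
    """
    rng = np.random.default_rng(seed)
    model = build_mv(spec, seed=seed)
    pool = build_voxel_pool(cases, spec.n_classes, mask_margin_mm)
    val_pool = build_voxel_pool(val_cases, spec.n_classes, mask_margin_mm)
    raw = [vol.data for vol, _ in cases]
    raw_val = [vol.data for vol, _ in val_cases]
    eye = np.eye(spec.n_classes, dtype=np.float64)

    opt = Adam([p for p in model.params() if p.trainable],
               beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.epsilon)
    best, best_snap = -np.inf, None
    model.train_log = []

    def window_views(v, rng_):
        ev = policy.draw(rng_)
        w = ev["window"] if ev["contrast"] else window
        lo = w.center - w.width / 2.0
        v = np.clip((v - lo) / w.width, 0.0, 1.0)
        if ev["flip"]:
            # left-right mirror: x is the row axis of the axial (0) and
            # coronal (2) views; the sagittal view is left untouched
            v = v.copy()
            v[:, :, ::2] = v[:, :, ::2, ::-1, :]
        return v

    # fixed validation draw
    vrng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    val_entries, val_targets = [], []
    for c in sorted(val_pool):
        items = val_pool[c]
        take = min(max(val_voxels // spec.n_classes, 1), len(items))
        sel = vrng.choice(len(items), size=take, replace=False)
        val_entries.append(items[sel])
        val_targets.append(np.full(take, c))
    val_entries = np.concatenate(val_entries)
    val_targets = np.concatenate(val_targets)
    val_views = _mv_batch_views(raw_val, val_entries, spec)
    lo = window.center - window.width / 2.0
    val_views = np.clip((val_views - lo) / window.width, 0.0, 1.0)

    for epoch in range(epochs):
        lr = lr_schedule(epoch, cfg)
        subset = sample_epoch_subset(pool, max_fraction, rng, budget_cap=pairs_cap)
        entries = np.concatenate([np.column_stack(
            [np.full(len(ix), c), pool[c][ix]]) for c, ix in subset.items()])
        rng.shuffle(entries, axis=0)
        ep_losses = []
        for s in range(0, len(entries), batch_size):
            chunk = entries[s:s + batch_size]
            targets = eye[chunk[:, 0]]
            views = _mv_batch_views(raw, chunk[:, 1:], spec)
            views = window_views(views, rng)
            q = model.forward(views, train=True)
            loss, gq = L.categorical_cross_entropy_grad(targets, q)
            _check_finite(loss, epoch, s)
            opt.zero_grad()
            model.backward(gq / len(chunk))
            opt.step(lr)
            ep_losses.append(loss / len(chunk))
        qv = np.concatenate([model.predict_proba(val_views[i:i + batch_size])
                             for i in range(0, len(val_views), batch_size)])
        val_dsc = _hard_dice(qv.argmax(-1), val_targets, range(spec.n_classes))
        model.train_log.append({"epoch": epoch, "lr": lr, "seed": seed,
                                "train_loss": float(np.mean(ep_losses)),
                                "val_dsc": val_dsc})
        if val_dsc > best:
            best, best_snap = val_dsc, _snapshot(model)
    _restore(model, best_snap)
    model.best_metric = best
    return model


def train_model(spec, cases, val_cases, cfg: OptimizerConfig = OptimizerConfig(),
                **kw):
    """Dispatch to the matching trainer for the spec type."""
    if isinstance(spec, UNetSpec):
        return train_unet(spec, cases, val_cases, cfg, **kw)
    if isinstance(spec, MVSpec):
        return train_mv(spec, cases, val_cases, cfg, **kw)
    raise TypeError(f"unknown spec type {type(spec)!r}")


def train_ensemble(spec, cases, val_cases, cfg: OptimizerConfig = OptimizerConfig(), *,
                   n_members: int = 5, base_seed: int = 0, **kw) -> Ensemble:
    """Sequentially train ``n_members`` models with member seeds base_seed + i."""
    members = [train_model(spec, cases, val_cases, cfg, seed=base_seed + i, **kw)
               for i in range(n_members)]
    return Ensemble(members)
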