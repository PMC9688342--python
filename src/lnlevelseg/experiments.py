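"""Desk-scale end-to-end experiments on synthetic neck phantoms.

The clinical study trained on 60 bilateral CT cases with GPU-scale budgets;
this module runs the same pipeline shrunk to phantom scale so the complete
loop — phantom generation, Gaussian patch sampling, augmented ensemble
training, sliding-window inference, sequential multi-view relabelling,
post-processing and evaluation — executes on one CPU in minutes.  Both the
acceptance tests and ``scripts/acceptance.py`` drive it.

Default scaled-down conditions: 16 half-scale phantoms (10 train / 2
validation / 4 held-out test), a 3-member 2-class residual UNet ensemble
(base 8 filters, 32-cubed patches, 256 pairs per epoch, 10 epochs) for the
combined-structure stage, and a single small 5-class multi-view classifier
for the relabelling stage of the sequential configuration.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .inference import ensemble_fuse, run_configuration
from .metrics import dsc
from .networks import MVSpec, UNetSpec
from .phantom import PhantomSpec, generate_phantom
from .postprocess import postprocess_combined
from .training import Ensemble, OptimizerConfig, train_mv, train_unet
from .volume_io import WindowSetting

__all__ = ["PhantomExperimentResult", "run_phantom_experiment"]


@dataclasses.dataclass
class PhantomExperimentResult:
    """Held-out-phantom outcomes of the scaled-down sequential pipeline."""

    unet_ensemble: Ensemble
    mv_model: object
    #: per test case: combined-structure DSC of the fused, post-processed ensemble
    fused_dsc: list[float]
    #: per test case, per member: combined-structure DSC of single models
    member_dsc: list[list[float]]
    #: per test case: voxels where the C3 output foreground differs from the
    #: post-processed UNet-stage foreground (0 = exact preservation)
    foreground_mismatch: list[int]
    #: per test case: mean per-level DSC of the final C3 segmentation
    level_dsc: list[float]

    @property
    def min_fused_dsc(self) -> float:
        return float(min(self.fused_dsc))

    @property
    def min_member_dsc(self) -> list[float]:
        return [float(min(col)) for col in map(list, zip(*self.member_dsc))] \
            if self.member_dsc else []


def run_phantom_experiment(seed: int = 0, *, n_train: int = 10, n_val: int = 2,
                           n_test: int = 4, n_members: int = 3,
                           epochs: int = 10, pairs_per_epoch: int = 256,
                           batch_size: int = 4, base_filters: int = 8,
                           patch_size: int = 32, mv_epochs: int = 8,
                           mv_pairs_cap: int = 768,
                           window: WindowSetting = WindowSetting()
                           ) -> PhantomExperimentResult:
    """Train and evaluate the sequential (UNet then multi-view) pipeline.

    Deterministic given ``seed``; validation cases for checkpoint selection
    are carved from the training pool, never from the held-out test set.
    """
    rng = np.random.SeedSequence([seed, 2026])
    case_seeds = rng.generate_state(n_train + n_val + n_test)
    # seeds stay below 2**31 for portability of logs
    phantoms = [generate_phantom(PhantomSpec.tiny(seed=int(s % (2 ** 31))))
                for s in case_seeds]
    train = phantoms[:n_train]
    val = phantoms[n_train:n_train + n_val]
    test = phantoms[n_train + n_val:]

    vol0 = train[0][0]
    half_x = vol0.shape[0] * vol0.spacing[0] / 2.0
    roi_extent = (half_x, vol0.shape[1] * vol0.spacing[1],
                  vol0.shape[2] * vol0.spacing[2])

    unet_spec = UNetSpec(patch_size=patch_size, depth=2,
                         base_filters=base_filters, n_classes=2, dropout_p=0.1)
    cfg = OptimizerConfig()
    members = [
        train_unet(unet_spec, train, val, cfg, epochs=epochs,
                   pairs_per_epoch=pairs_per_epoch, batch_size=batch_size,
                   roi_extent=roi_extent, window=window, seed=seed + i)
        for i in range(n_members)
    ]
    ensemble = Ensemble(members)

    mv_spec = MVSpec(in_plane_samples=16, strides=(1, 2, 4), filters=(4, 8, 16),
                     fusion_units=32, n_classes=5, dropout_p=0.1)
    mv = train_mv(mv_spec, train, val, cfg, epochs=mv_epochs,
                  pairs_cap=mv_pairs_cap, window=window, seed=seed + 100)

    fused_dsc, member_dsc, fg_mismatch, level_dsc = [], [], [], []
    for vol, ref in test:
        stages: dict = {}
        seg = run_configuration("C3", vol, unet_ensemble=ensemble,
                                mv_ensemble=mv, window=window, stages=stages)
        fg_stage = stages["unet_foreground"].data > 0
        ref_fg = ref.foreground()
        fused_dsc.append(dsc(fg_stage, ref_fg))
        fg_mismatch.append(int(np.logical_xor(seg.data > 0, fg_stage).sum()))
        per_member = []
        for pm in stages["unet_maps"]:
            mem_fg = postprocess_combined(ensemble_fuse([pm]), keep_components=2).data > 0
            per_member.append(dsc(mem_fg, ref_fg))
        member_dsc.append(per_member)
        lv = [dsc(seg.data == c, ref.data == c) for c in range(1, 6)]
        level_dsc.append(float(np.mean(lv)))
    return PhantomExperimentResult(ensemble, mv, fused_dsc, member_dsc,
                                   fg_mismatch, level_dsc)
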