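import dataclasses

import numpy as np
import pytest

from lnlevelseg import (LabelMap, MVSpec, UNetSpec, Volume, build_mv,
                        classify_masked_voxels, ensemble_fuse, expand_mask,
                        run_configuration, sliding_window_predict)
from lnlevelseg.inference import EvaluationMask, ProbabilityMap
from lnlevelseg.networks import extract_views


@dataclasses.dataclass
class _EchoUNet:
    """Stub UNet whose channel-1 probability echoes the input patch values."""

    spec: UNetSpec

    def predict_proba(self, patches):
        p = np.asarray(patches, np.float32)
        return np.stack([1.0 - p] + [p] * (self.spec.n_classes - 1), axis=-1)


@dataclasses.dataclass
class _ConstMV:
    """Stub multi-view model emitting one fixed distribution per voxel."""

    spec: MVSpec
    dist: np.ndarray

    def predict_proba(self, views):
        return np.tile(self.dist, (len(views), 1))


class TestSlidingWindow:
    def test_every_voxel_scored_once_from_its_window(self, rng):
        """Echo harness: the output reproduces the input exactly, so every
        voxel got the prediction of the window whose center crop covers it."""
        vol = Volume(rng.random((128, 128, 128), dtype=np.float32), (1.25,) * 3)
        stub = _EchoUNet(UNetSpec(patch_size=64, depth=2, base_filters=4,
                                  n_classes=2))
        out = sliding_window_predict(stub, vol)
        assert out.data.shape == (128, 128, 128, 2)
        assert np.array_equal(out.data[..., 1], vol.data)

    def test_tiling_arithmetic_non_multiple_shape(self, rng):
        vol = Volume(rng.random((50, 33, 70), dtype=np.float32), (1.25,) * 3)
        stub = _EchoUNet(UNetSpec(patch_size=32, depth=2, base_filters=4,
                                  n_classes=2))
        out = sliding_window_predict(stub, vol)
        assert np.array_equal(out.data[..., 1], vol.data)

    def test_constant_stub_constant_map(self):
        vol = Volume(np.full((40, 40, 40), 0.3, np.float32), (1.25,) * 3)
        stub = _EchoUNet(UNetSpec(patch_size=32, depth=2, base_filters=4,
                                  n_classes=2))
        out = sliding_window_predict(stub, vol)
        assert np.allclose(out.data[..., 1], 0.3)


class TestMaskExpansion:
    def test_zero_margin_identity(self, tiny_phantom):
        _, lab = tiny_phantom
        mask = expand_mask(lab, 0.0)
        assert np.array_equal(mask.data, lab.foreground())

    def test_single_voxel_matches_distance_oracle(self):
        data = np.zeros((30, 30, 30), np.uint8)
        data[15, 15, 15] = 1
        lab = LabelMap(data, (1.25, 1.25, 1.25))
        mask = expand_mask(lab, 15.0)
        idx = np.indices(data.shape).reshape(3, -1).T
        d = np.linalg.norm((idx - [15, 15, 15]) * 1.25, axis=1)
        oracle = (d <= 15.0).reshape(data.shape)
        assert np.array_equal(mask.data, oracle)

    def test_monotone_nesting(self, tiny_phantom):
        _, lab = tiny_phantom
        m10 = expand_mask(lab, 10.0).data
        m15 = expand_mask(lab, 15.0).data
        assert np.all(m15[m10])

    def test_negative_margin_rejected(self, tiny_phantom):
        with pytest.raises(ValueError):
            expand_mask(tiny_phantom[1], -1.0)


class TestMaskedClassification:
    def test_empty_mask_warns_and_returns_background(self):
        vol = Volume(np.zeros((8, 8, 8), np.float32), (1.25,) * 3)
        mask = EvaluationMask(np.zeros((8, 8, 8), bool), vol.spacing)
        stub = _ConstMV(MVSpec(in_plane_samples=8, strides=(1,), n_scales=1,
                               filters=(2,)), np.eye(6)[1])
        with pytest.warns(UserWarning, match="empty"):
            out = classify_masked_voxels(stub, vol, mask)
        assert np.array_equal(out.data.argmax(-1), np.zeros((8, 8, 8)))

    def test_restriction_to_mask(self, rng):
        vol = Volume(rng.random((10, 10, 10)).astype(np.float32), (1.25,) * 3)
        m = np.zeros((10, 10, 10), bool)
        m.ravel()[rng.choice(1000, 10, replace=False)] = True
        stub = _ConstMV(MVSpec(in_plane_samples=8, strides=(1,), n_scales=1,
                               filters=(2,)), np.eye(6)[3])
        out = classify_masked_voxels(stub, vol, EvaluationMask(m, vol.spacing))
        labels = out.data.argmax(-1)
        assert (labels == 3).sum() == 10
        assert np.array_equal(labels == 3, m)

    def test_full_mask_matches_voxel_loop_oracle(self, rng):
        vol = Volume(rng.random((8, 8, 8)).astype(np.float32), (1.25,) * 3)
        spec = MVSpec(in_plane_samples=8, strides=(1, 2), n_scales=2,
                      filters=(2, 4), fusion_units=8, n_classes=6)
        net = build_mv(spec, seed=0)
        mask = EvaluationMask(np.ones((8, 8, 8), bool), vol.spacing)
        out = classify_masked_voxels(net, vol, mask, batch_size=64)
        for v in [(0, 0, 0), (3, 4, 5), (7, 7, 7)]:
            q = net.predict_proba(extract_views(vol.data, v, spec)[None])[0]
            assert np.allclose(out.data[v], q, atol=1e-5)


class TestEnsembleFusion:
    def _pm(self, arr):
        return ProbabilityMap(np.asarray(arr, np.float32), (1.25,) * 3)

    def test_identical_members_equal_argmax(self, rng):
        probs = rng.random((4, 4, 4, 6)).astype(np.float32)
        probs /= probs.sum(-1, keepdims=True)
        fused = ensemble_fuse([self._pm(probs)] * 3)
        assert np.array_equal(fused.data, probs.argmax(-1))

    def test_summed_probability_hand_example(self):
        a = self._pm(np.array([0.6, 0.4]).reshape(1, 1, 1, 2))
        b = self._pm(np.array([0.1, 0.9]).reshape(1, 1, 1, 2))
        fused = ensemble_fuse([a, b])
        assert fused.data[0, 0, 0] == 1  # summed (0.7, 1.3)

    def test_fusion_beats_majority_vote(self):
        # two weak voters for class 1, one confident voter for class 0
        members = [self._pm(np.array(p).reshape(1, 1, 1, 2)) for p in
                   [(0.9, 0.1), (0.45, 0.55), (0.45, 0.55)]]
        fused = ensemble_fuse(members)
        votes = np.argmax([m.data[0, 0, 0] for m in members], axis=-1)
        assert np.bincount(votes).argmax() == 1   # majority vote says 1
        assert fused.data[0, 0, 0] == 0           # summed probability says 0

    def test_ties_break_to_lower_class(self):
        fused = ensemble_fuse([self._pm(np.full((1, 1, 1, 3), 1 / 3))])
        assert fused.data[0, 0, 0] == 0

    def test_geometry_mismatch_rejected(self, rng):
        a = self._pm(rng.random((2, 2, 2, 6)))
        b = self._pm(rng.random((2, 2, 3, 6)))
        with pytest.raises(ValueError, match="geometry"):
            ensemble_fuse([a, b])


class TestConfigurations:
    def _binary_phantom_volume(self, tiny_phantom):
        """Volume whose windowed intensities equal the reference foreground."""
        _, lab = tiny_phantom
        hu = np.where(lab.foreground(), 1000.0, -1000.0).astype(np.float32)
        return Volume(hu, lab.spacing), lab

    def test_c1_labels_in_range(self, rng):
        vol = Volume(rng.random((32, 32, 32)).astype(np.float32), (1.25,) * 3)
        stub = _EchoUNet(UNetSpec(patch_size=32, depth=2, base_filters=4,
                                  n_classes=6))
        seg = run_configuration("C1", vol, unet_ensemble=[stub])
        assert set(np.unique(seg.data)) <= set(range(6))

    def test_c2_foreground_inside_mask(self, tiny_phantom):
        vol, lab = tiny_phantom
        stub = _ConstMV(MVSpec(in_plane_samples=8, strides=(1,), n_scales=1,
                               filters=(2,)), np.eye(6)[2])
        seg = run_configuration("C2", vol, mv_ensemble=[stub], reference=lab,
                                mask_margin_mm=10.0)
        mask = expand_mask(lab, 10.0).data
        assert not np.any((seg.data > 0) & ~mask)

    def test_c3_preserves_unet_foreground_exactly(self, tiny_phantom):
        vol, lab = self._binary_phantom_volume(tiny_phantom)
        unet = _EchoUNet(UNetSpec(patch_size=32, depth=2, base_filters=4,
                                  n_classes=2))
        mv_spec = MVSpec(in_plane_samples=8, strides=(1,), n_scales=1,
                         filters=(2,), fusion_units=8, n_classes=5)
        mv = build_mv(mv_spec, seed=0)
        stages = {}
        seg = run_configuration("C3", vol, unet_ensemble=[unet],
                                mv_ensemble=[mv], stages=stages)
        fg_stage = stages["unet_foreground"].data > 0
        assert np.array_equal(seg.data > 0, fg_stage)
        assert set(np.unique(seg.data[fg_stage])) <= {1, 2, 3, 4, 5}

    def test_class_count_mismatch_rejected(self, tiny_phantom):
        vol, _ = tiny_phantom
        stub = _EchoUNet(UNetSpec(patch_size=32, depth=2, base_filters=4,
                                  n_classes=2))
        with pytest.raises(ValueError, match="6-class"):
            run_configuration("C1", vol, unet_ensemble=[stub])

    def test_unknown_configuration_rejected(self, tiny_phantom):
        with pytest.raises(ValueError, match="C1, C2 or C3"):
            run_configuration("C9", tiny_phantom[0])
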