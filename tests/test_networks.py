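import numpy as np
import pytest

from lnlevelseg import (MVSpec, UNetSpec, build_mv, build_unet, extract_views,
                        load_model, save_model)
from lnlevelseg.networks import extract_views_batch

TINY_UNET = UNetSpec(patch_size=16, depth=2, base_filters=4, n_classes=6,
                     dropout_p=0.1)
TINY_MV = MVSpec(in_plane_samples=16, strides=(1, 2, 4), filters=(2, 4, 8),
                 fusion_units=16, n_classes=6)


class TestUNet:
    def test_output_shape_and_softmax(self, rng):
        net = build_unet(TINY_UNET, seed=0)
        x = rng.random((2, 16, 16, 16), dtype=np.float32)
        probs = net.predict_proba(x)
        assert probs.shape == (2, 16, 16, 16, 6)
        assert np.allclose(probs.sum(-1), 1.0, atol=1e-5)
        assert probs.min() >= 0.0

    def test_two_class_variant(self, rng):
        spec = UNetSpec(patch_size=16, depth=2, base_filters=4, n_classes=2)
        net = build_unet(spec, seed=0)
        probs = net.predict_proba(rng.random((1, 16, 16, 16), dtype=np.float32))
        assert probs.shape[-1] == 2

    def test_seeded_builds_identical(self):
        a, b = build_unet(TINY_UNET, seed=9), build_unet(TINY_UNET, seed=9)
        assert all(np.array_equal(p.value, q.value)
                   for p, q in zip(a.params(), b.params()))
        c = build_unet(TINY_UNET, seed=10)
        assert any(not np.array_equal(p.value, q.value)
                   for p, q in zip(a.params(), c.params()))

    def test_incompatible_patch_depth_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            UNetSpec(patch_size=20, depth=4)

    def test_deterministic_at_inference(self, rng):
        net = build_unet(TINY_UNET, seed=1)
        x = rng.random((1, 16, 16, 16), dtype=np.float32)
        assert np.array_equal(net.predict_proba(x), net.predict_proba(x))

    def test_translation_covariance_on_interior(self, rng):
        """Shifting content by a pooling-aligned offset shifts the argmax map."""
        net = build_unet(UNetSpec(patch_size=32, depth=2, base_filters=4,
                                  n_classes=3), seed=4)
        # non-trivial running stats so eval-mode BN is not degenerate
        for p in net.params():
            if not p.trainable and p.value.ndim == 1:
                p.value += 0.01
        base = rng.random((40, 32, 32), dtype=np.float32)
        a = net.predict_proba(base[None, :32]).argmax(-1)[0]
        b = net.predict_proba(base[None, 8:40]).argmax(-1)[0]
        inner_a = a[16:24, 8:24, 8:24]
        inner_b = b[8:16, 8:24, 8:24]
        agreement = (inner_a == inner_b).mean()
        assert agreement >= 0.95


class TestMultiView:
    def test_probability_output(self, rng):
        net = build_mv(TINY_MV, seed=0)
        views = rng.random((3, 3, 3, 16, 16), dtype=np.float32)
        q = net.predict_proba(views)
        assert q.shape == (3, 6)
        assert np.allclose(q.sum(-1), 1.0, atol=1e-6)

    def test_five_class_variant(self, rng):
        spec = MVSpec(in_plane_samples=16, strides=(1, 2, 4), filters=(2, 4, 8),
                      fusion_units=16, n_classes=5)
        q = build_mv(spec, seed=0).predict_proba(
            rng.random((1, 3, 3, 16, 16), dtype=np.float32))
        assert q.shape == (1, 5)

    def test_batching_order_preserving(self, rng):
        net = build_mv(TINY_MV, seed=2)
        views = rng.random((5, 3, 3, 16, 16), dtype=np.float32)
        q_all = net.predict_proba(views)
        q_one = np.concatenate([net.predict_proba(views[i:i + 1])
                                for i in range(5)])
        assert np.allclose(q_all, q_one, atol=1e-5)

    def test_stride_mismatch_rejected(self):
        with pytest.raises(ValueError, match="stride"):
            MVSpec(n_scales=3, strides=(1, 2))


class TestViewExtraction:
    def test_constant_volume_constant_views(self):
        data = np.full((30, 30, 30), 7.0, np.float32)
        vs = extract_views(data, (15, 15, 15), TINY_MV)
        assert vs.shape == (3, 3, 16, 16)
        assert np.all(vs == 7.0)

    def test_scale_spans(self):
        spec = MVSpec()
        assert spec.span_mm(0) == pytest.approx(40.0)   # 4 cm
        assert spec.span_mm(1) == pytest.approx(80.0)   # 8 cm
        assert spec.span_mm(2) == pytest.approx(160.0)  # 16 cm

    def test_axial_scale0_equals_direct_crop(self, rng):
        data = rng.random((40, 40, 40)).astype(np.float32)
        spec = MVSpec(in_plane_samples=8, strides=(1,), n_scales=1, filters=(2,))
        vs = extract_views(data, (20, 21, 22), spec)
        assert np.array_equal(vs[0, 0], data[16:24, 17:25, 22])
        # sagittal: (y, z) plane at fixed x; coronal: (x, z) at fixed y
        assert np.array_equal(vs[0, 1], data[20, 17:25, 18:26])
        assert np.array_equal(vs[0, 2], data[16:24, 21, 18:26])

    def test_edge_padding_replicates(self):
        data = np.arange(27, dtype=np.float32).reshape(3, 3, 3)
        spec = MVSpec(in_plane_samples=8, strides=(4,), n_scales=1, filters=(2,))
        vs = extract_views(data, (0, 0, 0), spec)
        assert np.isfinite(vs).all()
        assert vs[0, 0, 0, 0] == data[0, 0, 0]

    def test_voxel_outside_volume_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            extract_views(np.zeros((5, 5, 5)), (5, 0, 0), TINY_MV)

    def test_batch_matches_single(self, rng):
        data = rng.random((20, 20, 20)).astype(np.float32)
        centers = np.array([[3, 4, 5], [10, 10, 10], [19, 0, 7]])
        batch = extract_views_batch(data, centers, TINY_MV)
        for i, c in enumerate(centers):
            assert np.array_equal(batch[i], extract_views(data, c, TINY_MV))


class TestCheckpoints:
    def test_unet_roundtrip(self, tmp_path, rng):
        net = build_unet(TINY_UNET, seed=3)
        net.best_metric = 0.77
        x = rng.random((1, 16, 16, 16), dtype=np.float32)
        ref = net.predict_proba(x)
        path = save_model(net, tmp_path / "u.npz")
        back = load_model(path)
        assert back.spec == net.spec
        assert back.best_metric == pytest.approx(0.77)
        assert np.allclose(back.predict_proba(x), ref, atol=1e-6)

    def test_mv_roundtrip(self, tmp_path, rng):
        net = build_mv(TINY_MV, seed=3)
        views = rng.random((2, 3, 3, 16, 16), dtype=np.float32)
        ref = net.predict_proba(views)
        back = load_model(save_model(net, tmp_path / "m.npz"))
        assert np.allclose(back.predict_proba(views), ref, atol=1e-6)
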