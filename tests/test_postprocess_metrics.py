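import numpy as np
import pytest
from scipy import ndimage

from lnlevelseg import (LabelMap, dsc, evaluate_case, expand_ptv, hausdorff,
                        icc_consistency, msd, postprocess_combined,
                        volume_outside)
from lnlevelseg.metrics import surface_voxels


def _lab(data, spacing=(1.25, 1.25, 1.25)):
    return LabelMap(np.asarray(data, np.uint8), spacing)


def _bfs_components(mask):
    """Independent 26-connectivity component labelling by exhaustive BFS."""
    visited = np.zeros_like(mask, bool)
    comps = []
    idx = np.argwhere(mask)
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
               for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    for start in map(tuple, idx):
        if visited[start]:
            continue
        stack, comp = [start], []
        visited[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for o in offsets:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) \
                        and mask[w] and not visited[w]:
                    visited[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps


class TestPostprocess:
    def test_interior_hole_filled(self):
        data = np.zeros((9, 9, 9), np.uint8)
        data[2:7, 2:7, 2:7] = 3
        data[4, 4, 4] = 0
        out = postprocess_combined(_lab(data))
        assert out.data[4, 4, 4] == 3  # majority label of the neighbourhood

    def test_small_component_removed(self):
        data = np.zeros((12, 12, 12), np.uint8)
        data[1:6, 1:6, 1:5] = 1          # 100 voxels
        data[9:11, 9:11, 9:11] = 2       # 8 voxels, disjoint (5 in spec example)
        data[9, 9, 9] = 2
        out = postprocess_combined(_lab(data))
        assert np.all(out.data[9:11, 9:11, 9:11] == 0)
        assert (out.data == 1).sum() == 100

    def test_keep_two_components_preserves_bilateral(self, tiny_phantom):
        _, lab = tiny_phantom
        out = postprocess_combined(lab, keep_components=2)
        assert np.array_equal(out.data, lab.data)

    def test_matches_component_oracle_with_speckle(self, rng, tiny_phantom):
        _, lab = tiny_phantom
        noisy = lab.data.copy()
        # inject isolated speckle voxels away from the structure
        for _ in range(20):
            i = tuple(rng.integers(0, s) for s in noisy.shape)
            if noisy[i] == 0 and not ndimage.binary_dilation(
                    noisy > 0, np.ones((3, 3, 3)))[i]:
                noisy[i] = rng.integers(1, 6)
        sub = _lab(noisy[:32, :48, 20:60])
        out = postprocess_combined(sub)
        comps = _bfs_components(ndimage.binary_fill_holes(sub.data > 0))
        largest = max(comps, key=len)
        expect = np.zeros(sub.shape, bool)
        expect[tuple(np.array(largest).T)] = True
        assert np.array_equal(out.data > 0, expect)

    def test_idempotent(self, tiny_phantom):
        _, lab = tiny_phantom
        once = postprocess_combined(lab, keep_components=2)
        twice = postprocess_combined(once, keep_components=2)
        assert np.array_equal(once.data, twice.data)

    def test_empty_foreground_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = postprocess_combined(_lab(np.zeros((4, 4, 4))))
        assert not out.data.any()


class TestPTV:
    def test_zero_margin_is_level_union(self, tiny_phantom):
        _, lab = tiny_phantom
        ptv = expand_ptv(lab, [2, 3, 4], margin_mm=0.0)
        assert np.array_equal(ptv, np.isin(lab.data, [2, 3, 4]))

    def test_single_voxel_ball_count_oracle(self):
        data = np.zeros((15, 15, 15), np.uint8)
        data[7, 7, 7] = 1
        ptv = expand_ptv(_lab(data), [1], margin_mm=4.0)
        idx = np.indices(data.shape).reshape(3, -1).T
        d = np.linalg.norm((idx - [7, 7, 7]) * 1.25, axis=1)
        assert ptv.sum() == (d <= 4.0).sum()

    def test_nested_ptvs(self, tiny_phantom):
        _, lab = tiny_phantom
        p15 = expand_ptv(lab, [1, 2, 3, 4, 5], 4.0)
        p24 = expand_ptv(lab, [2, 3, 4], 4.0)
        assert np.all(p15[p24])

    def test_unknown_level_rejected(self, tiny_phantom):
        with pytest.raises(ValueError, match="unknown level"):
            expand_ptv(tiny_phantom[1], [7])


class TestOverlapMetrics:
    def test_dsc_basics(self):
        a = np.zeros((4, 4, 4), bool); a[:2] = True
        assert dsc(a, a) == 1.0
        assert dsc(a, ~a) == 0.0
        assert dsc(np.zeros((2, 2, 2)), np.zeros((2, 2, 2))) == 1.0
        assert dsc(a, np.zeros_like(a)) == 0.0

    def test_dsc_half_overlap(self):
        a = np.zeros(8, bool); a[:4] = True
        b = np.zeros(8, bool); b[2:6] = True
        assert dsc(a.reshape(2, 2, 2), b.reshape(2, 2, 2)) == pytest.approx(0.5)

    def test_dsc_symmetric(self, rng):
        a = rng.random((5, 5, 5)) < 0.4
        b = rng.random((5, 5, 5)) < 0.4
        assert dsc(a, b) == dsc(b, a)

    def test_volume_outside(self):
        ref = np.zeros((10, 10, 10), bool); ref[2:5, 2:5, 2:5] = True
        pred = ref.copy(); pred[8, 8, 8] = True
        sp = (1.25, 1.25, 1.25)
        assert volume_outside(ref, ref, sp) == 0.0
        assert volume_outside(pred, ref, sp) == pytest.approx(1.953125e-3)
        pred2 = pred.copy(); pred2[8, 8, 9] = True
        assert volume_outside(pred2, ref, sp) == pytest.approx(2 * 1.953125e-3)


class TestSurfaceDistances:
    def test_identical_masks_zero(self):
        m = np.zeros((8, 8, 8), bool); m[2:6, 2:6, 2:6] = True
        sp = (1.0, 1.0, 1.0)
        assert hausdorff(m, m, sp) == 0.0
        assert msd(m, m, sp) == 0.0

    def test_two_voxels_ten_mm_apart(self):
        a = np.zeros((20, 5, 5), bool); a[2, 2, 2] = True
        b = np.zeros((20, 5, 5), bool); b[10, 2, 2] = True
        sp = (1.25, 1.25, 1.25)
        assert hausdorff(a, b, sp) == pytest.approx(10.0)
        assert msd(a, b, sp) == pytest.approx(10.0)

    def test_empty_mask_undefined(self):
        m = np.zeros((4, 4, 4), bool); m[1, 1, 1] = True
        assert np.isnan(hausdorff(m, np.zeros_like(m), (1, 1, 1)))
        assert np.isnan(msd(np.zeros_like(m), m, (1, 1, 1)))

    def test_random_masks_match_brute_force_oracle(self, rng):
        sp = (1.5, 1.0, 2.0)
        for _ in range(5):
            a = rng.random((6, 6, 6)) < 0.35
            b = rng.random((6, 6, 6)) < 0.35
            if not a.any() or not b.any():
                continue
            sa = np.argwhere(surface_voxels(a)) * sp
            sb = np.argwhere(surface_voxels(b)) * sp
            d = np.linalg.norm(sa[:, None, :] - sb[None, :, :], axis=-1)
            hd_oracle = max(d.min(1).max(), d.min(0).max())
            msd_oracle = (d.min(1).mean() + d.min(0).mean()) / 2
            assert hausdorff(a, b, sp) == pytest.approx(hd_oracle, abs=1e-9)
            assert msd(a, b, sp) == pytest.approx(msd_oracle, abs=1e-9)

    def test_symmetry(self, rng):
        a = rng.random((6, 6, 6)) < 0.4
        b = rng.random((6, 6, 6)) < 0.4
        sp = (1.25, 1.25, 1.25)
        assert hausdorff(a, b, sp) == hausdorff(b, a, sp)
        assert msd(a, b, sp) == msd(b, a, sp)

    def test_surface_is_six_connectivity_exposure(self):
        m = np.zeros((5, 5, 5), bool); m[1:4, 1:4, 1:4] = True
        surf = surface_voxels(m)
        assert not surf[2, 2, 2]      # interior voxel
        assert surf[1, 2, 2]


class TestICC:
    def test_identity_and_offset(self):
        v = np.array([1.0, 2.0, 5.0, 7.0, 3.0, 9.0])
        assert icc_consistency(v, v) == pytest.approx(1.0)
        assert icc_consistency(v, v + 3.7) == pytest.approx(1.0)

    def test_constant_inputs_undefined(self):
        assert np.isnan(icc_consistency([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]))

    def test_six_case_table_matches_anova_oracle(self):
        v1 = np.array([10.0, 12.5, 9.1, 14.2, 11.0, 8.4])
        v2 = np.array([10.8, 12.1, 9.9, 13.5, 12.2, 8.0])
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        n = len(v1)
        df = pd.DataFrame({
            "targets": np.tile(np.arange(n), 2),
            "raters": np.repeat(["a", "b"], n),
            "score": np.concatenate([v1, v2]),
        })
        table = pg.intraclass_corr(df, targets="targets", raters="raters",
                                   ratings="score")
        # two-way mixed, single measurement, consistency
        row = table["Type"].isin(["ICC3", "ICC(C,1)"])
        expect = float(table.loc[row, "ICC"].iloc[0])
        assert icc_consistency(v1, v2) == pytest.approx(expect, abs=1e-10)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            icc_consistency([1.0, 2.0], [1.0, 2.0])


class TestCaseReport:
    def test_perfect_prediction_report(self, tiny_phantom):
        _, lab = tiny_phantom
        report = evaluate_case(lab, lab)
        assert list(report.index) == ["I", "II", "III", "IV", "V", "I-V",
                                      "PI-PV", "PII-PIV"]
        assert np.allclose(report["dsc"], 1.0)
        assert np.allclose(report["hd_mm"], 0.0)
        assert np.allclose(report["volume_outside_ml"], 0.0)
        assert np.allclose(report["pred_volume_ml"], report["ref_volume_ml"])

    def test_missing_level_conventions(self, tiny_phantom):
        _, lab = tiny_phantom
        pred = LabelMap(np.where(lab.data == 5, 0, lab.data).astype(np.uint8),
                        lab.spacing)
        report = evaluate_case(pred, lab)
        assert report.loc["V", "dsc"] == 0.0
        assert np.isnan(report.loc["V", "hd_mm"])
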