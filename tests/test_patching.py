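import itertools

import numpy as np
import pytest

import segpipe as sp
from segpipe.errors import CoverageError, ValidationError
from segpipe.patching import PatchSet
from segpipe.preprocessing import one_hot_decode, one_hot_encode


def brute_force_offsets(shape, patch, overlap):
    """Independent enumeration oracle: walk each axis by stride, edge-align."""
    per_axis = []
    for s, p, o in zip(shape, patch, overlap):
        stride = p - o
        offs, pos = [], 0
        while pos + p <= s:
            offs.append(pos)
            pos += stride
        if offs[-1] + p < s:
            offs.append(s - p)
        per_axis.append(offs)
    return [tuple(t) for t in itertools.product(*per_axis)]


def random_config(rng, ndim):
    shape = tuple(int(rng.integers(4, 65)) for _ in range(ndim))
    patch = tuple(int(rng.integers(2, s + 1)) for s in shape)
    overlap = tuple(int(rng.integers(0, p)) for p in patch)
    return shape, patch, overlap


class TestGrid:
    def test_large_ct_case(self):
        offs = sp.compute_patch_grid((400, 512, 512), (128,) * 3, (0,) * 3)
        assert len(offs) == 64
        assert sorted({o[0] for o in offs}) == [0, 128, 256, 272]
        for a in (1, 2):
            assert sorted({o[a] for o in offs}) == [0, 128, 256, 384]

    def test_single_patch_when_shape_equals_patch(self):
        assert sp.compute_patch_grid((8, 8), (8, 8), (3, 3)) == [(0, 0)]

    def test_stride_two_grid(self):
        offs = sp.compute_patch_grid((8, 8), (4, 4), (2, 2))
        assert sorted({o[0] for o in offs}) == [0, 2, 4]
        assert len(offs) == 9

    def test_matches_bruteforce_and_covers(self, rng):
        for trial in range(100):
            ndim = 2 if trial % 2 else 3
            shape, patch, overlap = random_config(rng, ndim)
            offs = sp.compute_patch_grid(shape, patch, overlap)
            assert offs == brute_force_offsets(shape, patch, overlap)
            covered = np.zeros(shape, dtype=bool)
            for off in offs:
                assert all(0 <= o and o + p <= s
                           for o, p, s in zip(off, patch, shape))
                covered[tuple(slice(o, o + p) for o, p in zip(off, patch))] = True
            assert covered.all()

    def test_patch_larger_than_volume_errors(self):
        with pytest.raises(ValidationError, match="larger than volume"):
            sp.compute_patch_grid((4, 4), (8, 4), (0, 0))


class TestExtract:
    def test_constant_volume(self):
        vol = np.full((8, 8, 1), 3.5, np.float32)
        ps = sp.extract_patches(vol, sp.compute_patch_grid((8, 8), (4, 4), (2, 2)),
                                (4, 4))
        assert np.all(ps.patches == 3.5)

    def test_corner_values_match_flat_index(self):
        shape = (6, 5)
        vol = np.arange(30, dtype=np.float32).reshape(shape)[..., None]
        offs = sp.compute_patch_grid(shape, (3, 3), (1, 1))
        ps = sp.extract_patches(vol, offs, (3, 3))
        for off, patch in zip(ps.offsets, ps.patches):
            assert patch[0, 0, 0] == off[0] * 5 + off[1]

    def test_nonoverlapping_reassembly(self, rng):
        vol = rng.normal(size=(8, 12, 2)).astype(np.float32)
        offs = sp.compute_patch_grid((8, 12), (4, 4), (0, 0))
        ps = sp.extract_patches(vol, offs, (4, 4))
        rebuilt = np.zeros_like(vol)
        for off, patch in zip(ps.offsets, ps.patches):
            rebuilt[off[0]:off[0] + 4, off[1]:off[1] + 4] = patch
        np.testing.assert_array_equal(rebuilt, vol)


class TestBlankFilter:
    def _sets(self, seg, patch, overlap):
        shape = seg.shape
        offs = sp.compute_patch_grid(shape, patch, overlap)
        img = sp.extract_patches(np.zeros(shape + (1,), np.float32), offs, patch)
        segs = sp.extract_patches(seg[..., None], offs, patch)
        return img, segs

    def test_all_background_drops_everything(self):
        img, segs = self._sets(np.zeros((8, 8), np.int32), (4, 4), (0, 0))
        fi, fs = sp.filter_blank_patches(img, segs)
        assert len(fi) == 0 and len(fs) == 0

    def test_single_voxel_keeps_unique_container(self):
        seg = np.zeros((8, 8), np.int32)
        seg[0, 0] = 1
        img, segs = self._sets(seg, (4, 4), (0, 0))
        fi, fs = sp.filter_blank_patches(img, segs)
        assert fi.offsets == [(0, 0)] and fs.offsets == [(0, 0)]

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            shape = tuple(int(rng.integers(5, 20)) for _ in range(2))
            seg = (rng.random(shape) < 0.02).astype(np.int32)
            patch = tuple(int(rng.integers(2, s + 1)) for s in shape)
            overlap = tuple(int(rng.integers(0, p)) for p in patch)
            img, segs = self._sets(seg, patch, overlap)
            fi, _ = sp.filter_blank_patches(img, segs)
            expected = sum(
                1 for off in sp.compute_patch_grid(shape, patch, overlap)
                if seg[tuple(slice(o, o + p) for o, p in zip(off, patch))].any()
            )
            assert len(fi) == expected

    def test_misaligned_sets_rejected(self):
        img, segs = self._sets(np.ones((8, 8), np.int32), (4, 4), (0, 0))
        segs.offsets = segs.offsets[::-1]
        with pytest.raises(ValidationError):
            sp.filter_blank_patches(img, segs)


class TestRandomCrop:
    def test_volume_equals_patch(self, rng):
        img = rng.normal(size=(4, 4, 1)).astype(np.float32)
        seg = rng.integers(0, 2, size=(4, 4)).astype(np.int32)
        x, y = sp.random_crop(img, seg, (4, 4), rng)
        np.testing.assert_array_equal(x, img)
        np.testing.assert_array_equal(y, seg)

    def test_seed_determinism(self):
        img = np.random.default_rng(0).normal(size=(10, 10, 1)).astype(np.float32)
        seg = np.zeros((10, 10), np.int32)
        a = sp.random_crop(img, seg, (4, 4), np.random.default_rng(42))
        b = sp.random_crop(img, seg, (4, 4), np.random.default_rng(42))
        np.testing.assert_array_equal(a[0], b[0])

    def test_offset_uniformity(self):
        # axis of 2 valid offsets: both should appear about half the time
        img = np.arange(2, dtype=np.float32).reshape(2, 1, 1)
        seg = np.zeros((2, 1), np.int32)
        rng = np.random.default_rng(7)
        hits = sum(
            sp.random_crop(img, seg, (1, 1), rng)[0][0, 0, 0] == 0.0
            for _ in range(10_000)
        )
        assert abs(hits / 10_000 - 0.5) < 0.02


class TestMerge:
    def test_two_window_mean(self):
        off = [(0,), (4,)]
        patches = np.zeros((2, 6, 1), np.float64)
        patches[0] = 0.2
        patches[1] = 0.6
        ps = PatchSet(off, patches, (10,))
        merged = sp.merge_overlapping_predictions(ps, (10,), 1)
        np.testing.assert_allclose(merged[:4, 0], 0.2)
        np.testing.assert_allclose(merged[4:6, 0], 0.4)  # overlap
        np.testing.assert_allclose(merged[6:, 0], 0.6)

    def test_uncovered_voxel_raises(self):
        ps = PatchSet([(0,)], np.ones((1, 3, 1)), (5,))
        with pytest.raises(CoverageError):
            sp.merge_overlapping_predictions(ps, (5,), 1)

    def test_permutation_invariance(self, rng):
        shape = (12, 12)
        offs = sp.compute_patch_grid(shape, (6, 6), (3, 3))
        probs = rng.random((len(offs), 6, 6, 2))
        a = sp.merge_overlapping_predictions(PatchSet(list(offs), probs, shape),
                                             shape, 2)
        perm = rng.permutation(len(offs))
        b = sp.merge_overlapping_predictions(
            PatchSet([offs[i] for i in perm], probs[perm], shape), shape, 2)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_lossless_roundtrip_on_ground_truth(self, rng):
        # the flagship guarantee: slice one-hot truth, merge, decode -> identity
        for trial in range(20):
            ndim = 2 if trial % 2 else 3
            shape = tuple(int(rng.integers(6, 24)) for _ in range(ndim))
            patch = tuple(int(rng.integers(2, s + 1)) for s in shape)
            overlap = tuple(int(rng.integers(0, p)) for p in patch)
            mask = rng.integers(0, 3, size=shape).astype(np.int32)
            onehot = one_hot_encode(mask, 3)
            offs = sp.compute_patch_grid(shape, patch, overlap)
            ps = sp.extract_patches(onehot, offs, patch)
            merged = sp.merge_overlapping_predictions(ps, shape, 3)
            np.testing.assert_array_equal(one_hot_decode(merged), mask)
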