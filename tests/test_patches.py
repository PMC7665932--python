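"""Patch extraction, random crops, augmentation, and the patch cache."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrdenoise.patches import (
    PatchSet,
    augment,
    extract_patches,
    grid_patch_count,
    load_patch_cache,
    minibatches,
    random_crops,
    save_patch_cache,
)
from mrdenoise.phantom import ImagePair, NoiseSpec


def _make_pair(h, w, seed=0):
    rng = np.random.default_rng(seed)
    clean = rng.random((h, w))
    return ImagePair(clean=clean, noisy=clean + rng.normal(0, 0.1, (h, w)),
                     noise=NoiseSpec(model="gaussian", percent=10.0))


def _brute_force_offsets(dim, patch, stride):
    return [o for o in range(0, dim + 1, stride) if o + patch <= dim]


class TestExtractPatches:
    def test_exact_fit_gives_one_patch(self):
        ps = extract_patches(_make_pair(32, 32), patch_size=32, stride=10)
        assert len(ps) == 1

    def test_standard_grid_on_180x215(self):
        ps = extract_patches(_make_pair(180, 215), patch_size=32, stride=10)
        ny = len(_brute_force_offsets(180, 32, 10))
        nx = len(_brute_force_offsets(215, 32, 10))
        assert (ny, nx) == (15, 19)
        assert len(ps) == ny * nx == 285

    def test_undersized_image_gives_empty_set(self):
        ps = extract_patches(_make_pair(30, 30), patch_size=32, stride=10)
        assert len(ps) == 0

    def test_pairing_integrity(self):
        pair = _make_pair(50, 60, seed=3)
        ps = extract_patches(pair, patch_size=16, stride=7)
        noise = pair.noisy - pair.clean
        idx = 0
        for y0 in _brute_force_offsets(50, 16, 7):
            for x0 in _brute_force_offsets(60, 16, 7):
                expected = noise[y0 : y0 + 16, x0 : x0 + 16]
                np.testing.assert_array_equal(ps.noisy[idx] - ps.clean[idx], expected)
                idx += 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        h=st.integers(16, 64),
        w=st.integers(16, 64),
        patch=st.integers(1, 64),
        stride=st.integers(1, 20),
    )
    def test_count_matches_brute_force_enumeration(self, h, w, patch, stride):
        ps = extract_patches(_make_pair(h, w), patch_size=patch, stride=stride)
        expected = len(_brute_force_offsets(h, patch, stride)) * len(
            _brute_force_offsets(w, patch, stride)
        )
        assert len(ps) == expected
        assert grid_patch_count(h, patch, stride) * grid_patch_count(w, patch, stride) == expected

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(_make_pair(32, 32), patch_size=0, stride=10)
        with pytest.raises(ValueError):
            extract_patches(_make_pair(32, 32), patch_size=32, stride=0)


class TestRandomCrops:
    def test_count_and_shape(self):
        ps = random_crops(_make_pair(64, 64), crop_size=45, n=10, seed=1)
        assert len(ps) == 10
        assert ps.noisy.shape == (10, 45, 45)

    def test_deterministic_for_fixed_seed(self):
        pair = _make_pair(64, 64)
        a = random_crops(pair, crop_size=45, n=5, seed=1)
        b = random_crops(pair, crop_size=45, n=5, seed=1)
        assert np.array_equal(a.noisy, b.noisy)

    def test_full_image_crop_degenerate_case(self):
        pair = _make_pair(40, 40)
        ps = random_crops(pair, crop_size=40, n=3, seed=2)
        for i in range(3):
            np.testing.assert_array_equal(ps.clean[i], pair.clean)

    def test_oversized_crop_rejected(self):
        with pytest.raises(ValueError):
            random_crops(_make_pair(32, 32), crop_size=45, n=1, seed=0)

    def test_crops_are_paired(self):
        pair = _make_pair(64, 64, seed=5)
        noise = pair.noisy - pair.clean
        ps = random_crops(pair, crop_size=20, n=8, seed=3)
        # every noisy crop differs from its clean crop by a sub-block of the
        # noise field, located somewhere in the image
        for i in range(8):
            diff = ps.noisy[i] - ps.clean[i]
            found = any(
                np.array_equal(diff, noise[y : y + 20, x : x + 20])
                for y in range(45)
                for x in range(45)
            )
            assert found


class TestAugment:
    def test_flips_quadruple_the_set(self):
        ps = random_crops(_make_pair(32, 32), crop_size=16, n=1, seed=0)
        out = augment(ps, flips=True, translations=False)
        assert len(out) == 4
        # the three extras are the h, v, hv mirrors of the original
        np.testing.assert_array_equal(out.clean[1], ps.clean[0][:, ::-1])
        np.testing.assert_array_equal(out.clean[2], ps.clean[0][::-1, :])
        np.testing.assert_array_equal(out.clean[3], ps.clean[0][::-1, ::-1])

    def test_identity_when_disabled(self):
        ps = random_crops(_make_pair(32, 32), crop_size=16, n=3, seed=0)
        out = augment(ps, flips=False, translations=False)
        assert np.array_equal(out.noisy, ps.noisy)
        assert np.array_equal(out.clean, ps.clean)

    def test_flip_is_involution(self):
        ps = random_crops(_make_pair(32, 32), crop_size=16, n=1, seed=0)
        once = augment(ps, flips=True, translations=False)
        assert np.array_equal(once.clean[1][:, ::-1], ps.clean[0])

    def test_flips_preserve_pixel_multisets(self):
        ps = random_crops(_make_pair(32, 32), crop_size=16, n=2, seed=1)
        out = augment(ps, flips=True, translations=False)
        base = np.sort(ps.clean, axis=None)
        for i in range(len(out)):
            np.testing.assert_array_equal(
                np.sort(out.clean[i], axis=None), np.sort(ps.clean[i % 2], axis=None)
            )
        assert np.array_equal(np.sort(out.clean[:2], axis=None), base)

    def test_translations_keep_pairing(self):
        ps = random_crops(_make_pair(32, 32), crop_size=16, n=2, seed=1)
        out = augment(ps, flips=False, translations=True, seed=4)
        assert len(out) == 4
        # cyclic shifts apply the same offset to noisy and clean
        for i in range(2, 4):
            diff = out.noisy[i] - out.clean[i]
            orig = ps.noisy[i - 2] - ps.clean[i - 2]
            assert np.isclose(np.sort(diff, axis=None), np.sort(orig, axis=None)).all()

    def test_empty_set_rejected(self):
        empty = PatchSet(
            noisy=np.empty((0, 8, 8)), clean=np.empty((0, 8, 8)), patch_size=8
        )
        with pytest.raises(ValueError):
            augment(empty)


class TestCacheAndBatches:
    def test_cache_round_trip(self, tmp_path):
        ps = random_crops(_make_pair(32, 32), crop_size=16, n=5, seed=1)
        path = tmp_path / "cache.npz"
        save_patch_cache(path, ps, meta={"seed": 1})
        loaded = load_patch_cache(path)
        assert np.array_equal(loaded.noisy, ps.noisy)
        assert np.array_equal(loaded.clean, ps.clean)
        assert loaded.patch_size == 16

    def test_minibatches_cover_all_patches_once(self):
        ps = random_crops(_make_pair(32, 32), crop_size=8, n=12, seed=1)
        batches = list(minibatches(ps, batch_size=4, seed=0))
        assert sum(b[0].shape[0] for b in batches) == 12
        stacked = np.concatenate([b[0] for b in batches])
        assert np.array_equal(
            np.sort(stacked, axis=None), np.sort(ps.noisy, axis=None)
        )

    def test_minibatch_shuffle_is_seeded(self):
        ps = random_crops(_make_pair(32, 32), crop_size=8, n=12, seed=1)
        a = [b[0] for b in minibatches(ps, 4, seed=5)]
        b = [x[0] for x in minibatches(ps, 4, seed=5)]
        for xa, xb in zip(a, b):
            assert np.array_equal(xa, xb)
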