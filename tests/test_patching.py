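import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mandfrac.patching import (GAP_WINDOWS, Patch, extract_patch, gap_channels,
                               patch_grid, relative_position,
                               sample_balanced_patches, soften_fracture_target)


class TestPatchGrid:
    def test_single_patch(self):
        assert patch_grid((64, 64, 64), 64, 32) == [(0, 0, 0)]

    def test_two_patches_along_one_axis(self):
        origins = patch_grid((96, 64, 64), 64, 32)
        assert sorted({o[0] for o in origins}) == [0, 32]
        assert len(origins) == 2

    def test_small_volume_clamped(self):
        assert patch_grid((63, 63, 63), 64, 32) == [(0, 0, 0)]

    @given(st.tuples(st.integers(1, 150), st.integers(1, 150),
                     st.integers(1, 150)),
           st.integers(1, 64))
    @settings(max_examples=40, deadline=None)
    def test_every_voxel_covered(self, shape, stride):
        """Tiling coverage: every voxel lies in at least one patch."""
        origins = patch_grid(shape, 64, stride)
        covered = np.zeros(shape, dtype=bool)
        for o in origins:
            sl = tuple(slice(a, min(a + 64, s)) for a, s in zip(o, shape))
            covered[sl] = True
        assert covered.all()


class TestExtractPatch:
    def test_interior_exact(self):
        rng = np.random.default_rng(0)
        data = rng.random((80, 80, 80)).astype(np.float32)
        p = extract_patch(data, (8, 8, 8), 64)
        assert np.array_equal(p.data[0], data[8:72, 8:72, 8:72])
        assert p.valid_extent == (64, 64, 64)

    def test_corner_padding(self):
        data = np.ones((10, 10, 10), dtype=np.float32)
        p = extract_patch(data, (9, 9, 9), 64)
        assert p.valid_extent == (1, 1, 1)
        assert p.data.sum() == 1.0

    def test_out_of_range_origin(self):
        data = np.zeros((10, 10, 10))
        with pytest.raises(ValueError):
            extract_patch(data, (10, 0, 0), 64)
        with pytest.raises(ValueError):
            extract_patch(data, (-1, 0, 0), 64)

    def test_mask_sum_conservation(self):
        """Tiled patches, deweighted by coverage, reproduce the mask sum."""
        rng = np.random.default_rng(1)
        mask = (rng.random((40, 50, 45)) > 0.8).astype(np.float32)
        origins = patch_grid(mask.shape, 32, 16)
        coverage = np.zeros(mask.shape, dtype=np.float32)
        for o in origins:
            sl = tuple(slice(a, min(a + 32, s)) for a, s in zip(o, mask.shape))
            coverage[sl] += 1
        total = 0.0
        weighted = mask / coverage
        for o in origins:
            total += extract_patch(weighted, o, 32).data.sum()
        assert total == pytest.approx(mask.sum(), rel=1e-5)


class TestGapChannels:
    def test_constant_patch_degenerate(self):
        p = extract_patch(np.full((64, 64, 64), 0.5, np.float32), (0, 0, 0))
        out = gap_channels(p)
        assert out.channels == 4
        assert np.all(out.data[1:] == 0.0)

    def test_windows_match_percentile_oracle(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9], np.float32)
        data = np.zeros((2, 2, 2), dtype=np.float32)
        data.flat[:] = vals
        p = extract_patch(data, (0, 0, 0), 2)
        out = gap_channels(p)
        for ch, (lo_p, hi_p) in enumerate(GAP_WINDOWS, start=1):
            lo, hi = np.percentile(vals, [lo_p, hi_p])
            expected = (np.clip(data, lo, hi) - lo) / (hi - lo)
            assert np.allclose(out.data[ch], expected, atol=1e-6)

    def test_monotone_within_window(self):
        rng = np.random.default_rng(3)
        data = rng.random((64, 64, 64)).astype(np.float32)
        out = gap_channels(extract_patch(data, (0, 0, 0)))
        flat_in = data.ravel()
        order = np.argsort(flat_in)
        for ch in range(1, 4):
            sorted_ch = out.data[ch].ravel()[order]
            assert np.all(np.diff(sorted_ch) >= -1e-6)

    def test_window_idempotent(self):
        """Reapplying a window to an already-windowed channel is identity."""
        rng = np.random.default_rng(4)
        data = rng.random((64, 64, 64)).astype(np.float32)
        once = gap_channels(extract_patch(data, (0, 0, 0)))
        for ch in range(1, 4):
            w = once.data[ch]
            lo, hi = w.min(), w.max()
            again = (np.clip(w, lo, hi) - lo) / (hi - lo)
            assert np.allclose(again, (w - lo) / (hi - lo), atol=1e-6)

    def test_rejects_multichannel(self):
        p = Patch(np.zeros((4, 64, 64, 64), np.float32), (0, 0, 0), (64, 64, 64))
        with pytest.raises(ValueError):
            gap_channels(p)


class TestRelativePosition:
    def test_centered(self):
        pos = relative_position((32, 32, 32), 64, (128, 128, 128))
        assert pos.rel == pytest.approx((0.5, 0.5, 0.5))

    def test_corner_closed_form(self):
        pos = relative_position((0, 0, 0), 64, (128, 128, 128))
        assert pos.rel == pytest.approx((31.5 / 127,) * 3)

    def test_far_corner_bounded(self):
        pos = relative_position((64, 64, 64), 64, (128, 128, 128))
        assert all(r <= 1.0 for r in pos.rel)

    def test_degenerate_axis(self):
        pos = relative_position((0, 0, 0), 64, (1, 128, 128))
        assert pos.rel[0] == 0.5


class TestSoftenTarget:
    def test_empty_mask(self):
        out = soften_fracture_target(np.zeros((10, 10, 10), np.uint8))
        assert np.all(out == 0.0)

    def test_single_voxel_radius1_ball(self):
        mask = np.zeros((7, 7, 7), np.uint8)
        mask[3, 3, 3] = 1
        out = soften_fracture_target(mask, dilation_radius_vox=1, sigma_vox=0)
        # radius-1 ball = centre + 6 face neighbours
        assert (out == 1.0).sum() == 7

    def test_dilation_grows_and_bounded(self):
        rng = np.random.default_rng(5)
        mask = (rng.random((20, 20, 20)) > 0.97).astype(np.uint8)
        out = soften_fracture_target(mask, 1, 0.5)
        assert (out > 0).sum() >= mask.sum()
        assert out.max() == pytest.approx(1.0)
        assert out.min() >= 0.0


class TestBalancedSampling:
    def test_exact_allocation(self, fractured_phantom):
        _, vol, _, frac, _ = fractured_phantom
        soft = soften_fracture_target(frac.data)
        pairs = sample_balanced_patches(vol.data, soft, 8, seed=0, patch_size=32)
        positives = sum(t.data.sum() > 0 for _, t in pairs)
        assert len(pairs) == 8 and positives == 4

    def test_seed_determinism(self, fractured_phantom):
        _, vol, _, frac, _ = fractured_phantom
        soft = soften_fracture_target(frac.data)
        a = sample_balanced_patches(vol.data, soft, 6, seed=3, patch_size=32)
        b = sample_balanced_patches(vol.data, soft, 6, seed=3, patch_size=32)
        assert [p.origin for p, _ in a] == [p.origin for p, _ in b]

    def test_no_positives_warns(self):
        vol = np.zeros((40, 40, 40), np.float32)
        with pytest.warns(UserWarning):
            pairs = sample_balanced_patches(vol, np.zeros_like(vol), 4,
                                            seed=0, patch_size=32)
        assert all(t.data.sum() == 0 for _, t in pairs)

    def test_odd_n_rejected(self):
        vol = np.zeros((40, 40, 40), np.float32)
        with pytest.raises(ValueError):
            sample_balanced_patches(vol, vol, 5, seed=0, patch_size=32)
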