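import numpy as np
import pytest

from mandfrac.inference import (FractureProposal, PipelineConfig,
                                crop_to_mandible, extract_proposals,
                                filter_by_confidence, run_pipeline,
                                unite_proposals, _interpolate_patch_lattice,
                                _overlap_average)
from mandfrac.patching import patch_grid
from mandfrac.smallscale import oracle_stage_fns
from mandfrac.volume_io import Volume


def _prop(voxels, conf, source="stage2"):
    return FractureProposal(np.asarray(voxels), source, conf, len(voxels))


class TestOverlapAveraging:
    def test_constant_tiles_any_stride(self):
        """A constant per-patch output stays constant after averaging."""
        shape = (70, 50, 40)
        for stride in (16, 24, 32):
            origins = patch_grid(shape, 32, stride)
            tiles = [np.full((32, 32, 32), 0.7, np.float32) for _ in origins]
            out = _overlap_average(shape, origins, 32, tiles)
            assert np.allclose(out, 0.7)

    def test_full_coverage(self):
        shape = (45, 33, 61)
        origins = patch_grid(shape, 32, 16)
        tiles = [np.ones((32, 32, 32), np.float32) for _ in origins]
        out = _overlap_average(shape, origins, 32, tiles)
        assert np.all(out == 1.0)


class TestCrop:
    def test_full_mask_identity(self):
        vol = np.random.default_rng(0).random((20, 20, 20)).astype(np.float32)
        cropped, offset, _ = crop_to_mandible(vol, np.ones_like(vol), 0.5, 10)
        assert cropped.shape == vol.shape and offset == (0, 0, 0)

    def test_single_voxel_margin(self):
        vol = np.zeros((32, 32, 32), np.float32)
        prob = np.zeros_like(vol)
        prob[10, 10, 10] = 1.0
        cropped, offset, sl = crop_to_mandible(vol, prob, 0.5, 5)
        assert offset == (5, 5, 5)
        assert cropped.shape == (11, 11, 11)

    def test_empty_map_warns_full_volume(self):
        vol = np.zeros((16, 16, 16), np.float32)
        with pytest.warns(UserWarning):
            cropped, offset, _ = crop_to_mandible(vol, np.zeros_like(vol))
        assert cropped.shape == vol.shape and offset == (0, 0, 0)


class TestClsInterpolation:
    def test_constant_lattice(self):
        ax = [[0, 16, 32], [0, 16, 32], [0, 16, 32]]
        vals = np.full((3, 3, 3), 0.4, np.float32)
        out = _interpolate_patch_lattice((64, 64, 64), ax, vals, 32)
        assert np.allclose(out, 0.4, atol=1e-6)

    def test_single_patch_constant(self):
        out = _interpolate_patch_lattice((32, 32, 32), [[0], [0], [0]],
                                         np.full((1, 1, 1), 0.9, np.float32), 32)
        assert np.allclose(out, 0.9, atol=1e-6)

    def test_linear_midpoint(self):
        ax = [[0, 32], [0], [0]]
        vals = np.array([[[0.0]], [[1.0]]], np.float32)
        out = _interpolate_patch_lattice((64, 32, 32), ax, vals, 32)
        # centres at x=15.5 and 47.5; midpoint x=31.5 -> 0.5
        mid = 0.5 * (out[31, 0, 0] + out[32, 0, 0])
        assert mid == pytest.approx(0.5, abs=1e-3)
        assert out[0, 0, 0] == pytest.approx(0.0, abs=1e-6)   # clamped edge
        assert out[-1, 0, 0] == pytest.approx(1.0, abs=1e-6)


class TestExtractProposals:
    def test_empty_map(self):
        assert extract_proposals(np.zeros((10, 10, 10), np.float32), 0.5, 3,
                                 1, np.zeros((10, 10, 10)), "stage2") == []

    def test_two_blobs_labeled_separately(self):
        m = np.zeros((20, 20, 20), np.float32)
        m[2:7, 2, 2] = 1.0
        m[12:17, 12, 12] = 1.0
        props = extract_proposals(m, 0.5, 3, 1, m, "stage2")
        assert len(props) == 2
        assert sorted(p.size for p in props) == [5, 5]
        assert all(p.confidence == 1.0 for p in props)

    def test_min_size_boundary(self):
        m = np.zeros((10, 10, 10), np.float32)
        m[0, 0, 0:4] = 1.0
        assert extract_proposals(m, 0.5, 3, 5, m, "s") == []
        assert len(extract_proposals(m, 0.5, 3, 4, m, "s")) == 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        m = rng.random((24, 24, 24)).astype(np.float32)
        lo = extract_proposals(m, 0.3, 3, 1, m, "s")
        hi = extract_proposals(m, 0.7, 3, 1, m, "s")
        assert sum(p.size for p in hi) <= sum(p.size for p in lo)


class TestUnite:
    def test_disjoint_concatenation(self):
        a = [_prop([[0, 0, 0], [0, 0, 1]], 0.9)]
        b = [_prop([[5, 5, 5]], 0.4, "stage3")]
        out = unite_proposals(a, b)
        assert len(out) == 2
        assert sorted(p.size for p in out) == [1, 2]

    def test_identical_idempotent(self):
        a = [_prop([[1, 1, 1]], 0.8)]
        b = [_prop([[1, 1, 1]], 0.6, "stage3")]
        out = unite_proposals(a, b)
        assert len(out) == 1
        assert out[0].size == 1
        assert out[0].source == "merged"
        assert out[0].confidence == 0.8

    def test_transitive_chain(self):
        """A∩B and B∩C nonempty (A∩C empty) collapse to one proposal."""
        A = _prop([[0, 0, 0], [0, 0, 1]], 0.9)
        B = _prop([[0, 0, 1], [0, 0, 2]], 0.5, "stage3")
        C = _prop([[0, 0, 2], [0, 0, 3]], 0.7)
        out = unite_proposals([A, C], [B])
        assert len(out) == 1
        assert out[0].size == 4
        assert out[0].confidence == 0.9


class TestFilter:
    def test_tau_zero_identity(self):
        props = [_prop([[0, 0, 0]], c) for c in (0.2, 0.6, 0.9)]
        assert filter_by_confidence(props, 0.0) == props

    def test_mixed_confidences(self):
        props = [_prop([[0, 0, 0]], c) for c in (0.9, 0.6, 0.2)]
        kept = filter_by_confidence(props, 0.5)
        assert [p.confidence for p in kept] == [0.9, 0.6]

    def test_monotone_in_tau(self):
        props = [_prop([[0, 0, 0]], c) for c in (0.1, 0.5, 0.8)]
        counts = [len(filter_by_confidence(props, t))
                  for t in (0.0, 0.3, 0.6, 0.9, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            filter_by_confidence([], 1.5)


class TestPipelineWithOracles:
    CFG = PipelineConfig(patch_size=32, stride=16)

    def test_null_case(self, small_scans):
        scan = next(s for s in small_scans if not s.fracture.any())
        mfn, ffn = oracle_stage_fns(scan.mandible, scan.fracture)
        res = run_pipeline(Volume(scan.volume), config=self.CFG,
                           mandible_fn=mfn, fracture_fn=ffn)
        assert res.proposals == []

    def test_exact_recovery_and_bounds(self, fractured_phantom):
        _, vol, mand, frac, records = fractured_phantom
        mfn, ffn = oracle_stage_fns(mand.data, frac.data)
        res = run_pipeline(Volume(vol.data), config=self.CFG,
                           mandible_fn=mfn, fracture_fn=ffn)
        assert len(res.proposals) == len(records)
        for p in res.proposals:
            assert np.all(p.voxels >= 0)
            assert np.all(p.voxels < np.array(vol.data.shape))

    def test_coordinate_roundtrip(self, fractured_phantom):
        """Proposal voxels map back to supra-threshold cropped probabilities."""
        _, vol, mand, frac, _ = fractured_phantom
        mfn, ffn = oracle_stage_fns(mand.data, frac.data)
        res = run_pipeline(Volume(vol.data), config=self.CFG,
                           mandible_fn=mfn, fracture_fn=ffn)
        either = np.maximum(res.seg_map, res.cls_map)
        for p in res.proposals:
            vals = either[tuple(p.voxels.T)]
            assert np.all(vals >= 0.5)
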