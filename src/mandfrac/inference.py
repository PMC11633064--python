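"""Scan-level inference: tiling, map fusion, proposal extraction and union.

The pipeline mirrors the training cascade. Stage 1 tiles the scan and
overlap-averages sigmoid mandible logits into a probability map; the scan is
cropped to the predicted mandible; stage 2 produces an overlap-averaged
fracture segmentation map; stage 3 produces one probability per patch,
interpolated trilinearly over the lattice of patch centres to cover every
voxel. Connected-component analysis turns both maps into fracture
proposals; proposals from the two stages whose voxel sets overlap are
united, and low-confidence proposals (mean stage-2 segmentation probability)
are excluded.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from . import patching
from .nn.autograd import Tensor
from .training import gap_batch, stage1_context
from .volume_io import Volume


@dataclasses.dataclass
class PipelineConfig:
    patch_size: int = 64
    stride: int = 32
    mandible_threshold: float = 0.5
    crop_margin_vox: int = 10
    seg_threshold: float = 0.5
    cls_threshold: float = 0.5
    min_size_vox: int = 10
    confidence_tau: float = 0.5
    connectivity: int = 3          # scipy structure rank: 3 -> 26-connectivity
    mandible_gate_dilation: int = 3
    batch_patches: int = 4


@dataclasses.dataclass
class FractureProposal:
    """A connected voxel set hypothesized to be one fracture."""

    voxels: np.ndarray          # (k, 3) voxel indices in scan space
    source: str                 # "stage2" | "stage3" | "merged"
    confidence: float           # mean stage-2 probability over voxels
    size: int

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.int64)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3 or len(self.voxels) == 0:
            raise ValueError("voxels must be a nonempty (k, 3) index array")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence outside [0,1]: {self.confidence}")
        self.size = len(self.voxels)

    def shifted(self, offset: Sequence[int]) -> "FractureProposal":
        return FractureProposal(self.voxels + np.asarray(offset, dtype=np.int64),
                                self.source, self.confidence, self.size)

    def centroid(self) -> np.ndarray:
        return self.voxels.mean(axis=0)


def _axis_origins(shape, patch_size, stride):
    out = []
    for dim in shape:
        last = max(dim - patch_size, 0)
        out.append(sorted(set(list(range(0, last + 1, stride)) + [last])))
    return out


def _overlap_average(shape, origins, patch_size, tiles):
    """Place per-tile value grids back, averaging overlapping contributions."""
    acc = np.zeros(shape, dtype=np.float32)
    cnt = np.zeros(shape, dtype=np.float32)
    for origin, tile in zip(origins, tiles):
        valid = tuple(min(patch_size, s - o) for o, s in zip(origin, shape))
        sl = tuple(slice(o, o + v) for o, v in zip(origin, valid))
        acc[sl] += tile[: valid[0], : valid[1], : valid[2]]
        cnt[sl] += 1.0
    return acc / np.maximum(cnt, 1.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def segment_mandible(volume: np.ndarray, s1, config: PipelineConfig) -> np.ndarray:
    """Tile the scan through stage 1 and overlap-average mandible probability."""
    s1.eval()
    origins = patching.patch_grid(volume.shape, config.patch_size, config.stride)
    tiles = []
    for start in range(0, len(origins), config.batch_patches):
        chunk = origins[start:start + config.batch_patches]
        patches = [patching.extract_patch(volume, o, config.patch_size) for o in chunk]
        out = s1(Tensor(gap_batch(patches)))
        tiles.extend(_sigmoid(out.mandible_logits.data[:, 0]))
    return _overlap_average(volume.shape, origins, config.patch_size, tiles)


def crop_to_mandible(volume: np.ndarray, mandible_prob: np.ndarray,
                     threshold: float = 0.5, margin_vox: int = 10):
    """Bounding-box crop around the thresholded mandible probability.

    Returns (cropped array, offset, slices). An empty segmentation keeps the
    full volume and warns.
    """
    fg = mandible_prob >= threshold
    if not fg.any():
        warnings.warn("empty mandible segmentation; keeping full volume")
        sl = tuple(slice(0, s) for s in volume.shape)
        return volume, (0, 0, 0), sl
    idx = np.argwhere(fg)
    lo = np.maximum(idx.min(axis=0) - margin_vox, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin_vox, volume.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return volume[sl], tuple(int(a) for a in lo), sl


def fracture_maps(cropped: np.ndarray, s1, s2, s3, config: PipelineConfig):
    """Voxel-level fracture maps from stages 2 and 3 over the cropped scan.

    seg_map: overlap-averaged sigmoid of the second cascade network's logits.
    cls_map: per-patch stage-3 probabilities carried by the patch centres and
    trilinearly interpolated to all voxels, nearest-lattice at the borders.
    """
    s1.eval(); s2.eval(); s3.eval()
    shape = cropped.shape
    ax_origins = _axis_origins(shape, config.patch_size, config.stride)
    origins = sorted(itertools.product(*ax_origins))
    seg_tiles = []
    cls_vals = np.zeros([len(a) for a in ax_origins], dtype=np.float32)
    ax_index = [{o: i for i, o in enumerate(a)} for a in ax_origins]

    for start in range(0, len(origins), config.batch_patches):
        chunk = origins[start:start + config.batch_patches]
        patches = [patching.extract_patch(cropped, o, config.patch_size)
                   for o in chunk]
        ctx2 = stage1_context(s1, patches)
        _, logits_b = s2(Tensor(ctx2))
        seg_tiles.extend(_sigmoid(logits_b.data[:, 0]))
        ctx3 = np.concatenate([ctx2, logits_b.data], axis=1)
        cls_logit = s3(Tensor(ctx3))
        for o, lgt in zip(chunk, cls_logit.data[:, 0]):
            cls_vals[ax_index[0][o[0]], ax_index[1][o[1]], ax_index[2][o[2]]] = \
                _sigmoid(lgt)

    seg_map = _overlap_average(shape, origins, config.patch_size, seg_tiles)
    cls_map = _interpolate_patch_lattice(shape, ax_origins, cls_vals,
                                         config.patch_size)
    return seg_map, cls_map


def _interpolate_patch_lattice(shape, ax_origins, values, patch_size):
    centers = [np.asarray(a, dtype=np.float32) + (patch_size - 1) / 2.0
               for a in ax_origins]
    # degenerate axes (single patch): constant along that axis
    interp_axes = [c if len(c) > 1 else np.array([0.0, 1.0], dtype=np.float32)
                   for c in centers]
    vals = values
    for ax, c in enumerate(centers):
        if len(c) == 1:
            vals = np.repeat(vals, 2, axis=ax)
    f = RegularGridInterpolator(interp_axes, vals, method="linear")
    coords = np.meshgrid(*[np.arange(s, dtype=np.float32) for s in shape],
                         indexing="ij")
    pts = np.stack([np.clip(c, a[0], a[-1]) for c, a in zip(coords, interp_axes)],
                   axis=-1)
    return np.clip(f(pts).astype(np.float32), 0.0, 1.0)


def extract_proposals(prob_map: np.ndarray, threshold: float,
                      connectivity: int, min_size_vox: int,
                      confidence_source: np.ndarray,
                      source: str) -> List[FractureProposal]:
    """Connected components of the thresholded map, scored and size-filtered."""
    binary = prob_map >= threshold
    if not binary.any():
        return []
    structure = ndimage.generate_binary_structure(3, connectivity)
    labels, n = ndimage.label(binary, structure)
    props = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) < min_size_vox:
            continue
        conf = float(confidence_source[tuple(vox.T)].mean())
        props.append(FractureProposal(vox, source, min(conf, 1.0), len(vox)))
    return sorted(props, key=lambda p: -p.confidence)


def unite_proposals(p2: Sequence[FractureProposal],
                    p3: Sequence[FractureProposal]) -> List[FractureProposal]:
    """Merge proposals whose voxel sets overlap (transitively).

    A merged proposal is the voxel union with source "merged" and the
    maximum parent confidence; non-overlapping proposals pass through.
    """
    all_props = list(p2) + list(p3)
    if not all_props:
        return []
    sets = [set(map(tuple, p.voxels)) for p in all_props]
    parent = list(range(len(all_props)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(all_props)):
        for j in range(i + 1, len(all_props)):
            if sets[i] & sets[j]:
                parent[find(i)] = find(j)

    groups = {}
    for i in range(len(all_props)):
        groups.setdefault(find(i), []).append(i)

    out = []
    for members in groups.values():
        if len(members) == 1:
            out.append(all_props[members[0]])
        else:
            vox = np.array(sorted(set().union(*(sets[m] for m in members))))
            conf = max(all_props[m].confidence for m in members)
            out.append(FractureProposal(vox, "merged", conf, len(vox)))
    return sorted(out, key=lambda p: -p.confidence)


def filter_by_confidence(props: Sequence[FractureProposal],
                         tau: float) -> List[FractureProposal]:
    """Keep proposals with confidence ≥ tau, order preserved."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau outside [0,1]: {tau}")
    return [p for p in props if p.confidence >= tau]


@dataclasses.dataclass
class PipelineResult:
    proposals: List[FractureProposal]   # in original scan coordinates
    mandible_map: np.ndarray
    seg_map: np.ndarray                 # full scan space, zero outside crop
    cls_map: np.ndarray
    crop_offset: Tuple[int, int, int]


def run_pipeline(volume: Volume, s1=None, s2=None, s3=None,
                 config: Optional[PipelineConfig] = None,
                 mandible_fn: Optional[Callable] = None,
                 fracture_fn: Optional[Callable] = None) -> PipelineResult:
    """Full scan-level pipeline on a normalized volume.

    ``mandible_fn(data) -> prob array`` and
    ``fracture_fn(cropped_data, offset) -> (seg_map, cls_map)`` override the
    learned stages — used to substitute ground-truth oracles when testing
    the surrounding proposal logic in isolation.
    """
    config = config or PipelineConfig()
    data = np.asarray(volume.data, dtype=np.float32)
    if mandible_fn is not None:
        mandible = np.asarray(mandible_fn(data), dtype=np.float32)
    else:
        mandible = segment_mandible(data, s1, config)

    cropped, offset, sl = crop_to_mandible(data, mandible,
                                           config.mandible_threshold,
                                           config.crop_margin_vox)
    if fracture_fn is not None:
        seg_c, cls_c = fracture_fn(cropped, offset)
    else:
        seg_c, cls_c = fracture_maps(cropped, s1, s2, s3, config)

    # stage-3 evidence outside the (dilated) predicted mandible is discarded
    gate = mandible[sl] >= config.mandible_threshold
    if gate.any() and config.mandible_gate_dilation > 0:
        gate = ndimage.binary_dilation(
            gate, ndimage.generate_binary_structure(3, 3),
            iterations=config.mandible_gate_dilation)
    cls_c = np.where(gate, cls_c, 0.0).astype(np.float32)

    p2 = extract_proposals(seg_c, config.seg_threshold, config.connectivity,
                           config.min_size_vox, seg_c, "stage2")
    p3 = extract_proposals(cls_c, config.cls_threshold, config.connectivity,
                           config.min_size_vox, seg_c, "stage3")
    merged = unite_proposals(p2, p3)
    final = filter_by_confidence(merged, config.confidence_tau)
    final = [p.shifted(offset) for p in final]

    seg_full = np.zeros(data.shape, dtype=np.float32)
    cls_full = np.zeros(data.shape, dtype=np.float32)
    seg_full[sl] = seg_c
    cls_full[sl] = cls_c
    return PipelineResult(final, mandible, seg_full, cls_full, offset)
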