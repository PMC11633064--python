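"""Patch extraction, adaptive grayscale channels and training targets.

The networks consume fixed-size cubic patches (64³ by default, 32³ in the
scaled-down configuration). This module handles inference tiling, the
grayscale adaptive-perception channels, patch-position targets, softened
fracture targets, and class-balanced patch sampling for training.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

# per-patch percentile windows: soft tissue, cancellous bone, cortical bone
GAP_WINDOWS: Tuple[Tuple[float, float], ...] = ((0, 40), (30, 70), (60, 100))


@dataclasses.dataclass
class Patch:
    """A C×s×s×s sub-grid with its origin in the parent volume.

    ``valid_extent`` counts non-padded voxels per axis; everything beyond it
    is zero padding inserted where the parent grid ends.
    """

    data: np.ndarray  # (C, s, s, s)
    origin: Tuple[int, int, int]
    valid_extent: Tuple[int, int, int]

    @property
    def size(self) -> int:
        return self.data.shape[1]

    @property
    def channels(self) -> int:
        return self.data.shape[0]


@dataclasses.dataclass
class PatchPosition:
    """Relative position of a patch centre inside its parent grid, in [0,1]³."""

    rel: Tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(not (0.0 <= r <= 1.0) for r in self.rel):
            raise ValueError(f"relative position outside [0,1]: {self.rel}")


def patch_grid(shape: Sequence[int], patch_size: int = 64,
               stride: int = 32) -> List[Tuple[int, int, int]]:
    """Tiling origins covering every voxel of ``shape``.

    Origins step by ``stride`` per axis; the last origin per axis is clamped
    to ``max(dim - patch_size, 0)`` so the final patch ends at the boundary.
    Sorted lexicographically, deduplicated.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    per_axis = []
    for dim in shape:
        last = max(dim - patch_size, 0)
        ax = sorted(set(list(range(0, last + 1, stride)) + [last]))
        per_axis.append(ax)
    return sorted(itertools.product(*per_axis))


def extract_patch(data: np.ndarray, origin: Sequence[int],
                  patch_size: int = 64) -> Patch:
    """Cut a cubic patch, zero-padding where the parent grid ends."""
    origin = tuple(int(o) for o in origin)
    shape = data.shape
    if any(o < 0 or o >= s for o, s in zip(origin, shape)):
        raise ValueError(f"origin {origin} outside grid {shape}")
    valid = tuple(min(patch_size, s - o) for o, s in zip(origin, shape))
    out = np.zeros((1, patch_size, patch_size, patch_size), dtype=np.float32)
    sl = tuple(slice(o, o + v) for o, v in zip(origin, valid))
    out[0, : valid[0], : valid[1], : valid[2]] = data[sl]
    return Patch(out, origin, valid)


def gap_channels(p: Patch, windows=GAP_WINDOWS) -> Patch:
    """Append three adaptive intensity windows as extra channels.

    Each window clips the patch to a per-patch percentile interval of the
    valid (non-padded) voxels and rescales it to [0, 1], emphasising soft
    tissue, cancellous bone and cortical bone in turn. A constant patch (or a
    collapsed window) yields an all-zero channel.
    """
    if p.channels != 1:
        raise ValueError(f"expected a single-channel patch, got C={p.channels}")
    base = p.data[0]
    valid = base[: p.valid_extent[0], : p.valid_extent[1], : p.valid_extent[2]]
    chans = [base]
    for lo_pct, hi_pct in windows:
        lo, hi = np.percentile(valid, [lo_pct, hi_pct])
        if hi <= lo:
            chans.append(np.zeros_like(base))
        else:
            w = (np.clip(base, lo, hi) - lo) / (hi - lo)
            chans.append(w.astype(np.float32))
    return Patch(np.stack(chans).astype(np.float32), p.origin, p.valid_extent)


def relative_position(origin: Sequence[int], patch_size: int,
                      parent_shape: Sequence[int]) -> PatchPosition:
    """Patch-centre index divided by (parent dim − 1), per axis, in [0, 1].

    Degenerate axes of size 1 map to 0.5.
    """
    rel = []
    for o, n in zip(origin, parent_shape):
        if n <= 1:
            rel.append(0.5)
        else:
            c = o + (patch_size - 1) / 2.0
            rel.append(float(np.clip(c / (n - 1), 0.0, 1.0)))
    return PatchPosition(tuple(rel))


def soften_fracture_target(mask: np.ndarray, dilation_radius_vox: int = 1,
                           sigma_vox: float = 0.5) -> np.ndarray:
    """Dilate then Gaussian-blur a binary fracture mask into a soft target.

    Thin fracture planes give few positive voxels; morphological dilation
    (ball structuring element) followed by Gaussian filtering increases their
    number and softens the boundary. The result is peak-renormalized to a
    maximum of 1 for nonempty input; an empty mask stays all-zero.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return np.zeros(m.shape, dtype=np.float32)
    if dilation_radius_vox > 0:
        struct = _ball(dilation_radius_vox)
        m = ndimage.binary_dilation(m, structure=struct)
    out = m.astype(np.float32)
    if sigma_vox > 0:
        out = ndimage.gaussian_filter(out, sigma_vox)
    peak = out.max()
    if peak > 0:
        out = out / peak
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return x * x + y * y + z * z <= r * r


def sample_balanced_patches(volume: np.ndarray, fracture_target: np.ndarray,
                            n: int, seed: int, patch_size: int = 64,
                            jitter: int | None = None):
    """Draw n/2 fracture-positive and n/2 fracture-free training patches.

    Positive patches are centred on a uniformly drawn positive target voxel
    with random jitter; negative patches are random origins whose target crop
    is all-zero. Deterministic under ``seed``. If the volume has no positive
    voxel the sample is all-negative (with a warning); if no all-negative
    location exists the sample is positive-only (with a warning).
    """
    if n % 2:
        raise ValueError("n must be even")
    rng = np.random.default_rng(seed)
    shape = volume.shape
    if jitter is None:
        jitter = patch_size // 4
    pos_idx = np.argwhere(fracture_target > 0)
    pairs = []

    def origin_for_center(center):
        o = [int(np.clip(c - patch_size // 2 + rng.integers(-jitter, jitter + 1),
                         0, max(s - patch_size, 0)))
             for c, s in zip(center, shape)]
        return tuple(o)

    n_pos = n // 2
    if len(pos_idx) == 0:
        warnings.warn("no positive voxels; returning all-negative sample")
        n_pos = 0
    for _ in range(n_pos):
        center = pos_idx[rng.integers(len(pos_idx))]
        for _try in range(20):
            o = origin_for_center(center)
            tgt = extract_patch(fracture_target, o, patch_size)
            if tgt.data.sum() > 0:
                break
        pairs.append((extract_patch(volume, o, patch_size), tgt))

    n_neg = n - len(pairs)
    made_neg = 0
    for _ in range(n_neg):
        ok = False
        for _try in range(200):
            o = tuple(int(rng.integers(0, max(s - patch_size, 0) + 1)) for s in shape)
            tgt = extract_patch(fracture_target, o, patch_size)
            if tgt.data.sum() == 0:
                ok = True
                break
        if not ok:
            warnings.warn("no all-negative patch location found; sample is positive-heavy")
            break
        made_neg += 1
        pairs.append((extract_patch(volume, o, patch_size), tgt))
    return pairs
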