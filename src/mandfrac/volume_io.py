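"""Reading, writing, resampling and normalising CBCT volumes.

All grids are plain ``numpy`` arrays indexed ``(x, y, z)`` with 0-based voxel
indices, matching the on-disk NIfTI data array order. A :class:`Volume`
carries voxel spacing (mm) and origin (mm); label masks and probability maps
share the same index space as their parent volume.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclasses.dataclass
class Volume:
    """A 3D scalar grid with voxel spacing and origin in mm.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Finite real intensities.
    spacing : tuple of float
        Voxel edge lengths (sx, sy, sz) in mm, all strictly positive.
    origin : tuple of float
        World coordinate of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if any(d < 1 for d in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def like(self, data: np.ndarray) -> "Volume":
        """New Volume over the same grid geometry with different data."""
        return Volume(data, self.spacing, self.origin)


class LabelMask(Volume):
    """Voxel-aligned integer label grid (0 = background)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.array_equal(rounded, self.data):
                raise ValueError("label mask contains non-integer values")
            self.data = rounded.astype(np.uint8)
        if self.data.min() < 0:
            raise ValueError("label mask contains negative labels")

    def like(self, data: np.ndarray) -> "LabelMask":
        return LabelMask(data, self.spacing, self.origin)


class ProbabilityMap(Volume):
    """Voxel-aligned grid of probabilities in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data, dtype=np.float32)
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"probabilities outside [0,1]: min={lo}, max={hi}")
        np.clip(self.data, 0.0, 1.0, out=self.data)

    def like(self, data: np.ndarray) -> "ProbabilityMap":
        return ProbabilityMap(data, self.spacing, self.origin)


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path, kind: str = "volume"):
    """Read a 3D NIfTI file.

    Parameters
    ----------
    path : str or Path
        Existing ``.nii`` / ``.nii.gz`` file with a 3D payload.
    kind : {"volume", "mask", "prob"}
        Container class of the result.

    Raises
    ------
    FileNotFoundError, ValueError
        Missing file; non-3D payload; non-positive or absent voxel spacing
        (scans with unknown spacing are rejected rather than guessed at).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D payload, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive or absent voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if kind == "mask":
        return LabelMask(data.astype(np.uint8), tuple(map(float, zooms)), origin)
    if kind == "prob":
        return ProbabilityMap(data.astype(np.float32), tuple(map(float, zooms)), origin)
    data = np.asarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite intensities")
    return Volume(data, tuple(map(float, zooms)), origin)


def write_volume(v: Volume, path) -> None:
    """Write a grid to NIfTI; masks as uint8, everything else as float32."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise IOError(f"directory does not exist: {parent}")
    if isinstance(v, LabelMask):
        data = v.data.astype(np.uint8)
    else:
        data = v.data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine_from(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def resample_isotropic(v: Volume, target_spacing_mm: float, order: int | None = None):
    """Resample to an isotropic grid of the given spacing.

    Output dimension per axis is ``round(dim * spacing / target)`` (minimum 1).
    Label masks use nearest-neighbour, intensities trilinear, unless ``order``
    overrides.
    """
    t = float(target_spacing_mm)
    if t <= 0:
        raise ValueError(f"target spacing must be positive, got {t}")
    if order is None:
        order = 0 if isinstance(v, LabelMask) else 1
    out_shape = tuple(
        max(1, int(round(d * s / t))) for d, s in zip(v.shape, v.spacing)
    )
    if out_shape == v.shape and all(abs(s - t) < 1e-12 for s in v.spacing):
        out = v.data.copy()
    else:
        zoom = [o / d for o, d in zip(out_shape, v.shape)]
        out = ndimage.zoom(np.asarray(v.data, dtype=np.float32), zoom,
                           order=order, mode="nearest", grid_mode=True)
        out = out[: out_shape[0], : out_shape[1], : out_shape[2]]
    cls = type(v)
    if isinstance(v, LabelMask):
        out = np.rint(out).astype(np.uint8)
    return cls(out, (t, t, t), v.origin)


def normalize_intensities(v: Volume, low_pct: float = 0.5, high_pct: float = 99.5) -> Volume:
    """Percentile-clip then rescale intensities to [0, 1].

    CBCT has no calibrated HU scale, so a robust per-volume window is taken:
    intensities are clipped to the [low_pct, high_pct] percentile interval and
    affinely mapped to [0, 1]. A constant volume maps to all zeros.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(f"need 0 <= low < high <= 100, got ({low_pct}, {high_pct})")
    data = np.asarray(v.data, dtype=np.float32)
    lo, hi = np.percentile(data, [low_pct, high_pct])
    if hi <= lo:
        return v.like(np.zeros_like(data))
    out = np.clip(data, lo, hi)
    out = (out - lo) / (hi - lo)
    return v.like(out.astype(np.float32))
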