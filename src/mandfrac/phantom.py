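"""Synthetic mandible phantoms with planted fractures and exact ground truth.

The phantom is a half-torus ("horseshoe") bone embedded in soft tissue: a
bright cortical shell around a dimmer cancellous interior on a dark
background, plus additive Gaussian noise. Zero or more fracture planes are
planted, of two kinds mirroring the clinical taxonomy:

* nondisplaced — a thin low-intensity plane crossing the bone, the bone
  itself staying in place;
* displaced — all bone on one side of the plane rigidly translated along the
  plane normal, leaving a gap; the ground truth is the 1-voxel interface band
  on both cut surfaces.

Every phantom ships with exact mandible and fracture label masks and a
per-fracture record, so detection pipelines can be scored without clinical
data. Identical spec + seed gives a bit-identical phantom.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import LabelMask, Volume, write_volume

NONDISPLACED = "nondisplaced"
DISPLACED = "displaced"


@dataclasses.dataclass
class PhantomSpec:
    """Geometry, contrast and fracture parameters of one phantom.

    Intensities are means on the normalized [0, 1] scale and must be ordered
    background < cancellous < cortical.
    """

    shape: Tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 0.4
    arch_radius_mm: float = 12.0
    bone_radius_mm: float = 4.0
    cortical_thickness_mm: float = 1.2
    cortical_intensity: float = 0.9
    cancellous_intensity: float = 0.5
    background_intensity: float = 0.15
    noise_sd: float = 0.03
    n_fractures: int = 1
    displaced_fraction: float = 0.3
    displacement_mm: float = 2.4
    plane_thickness_mm: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.background_intensity < self.cancellous_intensity
                < self.cortical_intensity):
            raise ValueError("intensities must be ordered background < cancellous < cortical")
        if self.plane_thickness_mm <= 0 or self.displacement_mm <= 0:
            raise ValueError("plane_thickness_mm and displacement_mm must be positive")
        if not (0 <= self.n_fractures <= 3):
            raise ValueError("n_fractures must be in 0..3")

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class FractureRecord:
    """Provenance of one planted fracture."""

    index: int
    kind: str  # NONDISPLACED | DISPLACED
    plane_point_mm: Tuple[float, float, float]
    plane_normal: Tuple[float, float, float]
    gt_voxel_count: int

    def __post_init__(self) -> None:
        n = np.asarray(self.plane_normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-6:
            raise ValueError("plane normal must have unit length")
        if self.gt_voxel_count < 1:
            raise ValueError("a planted fracture must cover >= 1 voxel")


def _grid_mm(shape: Sequence[int], spacing: float):
    """World (mm) coordinate arrays of every voxel centre, origin at volume centre."""
    axes = [(np.arange(n, dtype=np.float32) - (n - 1) / 2.0) * spacing for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _torus_distance(x, y, z, arch_radius):
    """Distance from the torus centreline circle lying in the z=0 plane."""
    radial = np.sqrt(x * x + y * y) - arch_radius
    return np.sqrt(radial * radial + z * z)


def _half_torus_masks(spec: PhantomSpec):
    """Boolean solid, cortical shell and cancellous interior of the horseshoe."""
    x, y, z = _grid_mm(spec.shape, spec.spacing_mm)
    d = _torus_distance(x, y, z, spec.arch_radius_mm)
    # horseshoe: keep the anterior half-arch plus a small posterior overshoot
    half = y >= -0.25 * spec.arch_radius_mm
    solid = (d <= spec.bone_radius_mm) & half
    interior = (d <= spec.bone_radius_mm - spec.cortical_thickness_mm) & half
    return solid, solid & ~interior, interior, (x, y, z)


def _sample_fracture_plane(rng: np.random.Generator, spec: PhantomSpec,
                           used_thetas=()):
    """A plane crossing the bone tube, roughly transverse to the arch.

    Planes are kept at least 0.3π of arch angle apart so distinct fractures
    stay spatially separated in the ground truth (a displaced segment shift
    can move a cut surface ~0.1π along the arch). Returns None when no
    sufficiently separated position can be drawn.
    """
    for _ in range(100):
        theta = rng.uniform(0.1 * np.pi, 0.9 * np.pi)  # position along the arch
        if all(abs(theta - t) >= 0.3 * np.pi for t in used_thetas):
            break
    else:
        return None
    px = spec.arch_radius_mm * np.cos(theta)
    py = spec.arch_radius_mm * np.sin(theta)
    pz = rng.uniform(-0.3, 0.3) * spec.bone_radius_mm
    # normal ~ local arch tangent, tilted a little so planes are oblique
    tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
    tilt = rng.normal(scale=0.15, size=3)
    normal = tangent + tilt
    normal /= np.linalg.norm(normal)
    return np.array([px, py, pz]), normal, theta


def generate_phantom(spec: PhantomSpec):
    """Build one phantom.

    Returns
    -------
    volume : Volume
        Noisy intensity grid on the normalized [0, 1] scale.
    mandible : LabelMask
        The voxelized half-torus (both bone segments for displaced cases).
    fracture : LabelMask
        Planted fracture voxels labeled 1..k per fracture.
    records : list of FractureRecord
        One per successfully planted fracture. A plane that misses the bone
        is re-sampled up to a retry cap, then dropped with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    solid, cortical, interior, (x, y, z) = _half_torus_masks(spec)
    sp = spec.spacing_mm

    intensity = np.full(spec.shape, spec.background_intensity, dtype=np.float32)
    intensity[interior] = spec.cancellous_intensity
    intensity[cortical] = spec.cortical_intensity

    mandible = solid.copy()
    fracture = np.zeros(spec.shape, dtype=np.uint8)
    records: List[FractureRecord] = []

    # at most one displaced fracture per phantom: a second rigid shift would
    # compound with the first and fragment the geometry; planted first so the
    # shift cannot carry bone away from already-recorded ground-truth bands
    n_displaced = int(spec.n_fractures >= 1
                      and rng.random() < spec.displaced_fraction)
    kinds = [DISPLACED] * n_displaced + [NONDISPLACED] * (spec.n_fractures - n_displaced)

    fid = 0
    used_thetas: List[float] = []
    for kind in kinds:
        planted = False
        for _attempt in range(10):
            sampled = _sample_fracture_plane(rng, spec, used_thetas)
            if sampled is None:
                break
            point, normal, theta = sampled
            sdist = (x - point[0]) * normal[0] + (y - point[1]) * normal[1] \
                + (z - point[2]) * normal[2]
            # restrict the band to the bone near the plane point: the
            # infinite plane may graze the opposite arm of the horseshoe
            local = ((x - point[0]) ** 2 + (y - point[1]) ** 2
                     + (z - point[2]) ** 2) <= (3.0 * spec.bone_radius_mm) ** 2
            if kind == NONDISPLACED:
                band = mandible & local \
                    & (np.abs(sdist) <= spec.plane_thickness_mm / 2.0)
                if band.sum() < 1:
                    continue
                intensity[band] = spec.background_intensity
                fid += 1
                fracture[band] = fid
                records.append(FractureRecord(fid, kind, tuple(point),
                                              tuple(normal), int(band.sum())))
                used_thetas.append(theta)
                planted = True
                break
            else:
                moved = _apply_displacement(mandible, intensity, sdist, normal,
                                            spec, fid + 1, fracture, local)
                if moved is None:
                    continue
                mandible, intensity, count = moved
                fid += 1
                records.append(FractureRecord(fid, kind, tuple(point),
                                              tuple(normal), count))
                used_thetas.append(theta)
                planted = True
                break
        if not planted:
            warnings.warn(f"fracture of kind {kind} could not be planted; dropped")

    # keep ground truth consistent with the final bone mask
    near_bone = ndimage.binary_dilation(mandible, ndimage.generate_binary_structure(3, 3))
    fracture[~near_bone] = 0
    records = [dataclasses.replace(r, gt_voxel_count=int((fracture == r.index).sum()))
               for r in records if (fracture == r.index).any()]

    noisy = intensity
    if spec.noise_sd > 0:
        noisy = intensity + rng.normal(0.0, spec.noise_sd,
                                       size=spec.shape).astype(np.float32)
        noisy = np.clip(noisy, 0.0, 1.0)

    spacing = (sp, sp, sp)
    return (Volume(noisy.astype(np.float32), spacing),
            LabelMask(mandible.astype(np.uint8), spacing),
            LabelMask(fracture, spacing),
            records)


def _apply_displacement(mandible, intensity, sdist, normal, spec, label,
                        fracture, local):
    """Rigidly shift the positive-side bone segment along the plane normal.

    The shift is rounded to a whole-voxel offset so masks stay exact. Returns
    the updated (mandible, intensity, gt_voxel_count) or None if the plane
    does not split the bone into two usable parts.
    """
    sp = spec.spacing_mm
    pos = mandible & (sdist > 0)
    neg = mandible & (sdist <= 0)
    if pos.sum() < 10 or neg.sum() < 10:
        return None
    shift_vox = np.rint(normal * spec.displacement_mm / sp).astype(int)
    if not shift_vox.any():
        return None
    shift_mm = shift_vox * sp

    moved_mask = _integer_shift(pos, shift_vox)
    moved_int = _integer_shift(np.where(pos, intensity, 0.0), shift_vox)

    new_mandible = neg | moved_mask
    new_intensity = np.where(neg, intensity, spec.background_intensity)
    new_intensity = np.where(moved_mask & ~neg, moved_int, new_intensity)

    # interface band: stationary cut surface + the moved segment's cut surface
    d_shift = float(np.dot(shift_mm, normal))
    surf_stay = neg & (sdist >= -sp)
    surf_moved = moved_mask & (sdist - d_shift <= sp) & (sdist - d_shift > -sp)
    band = (surf_stay | surf_moved) & new_mandible & local
    if band.sum() < 1:
        return None
    fracture[band] = label
    return new_mandible, new_intensity.astype(np.float32), int(band.sum())


def _integer_shift(a: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Shift an array by a whole-voxel offset, filling with zeros."""
    out = np.zeros_like(a)
    src = [slice(max(0, -s), a.shape[i] - max(0, s)) for i, s in enumerate(shift)]
    dst = [slice(max(0, s), a.shape[i] + min(0, s)) for i, s in enumerate(shift)]
    out[tuple(dst)] = a[tuple(src)]
    return out


def make_dataset(n_scans: int, spec: PhantomSpec, out_dir,
                 fractured_fraction: float = 0.5) -> pd.DataFrame:
    """Write ``n_scans`` phantom triples plus a fracture manifest.

    Exactly ``round(fractured_fraction * n_scans)`` scans carry fractures;
    which scans those are is a seeded shuffle. Per-scan seeds are
    ``spec.seed + scan_index`` so any scan can be regenerated in isolation.

    The manifest has one row per planted fracture (scan_id, kind,
    voxel_count, seed) plus one ``kind="none"`` row per intact scan so every
    scan appears.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    n_fractured = int(round(fractured_fraction * n_scans))
    rng = np.random.default_rng(spec.seed)
    fractured = np.zeros(n_scans, dtype=bool)
    fractured[rng.permutation(n_scans)[:n_fractured]] = True

    rows = []
    for i in range(n_scans):
        scan_spec = spec.replace(seed=spec.seed + i,
                                 n_fractures=spec.n_fractures if fractured[i] else 0)
        vol, mand, frac, records = generate_phantom(scan_spec)
        sid = f"scan_{i:04d}"
        write_volume(vol, os.path.join(out_dir, f"{sid}_image.nii.gz"))
        write_volume(mand, os.path.join(out_dir, f"{sid}_mandible.nii.gz"))
        write_volume(frac, os.path.join(out_dir, f"{sid}_fracture.nii.gz"))
        if records:
            for r in records:
                rows.append(dict(scan_id=sid, fracture_id=r.index, kind=r.kind,
                                 voxel_count=r.gt_voxel_count, seed=scan_spec.seed))
        else:
            rows.append(dict(scan_id=sid, fracture_id=0, kind="none",
                             voxel_count=0, seed=scan_spec.seed))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def _scan_stratum(kinds: set) -> str:
    real = {k for k in kinds if k != "none"}
    if not real:
        return "none"
    if len(real) == 1:
        return next(iter(real))
    return "mixed"


def split_dataset(manifest: pd.DataFrame,
                  fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> pd.DataFrame:
    """Stratified scan-level train/val/test split.

    Scans are stratified by fracture kind (none / nondisplaced / displaced /
    mixed). Within each stratum the split sizes match the target fractions to
    within one scan (largest-remainder rounding). Returns the manifest with a
    ``split`` column; no scan lands in two splits.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    names = ("train", "val", "test")
    rng = np.random.default_rng(seed)
    strata = manifest.groupby("scan_id")["kind"].agg(lambda k: _scan_stratum(set(k)))
    assignment = {}
    for _stratum, scans in strata.groupby(strata):
        ids = sorted(scans.index)
        if len(ids) < len(names):
            warnings.warn(f"stratum '{_stratum}' has fewer scans than splits; "
                          "assigning by global shuffle")
        rng.shuffle(ids)
        counts = _largest_remainder(len(ids), fractions)
        start = 0
        for name, c in zip(names, counts):
            for sid in ids[start:start + c]:
                assignment[sid] = name
            start += c
    out = manifest.copy()
    out["split"] = out["scan_id"].map(assignment)
    return out


def _largest_remainder(n: int, fractions) -> List[int]:
    exact = [f * n for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    rem = n - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)])  # largest remainder first
    for i in range(rem):
        base[order[i]] += 1
    return base
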