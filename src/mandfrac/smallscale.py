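"""Desk-scale reference experiment: train and score the full cascade on phantoms.

Clinical-scale training (hundreds of CBCT scans, 64³ patches, 500 epochs on
a GPU) is out of reach on a single CPU, so the package ships one fixed
scaled-down configuration that exercises every stage end to end: width-4
networks with 3 resolution levels, 32³ patches, 96³ phantoms, a few tens of
epochs. The phantom bone/fracture contrast makes the task learnable at this
size; the configuration below is the package's reference experiment and is
what the acceptance checks run.
"""

from __future__ import annotations

import dataclasses
import time
from typing import Dict, List, Optional

import numpy as np

from .evaluation import dice, evaluate_scans, froc
from .inference import PipelineConfig, run_pipeline
from .phantom import PhantomSpec, generate_phantom
from .stages import ArchSpec, stage_input_channels
from .training import Scan, TrainConfig, train_stage
from .volume_io import Volume


@dataclasses.dataclass
class SmallScaleConfig:
    """The fixed desk-scale study conditions."""

    n_train: int = 14
    n_val: int = 6
    n_test: int = 5
    fractured_fraction: float = 0.5
    patch_size: int = 32
    levels: int = 3
    base_width: int = 4
    stride: int = 16
    epochs_stage1: int = 15
    epochs_stage2: int = 10
    epochs_stage3: int = 8
    patches_per_epoch: int = 64
    val_patches: int = 16
    seed: int = 0


def make_phantom_scans(n: int, seed0: int, fractured_fraction: float = 0.5,
                       spec: Optional[PhantomSpec] = None,
                       all_fractured: bool = False):
    """Generate n phantoms; scan seeds are seed0 + index."""
    base = spec or PhantomSpec()
    scans, records = [], {}
    n_fractured = n if all_fractured else int(round(fractured_fraction * n))
    for i in range(n):
        fractured = all_fractured or i < n_fractured
        s = base.replace(seed=seed0 + i, n_fractures=1 if fractured else 0)
        vol, mand, frac, recs = generate_phantom(s)
        sid = f"phantom_{seed0 + i}"
        scans.append(Scan(sid, vol.data, mand.data, frac.data))
        records[sid] = recs
    return scans, records


def train_cascade(cfg: SmallScaleConfig, train_scans: List[Scan],
                  val_scans: List[Scan], verbose: bool = False) -> Dict[int, object]:
    """Successively train the three stages, each on its data regime."""
    nets = {}
    timings = {}
    # stage 1: scans with complete (unfractured) mandibles
    s1_train = [s for s in train_scans if not s.fracture.any()] or train_scans
    s1_val = [s for s in val_scans if not s.fracture.any()] or val_scans
    # stages 2-3: fractured scans
    fx_train = [s for s in train_scans if s.fracture.any()] or train_scans
    fx_val = [s for s in val_scans if s.fracture.any()] or val_scans

    for sid, tr, va, epochs in [(1, s1_train, s1_val, cfg.epochs_stage1),
                                (2, fx_train, fx_val, cfg.epochs_stage2),
                                (3, fx_train, fx_val, cfg.epochs_stage3)]:
        feat = nets[1].arch.feature_channels if nets else cfg.base_width
        arch = ArchSpec(sid, stage_input_channels(sid, feat),
                        levels=cfg.levels, base_width=cfg.base_width)
        tc = TrainConfig(stage_id=sid, max_epochs=epochs,
                         patches_per_epoch=cfg.patches_per_epoch,
                         val_patches=cfg.val_patches,
                         patch_size=cfg.patch_size, seed=cfg.seed)
        t0 = time.time()
        nets[sid], hist = train_stage(sid, tr, va, tc, prior_stages=nets, arch=arch)
        timings[sid] = time.time() - t0
        if verbose:
            print(f"stage {sid}: {timings[sid]:.0f} s, "
                  f"best epoch {hist.attrs['best_epoch']}, "
                  f"final val loss {hist.val_loss.iloc[-1]:.4f}", flush=True)
    return nets


def threshold_baseline_dice(scans: List[Scan]) -> float:
    """Noise-free separable baseline: bone by intensity threshold.

    The phantom's cancellous intensity exceeds the background, so a fixed
    midpoint threshold recovers the mandible up to noise and fracture gaps.
    This brute-force oracle sets the level of performance a learned
    segmenter should at least approach.
    """
    ds = []
    for s in scans:
        pred = s.volume > 0.33  # midpoint of background (0.15) and cancellous (0.5)
        ds.append(dice(pred, s.mandible > 0))
    return float(np.mean(ds))


def evaluate_cascade(nets, test_scans: List[Scan],
                     cfg: SmallScaleConfig) -> dict:
    """Scan-level evaluation on held-out phantoms.

    Returns mandible Dice (mean over scans), the detection report, and the
    sensitivity achievable at <= 1 false positive per scan from the FROC.
    """
    pc = PipelineConfig(patch_size=cfg.patch_size, stride=cfg.stride,
                        confidence_tau=0.0)  # FROC sweeps the threshold
    dices, scan_results = [], []
    for s in test_scans:
        vol = Volume(s.volume)
        res = run_pipeline(vol, nets[1], nets[2], nets[3], pc)
        dices.append(dice(res.mandible_map >= 0.5, s.mandible > 0))
        # the fracture mask labels voxels by fracture id, so both interface
        # bands of a displaced fracture count as one ground-truth fracture
        scan_results.append((res.proposals, s.fracture))
    report = evaluate_scans(scan_results)
    curve = froc(scan_results)
    at_most_1fp = [sens for _, sens, fp in curve.points if fp <= 1.0 + 1e-12]
    report["sensitivity_at_1fp_per_scan"] = max(at_most_1fp) if at_most_1fp else 0.0
    report["mandible_dice"] = float(np.mean(dices))
    return report


def oracle_stage_fns(mandible: np.ndarray, fracture: np.ndarray,
                     blob_dilation: int = 4):
    """Ground-truth stand-ins for the learned stages.

    The stage-1 oracle returns the true mandible mask as probabilities; the
    stage-2 oracle returns the true fracture mask; the stage-3 oracle mimics
    patch-level classification by a dilated blob around the fracture (a
    patch-resolution detector cannot localize more finely than that). Used
    to exercise cropping, proposal extraction, union and filtering in
    isolation from network quality.
    """
    from scipy import ndimage as ndi

    mand = (np.asarray(mandible) > 0).astype(np.float32)
    frac = (np.asarray(fracture) > 0)
    if frac.any() and blob_dilation > 0:
        blob = ndi.binary_dilation(frac, ndi.generate_binary_structure(3, 3),
                                   iterations=blob_dilation)
    else:
        blob = frac

    def mandible_fn(data):
        return mand

    def fracture_fn(cropped, offset):
        sl = tuple(slice(o, o + s) for o, s in zip(offset, cropped.shape))
        return frac[sl].astype(np.float32), blob[sl].astype(np.float32)

    return mandible_fn, fracture_fn


def run_reference_experiment(seed: int = 0, verbose: bool = False,
                             cfg: Optional[SmallScaleConfig] = None) -> dict:
    """Generate phantoms, train the cascade, and score it on held-out scans."""
    cfg = cfg or SmallScaleConfig(seed=seed)
    train_scans, _ = make_phantom_scans(cfg.n_train, seed0=cfg.seed,
                                        fractured_fraction=cfg.fractured_fraction)
    val_scans, _ = make_phantom_scans(cfg.n_val, seed0=cfg.seed + 1000,
                                      fractured_fraction=cfg.fractured_fraction)
    test_scans, _ = make_phantom_scans(cfg.n_test, seed0=cfg.seed + 2000,
                                       all_fractured=True)
    nets = train_cascade(cfg, train_scans, val_scans, verbose=verbose)
    report = evaluate_cascade(nets, test_scans, cfg)
    report["threshold_baseline_dice"] = threshold_baseline_dice(test_scans)
    return report
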