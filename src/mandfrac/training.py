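"""Successive training of the three stages.

Each stage is optimized with AdamW (weight decay 0.01) under a cosine
annealing schedule with linear warmup. Stage 1 trains on scans with complete
mandibles; stages 2 and 3 train on fractured scans with earlier stages
frozen in evaluation mode (their parameters receive no gradient and stay
bit-identical). An "epoch" draws a fixed number of randomly positioned
patches rather than exhaustively tiling every scan; model selection keeps
the parameters of the lowest-validation-loss epoch.
"""

from __future__ import annotations

import copy
import dataclasses
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import patching
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import AdamW
from .stages import ArchSpec, Stage1Net, Stage2Net, build_stage, stage_input_channels

STAGE_LR = {1: 0.005, 2: 0.002, 3: 0.002}


@dataclasses.dataclass
class TrainConfig:
    stage_id: int
    learning_rate: Optional[float] = None  # stage default when None
    weight_decay: float = 0.01
    max_epochs: int = 500
    batch_size: int = 4
    warmup_epochs: Optional[int] = None    # default: 5% of max_epochs
    seed: int = 0
    patches_per_epoch: int = 256
    val_patches: int = 32
    patch_size: int = 64
    position_loss_weight: float = 1.0
    soften_radius_vox: int = 1
    soften_sigma_vox: float = 0.5

    def __post_init__(self):
        if self.learning_rate is None:
            self.learning_rate = STAGE_LR[self.stage_id]
        if self.warmup_epochs is None:
            self.warmup_epochs = min(max(1, int(round(0.05 * self.max_epochs))),
                                     self.max_epochs - 1)
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be > 0 and batch_size >= 1")
        if self.warmup_epochs >= self.max_epochs:
            raise ValueError("warmup_epochs must be < max_epochs")


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Linear warmup to the base rate, then cosine annealing to zero."""
    if not 0 <= epoch < config.max_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.max_epochs})")
    base, w = config.learning_rate, config.warmup_epochs
    if epoch < w:
        return base * epoch / w
    span = config.max_epochs - w
    return base * 0.5 * (1.0 + np.cos(np.pi * (epoch - w) / span))


@dataclasses.dataclass
class Scan:
    """An in-memory training example: normalized volume plus ground truth."""

    scan_id: str
    volume: np.ndarray
    mandible: np.ndarray
    fracture: np.ndarray


# ------------------------------------------------------------ batch helpers

def gap_batch(patches: Sequence[patching.Patch]) -> np.ndarray:
    """Stack gap_channels of single-channel patches into (N, 4, s, s, s)."""
    return np.stack([patching.gap_channels(p).data for p in patches])


def stage1_context(s1: Stage1Net, patches: Sequence[patching.Patch]) -> np.ndarray:
    """Frozen stage-1 context: intensity ⊕ decoder features ⊕ logits.

    Run in evaluation mode with no gradient; used as the plain-array input
    to stages 2 and 3.
    """
    s1.eval()
    x = gap_batch(patches)
    out = s1(Tensor(x))
    intensity = x[:, :1]
    return np.concatenate(
        [intensity, out.decoder_features.data, out.mandible_logits.data], axis=1)


def _random_patch_origins(rng, scans: Sequence[Scan], n: int, patch_size: int,
                          bone_biased: bool = True):
    """(scan, origin) pairs; half centred on mandible voxels when biased."""
    picks = []
    for i in range(n):
        scan = scans[rng.integers(len(scans))]
        shape = scan.volume.shape
        hi = [max(s - patch_size, 0) for s in shape]
        if bone_biased and i % 2 == 0 and scan.mandible.any():
            idx = np.argwhere(scan.mandible > 0)
            c = idx[rng.integers(len(idx))]
            origin = tuple(int(np.clip(cc - patch_size // 2
                                       + rng.integers(-patch_size // 4,
                                                      patch_size // 4 + 1),
                                       0, h)) for cc, h in zip(c, hi))
        else:
            origin = tuple(int(rng.integers(0, h + 1)) for h in hi)
        picks.append((scan, origin))
    return picks


# ----------------------------------------------------------- stage batches

def _stage1_batch(rng, scans, config):
    picks = _random_patch_origins(rng, scans, config.batch_size, config.patch_size)
    patches, targets, positions = [], [], []
    for scan, origin in picks:
        patches.append(patching.extract_patch(scan.volume, origin, config.patch_size))
        targets.append(patching.extract_patch(scan.mandible, origin, config.patch_size).data)
        positions.append(patching.relative_position(
            origin, config.patch_size, scan.volume.shape).rel)
    return gap_batch(patches), np.stack(targets), np.asarray(positions, np.float32)


def _stage1_loss(net: Stage1Net, x, seg_t, pos_t, config):
    out = net(Tensor(x))
    seg = ag.bce_with_logits(out.mandible_logits, seg_t)
    pos = ag.smooth_l1(out.position, pos_t)
    return ag.add(seg, ag.scale(pos, config.position_loss_weight))


def _soft_targets(scans, config) -> Dict[str, np.ndarray]:
    return {s.scan_id: patching.soften_fracture_target(
        s.fracture, config.soften_radius_vox, config.soften_sigma_vox)
        for s in scans}


def _stage2_batch(rng, scans, soft, config):
    scan = scans[rng.integers(len(scans))]
    pairs = patching.sample_balanced_patches(
        scan.volume, soft[scan.scan_id], config.batch_size,
        seed=int(rng.integers(2 ** 31)), patch_size=config.patch_size)
    patches = [p for p, _ in pairs]
    targets = np.stack([t.data for _, t in pairs])
    return patches, targets


def _stage2_loss(net: Stage2Net, ctx, targets):
    la, lb = net(Tensor(ctx))
    return ag.add(ag.bce_with_logits(la, targets), ag.bce_with_logits(lb, targets))


def _stage3_batch(rng, scans, config):
    """Half fracture-containing, half fracture-free patches with binary labels."""
    patches, labels = [], []
    for i in range(config.batch_size):
        scan = scans[rng.integers(len(scans))]
        want_pos = (i % 2 == 0) and scan.fracture.any()
        shape = scan.volume.shape
        hi = [max(s - config.patch_size, 0) for s in shape]
        for _try in range(50):
            if want_pos:
                idx = np.argwhere(scan.fracture > 0)
                c = idx[rng.integers(len(idx))]
                origin = tuple(int(np.clip(cc - config.patch_size // 2
                                           + rng.integers(-config.patch_size // 4,
                                                          config.patch_size // 4 + 1),
                                           0, h)) for cc, h in zip(c, hi))
            else:
                origin = tuple(int(rng.integers(0, h + 1)) for h in hi)
            frac = patching.extract_patch(scan.fracture, origin, config.patch_size)
            has = frac.data.sum() > 0
            if has == want_pos:
                break
        patches.append(patching.extract_patch(scan.volume, origin, config.patch_size))
        labels.append(1.0 if has else 0.0)
    return patches, np.asarray(labels, np.float32).reshape(-1, 1)


def _stage3_context(s1: Stage1Net, s2: Stage2Net, patches) -> np.ndarray:
    ctx2 = stage1_context(s1, patches)
    s2.eval()
    _, lb = s2(Tensor(ctx2))
    return np.concatenate([ctx2, lb.data], axis=1)


# -------------------------------------------------------------- train loop

def train_stage(stage_id: int, train_scans: Sequence[Scan],
                val_scans: Sequence[Scan], config: TrainConfig,
                prior_stages: Optional[dict] = None,
                arch: Optional[ArchSpec] = None):
    """Train one stage; returns (net-at-best-validation-epoch, history).

    ``prior_stages`` maps stage id to the trained, frozen earlier networks
    (required for stages 2 and 3). History is a DataFrame with one row per
    epoch (epoch, lr, train_loss, val_loss).
    """
    if not train_scans or not val_scans:
        raise ValueError("empty dataset")
    prior_stages = prior_stages or {}
    if stage_id > 1 and 1 not in prior_stages:
        raise ValueError("stage 1 must be trained before stages 2 and 3")
    if stage_id == 3 and 2 not in prior_stages:
        raise ValueError("stage 2 must be trained before stage 3")
    for p in prior_stages.values():
        p.eval()

    if arch is None:
        feat = prior_stages[1].arch.feature_channels if prior_stages else 16
        arch = ArchSpec(stage_id, stage_input_channels(stage_id, feat))
    net = build_stage(stage_id, arch, seed=config.seed)
    opt = AdamW(net.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    val_rng = np.random.default_rng(config.seed + 10_000)

    soft = _soft_targets(train_scans, config) if stage_id == 2 else None
    soft_val = _soft_targets(val_scans, config) if stage_id == 2 else None

    steps = max(1, config.patches_per_epoch // config.batch_size)
    val_steps = max(1, config.val_patches // config.batch_size)
    history: List[dict] = []
    best = (np.inf, None, -1)

    def batch_loss(scans, soft_map, r, train: bool):
        if stage_id == 1:
            x, seg_t, pos_t = _stage1_batch(r, scans, config)
            return _stage1_loss(net, x, seg_t, pos_t, config)
        if stage_id == 2:
            patches, targets = _stage2_batch(r, scans, soft_map, config)
            ctx = stage1_context(prior_stages[1], patches)
            return _stage2_loss(net, ctx, targets)
        patches, labels = _stage3_batch(r, scans, config)
        ctx = _stage3_context(prior_stages[1], prior_stages[2], patches)
        return ag.bce_with_logits(net(Tensor(ctx)), labels)

    for epoch in range(config.max_epochs):
        opt.lr = lr_schedule(epoch, config)
        net.train()
        train_losses = []
        for _ in range(steps):
            opt.zero_grad()
            loss = batch_loss(train_scans, soft, rng, True)
            loss.backward()
            opt.step()
            train_losses.append(float(loss.data))
        net.eval()
        vr = np.random.default_rng(val_rng.integers(2 ** 31))
        val_losses = [float(batch_loss(val_scans, soft_val, vr, False).data)
                      for _ in range(val_steps)]
        val_loss = float(np.mean(val_losses))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.append(dict(epoch=epoch, lr=opt.lr,
                            train_loss=float(np.mean(train_losses)),
                            val_loss=val_loss))
        if val_loss < best[0]:
            best = (val_loss, copy.deepcopy(net.named_state()), epoch)

    net.load_state(best[1])
    net.eval()
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best[2]
    return net, hist
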