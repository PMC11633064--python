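"""The three stage networks and their losses.

Stage 1 is a U-shaped network with a shared encoder: the decoder predicts a
mandible segmentation, while a position head (global average pooling over
the deepest encoder features, then two fully connected layers) regresses the
patch's relative position inside the scan. Stage 2 is a cascade of two
U-Nets segmenting fracture lines, the second refining the first's logits.
Stage 3 is an encoder + GAP + two fully connected layers classifying whether
a patch contains any fracture. Every hidden layer is followed by batch
normalization and a leaky ReLU.

The architecture is parameterized by an :class:`ArchSpec` (encoder depth,
base channel width) so the same code runs full-size (4 levels, width 16) and
scaled-down (3 levels, width 4) configurations.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Tuple

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Conv3d, ConvBlock, Linear, Module

PROB_EPS = 1e-7


@dataclasses.dataclass
class ArchSpec:
    """Architecture descriptor shared by all stages.

    ``in_channels`` is the channel count of the concatenated input a stage
    consumes; it is recorded so checkpoints refuse to load into a mismatched
    model. ``feature_channels`` is the width of the stage-1 decoder features
    carried to stages 2 and 3 (the decoder's final hidden width).
    """

    stage_id: int
    in_channels: int
    levels: int = 4
    base_width: int = 16
    hidden_units: int = 64

    @property
    def widths(self):
        return [self.base_width * 2 ** i for i in range(self.levels)]

    @property
    def feature_channels(self) -> int:
        return self.base_width

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @staticmethod
    def from_json(s: str) -> "ArchSpec":
        return ArchSpec(**json.loads(s))


class Encoder(Module):
    """Stack of conv blocks with 2× max pooling between resolution levels."""

    def __init__(self, rng, arch: ArchSpec):
        super().__init__()
        self.levels = arch.levels
        widths = arch.widths
        for i in range(arch.levels):
            cin = arch.in_channels if i == 0 else widths[i - 1]
            setattr(self, f"enc{i}", ConvBlock(rng, cin, widths[i]))

    def __call__(self, x: Tensor):
        skips = []
        h = x
        for i in range(self.levels):
            h = getattr(self, f"enc{i}")(h)
            if i < self.levels - 1:
                skips.append(h)
                h = ag.max_pool2(h)
        return h, skips


class UNet(Module):
    """U-shaped segmentation network with concatenation skip connections.

    Decoder upsampling is nearest-neighbour ×2 followed by a conv block; the
    head is a 1×1×1 convolution to one logit channel.
    """

    def __init__(self, rng, arch: ArchSpec):
        super().__init__()
        self.levels = arch.levels
        widths = arch.widths
        self.encoder = Encoder(rng, arch)
        for i in reversed(range(arch.levels - 1)):
            setattr(self, f"dec{i}", ConvBlock(rng, widths[i + 1] + widths[i], widths[i]))
        self.head = Conv3d(rng, widths[0], 1, kernel=1)

    def __call__(self, x: Tensor):
        h, skips = self.encoder(x)
        bottleneck = h
        for i in reversed(range(self.levels - 1)):
            h = ag.concat([ag.upsample2(h), skips[i]])
            h = getattr(self, f"dec{i}")(h)
        return self.head(h), h, bottleneck


@dataclasses.dataclass
class Stage1Output:
    mandible_logits: Tensor      # (N, 1, s, s, s)
    position: Tensor             # (N, 3), sigmoid-bounded to [0, 1]
    decoder_features: Tensor     # (N, F, s, s, s)


class Stage1Net(Module):
    """Mandible segmentation + patch-position regression, shared encoder."""

    def __init__(self, arch: ArchSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.unet = UNet(rng, arch)
        deep = arch.widths[-1]
        self.fc1 = Linear(rng, deep, arch.hidden_units)
        self.fc2 = Linear(rng, arch.hidden_units, 3)

    def __call__(self, patch4: Tensor) -> Stage1Output:
        if patch4.data.shape[1] != self.arch.in_channels:
            raise ValueError(
                f"stage 1 expects {self.arch.in_channels} channels, "
                f"got {patch4.data.shape[1]}")
        logits, dec_feat, bottleneck = self.unet(patch4)
        pooled = ag.global_avg_pool(bottleneck)
        pos = ag.sigmoid(self.fc2(ag.leaky_relu(self.fc1(pooled))))
        return Stage1Output(logits, pos, dec_feat)


class Stage2Net(Module):
    """Cascade of two U-Nets for fracture-line segmentation.

    The second U-Net receives the first's logits appended to its input and
    refines them; the final fracture probability is sigmoid of the second
    network's logits. Trained jointly (the cascade is not detached).
    """

    def __init__(self, arch: ArchSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.unet_a = UNet(rng, arch)
        arch_b = dataclasses.replace(arch, in_channels=arch.in_channels + 1)
        self.unet_b = UNet(rng, arch_b)

    def __call__(self, ctx: Tensor) -> Tuple[Tensor, Tensor]:
        if ctx.data.shape[1] != self.arch.in_channels:
            raise ValueError(
                f"stage 2 expects {self.arch.in_channels} channels, "
                f"got {ctx.data.shape[1]}")
        logits_a, _, _ = self.unet_a(ctx)
        logits_b, _, _ = self.unet_b(ag.concat([ctx, logits_a]))
        return logits_a, logits_b


class Stage3Net(Module):
    """Patch-level fracture classifier: encoder, GAP, two FC layers."""

    def __init__(self, arch: ArchSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.encoder = Encoder(rng, arch)
        self.fc1 = Linear(rng, arch.widths[-1], arch.hidden_units)
        self.fc2 = Linear(rng, arch.hidden_units, 1)

    def __call__(self, ctx: Tensor) -> Tensor:
        if ctx.data.shape[1] != self.arch.in_channels:
            raise ValueError(
                f"stage 3 expects {self.arch.in_channels} channels, "
                f"got {ctx.data.shape[1]}")
        h, _ = self.encoder(ctx)
        return self.fc2(ag.leaky_relu(self.fc1(ag.global_avg_pool(h))))


def build_stage(stage_id: int, arch: ArchSpec, seed: int = 0) -> Module:
    net = {1: Stage1Net, 2: Stage2Net, 3: Stage3Net}[stage_id](arch, seed)
    return net


def stage_input_channels(stage_id: int, feature_channels: int,
                         n_gap_windows: int = 3) -> int:
    """Channel count of each stage's concatenated input.

    Stage 1: intensity + adaptive windows. Stage 2: intensity ⊕ stage-1
    decoder features ⊕ stage-1 logits. Stage 3: stage-2 input ⊕ stage-2
    logits.
    """
    if stage_id == 1:
        return 1 + n_gap_windows
    if stage_id == 2:
        return 1 + feature_channels + 1
    if stage_id == 3:
        return 1 + feature_channels + 1 + 1
    raise ValueError(f"unknown stage {stage_id}")


# ----------------------------------------------------------------- losses

def bce_loss(probabilities, targets, eps: float = PROB_EPS) -> float:
    """Mean binary cross-entropy on probabilities, clamped away from {0,1}."""
    p = np.asarray(probabilities, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if t.min() < 0 or t.max() > 1:
        raise ValueError("targets must lie in [0, 1]")
    p = np.clip(p, eps, 1 - eps)
    return float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())


def smooth_l1_loss(pred, target, beta: float = 1.0) -> float:
    """Mean smooth-L1: 0.5·d²/beta for |d| < beta, else |d| − 0.5·beta."""
    d = np.asarray(pred, dtype=np.float64) - np.asarray(target, dtype=np.float64)
    ad = np.abs(d)
    return float(np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta).mean())


# -------------------------------------------------------------- checkpoints

def save_stage(net: Module, path) -> None:
    """One file per stage: parameters + buffers + embedded descriptor."""
    state = net.named_state()
    np.savez(path, __descriptor__=np.frombuffer(
        net.arch.to_json().encode(), dtype=np.uint8), **state)


def load_stage(path, seed: int = 0) -> Module:
    """Rebuild a stage from its checkpoint; descriptor mismatches refuse."""
    with np.load(path) as z:
        arch = ArchSpec.from_json(bytes(z["__descriptor__"]).decode())
        net = build_stage(arch.stage_id, arch, seed)
        expected = set(net.named_state())
        stored = set(z.files) - {"__descriptor__"}
        if expected != stored:
            raise ValueError(f"checkpoint does not match architecture "
                             f"{arch}: missing {expected - stored}, "
                             f"unexpected {stored - expected}")
        net.load_state({k: z[k] for k in stored})
    net.eval()
    return net
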