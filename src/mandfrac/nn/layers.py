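"""Layer and optimizer classes on top of the autodiff engine."""

from __future__ import annotations

from typing import Dict, Iterable, List

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter registry, train/eval mode, checkpoint dicts."""

    def __init__(self):
        self._params: Dict[str, Tensor] = {}
        self._buffers: Dict[str, np.ndarray] = {}
        self._children: Dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array.astype(np.float32), requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, array: np.ndarray) -> np.ndarray:
        a = array.astype(np.float32)
        self._buffers[name] = a
        return a

    def parameters(self) -> List[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_state(self, prefix: str = "") -> Dict[str, np.ndarray]:
        state = {prefix + k: v.data for k, v in self._params.items()}
        state.update({prefix + k: v for k, v in self._buffers.items()})
        for name, child in self._children.items():
            state.update(child.named_state(prefix + name + "."))
        return state

    def load_state(self, state: Dict[str, np.ndarray], prefix: str = "") -> None:
        for k, t in self._params.items():
            t.data = np.asarray(state[prefix + k], dtype=np.float32).copy()
        for k in self._buffers:
            self._buffers[k][...] = state[prefix + k]
        for name, child in self._children.items():
            child.load_state(state, prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int = 3):
        super().__init__()
        fan_in = in_ch * kernel ** 3
        self.w = self.register("w", _he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in))
        self.b = self.register("b", np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.w, self.b)


class BatchNorm3d(Module):
    def __init__(self, channels: int):
        super().__init__()
        self.gamma = self.register("gamma", np.ones(channels))
        self.beta = self.register("beta", np.zeros(channels))
        self.running_mean = self.register_buffer("running_mean", np.zeros(channels))
        self.running_var = self.register_buffer("running_var", np.ones(channels))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.batch_norm(x, self.gamma, self.beta,
                             self.running_mean, self.running_var, self.training)


class Linear(Module):
    def __init__(self, rng, in_f: int, out_f: int):
        super().__init__()
        self.w = self.register("w", _he_init(rng, (in_f, out_f), in_f))
        self.b = self.register("b", np.zeros(out_f))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.w, self.b)


class ConvBlock(Module):
    """conv → batch norm → leaky ReLU, twice."""

    def __init__(self, rng, in_ch: int, out_ch: int):
        super().__init__()
        self.conv1 = Conv3d(rng, in_ch, out_ch)
        self.bn1 = BatchNorm3d(out_ch)
        self.conv2 = Conv3d(rng, out_ch, out_ch)
        self.bn2 = BatchNorm3d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        x = ag.leaky_relu(self.bn1(self.conv1(x)))
        return ag.leaky_relu(self.bn2(self.conv2(x)))


class AdamW(Module):
    """AdamW: Adam moments plus decoupled weight decay."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        super().__init__()
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
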