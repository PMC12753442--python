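"""Neural-network building blocks on top of the autodiff engine.

Includes the residual convolutional backbones used for the image
modalities: a full 18-layer residual network (stem 7x7/2 + max-pool +
four stages of two basic blocks, channels 64-512) and a reduced-depth
variant sized for small grayscale inputs on a single CPU.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, max_pool2d


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _submodules(self):
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield k, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{k}.{i}", item

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, m in self._submodules():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                state[prefix + k] = v.data.copy()
        for name, m in self._submodules():
            state.update(m.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray],
                        prefix: str = "") -> None:
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                key = prefix + k
                if key not in state:
                    raise KeyError(f"missing weight {key!r} in state dict")
                if state[key].shape != v.data.shape:
                    raise ValueError(
                        f"shape mismatch for {key!r}: checkpoint "
                        f"{state[key].shape} vs model {v.data.shape}")
                v.data = np.asarray(state[key], dtype=v.data.dtype).copy()
        for name, m in self._submodules():
            m.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        # Kaiming-style scaling for rectifier networks
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, (n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.blocks = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.blocks:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                        (c_out, c_in, kernel, kernel)),
                             requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.stride, self.padding)


class BatchNorm2d(Module):
    """Per-channel normalization; batch statistics while training,
    exponential running statistics in evaluation mode."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.running_mean = Tensor(np.zeros((1, channels, 1, 1)))
        self.running_var = Tensor(np.ones((1, channels, 1, 1)))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu.detach()) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean.data = ((1 - m) * self.running_mean.data
                                      + m * mu.data)
            self.running_var.data = ((1 - m) * self.running_var.data
                                     + m * var.data)
        else:
            mu, var = self.running_mean, self.running_var
        norm = (x - mu) * ((var + self.eps) ** -0.5)
        return norm * self.gamma + self.beta


class BasicBlock(Module):
    """Two 3x3 convolutions with identity (or 1x1 projection) shortcut."""

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.shortcut_conv = Conv2d(c_in, c_out, 1, stride, 0, rng)
            self.shortcut_bn = BatchNorm2d(c_out)
        else:
            self.shortcut_conv = None
            self.shortcut_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        identity = x
        if self.shortcut_conv is not None:
            identity = self.shortcut_bn(self.shortcut_conv(x))
        return (out + identity).relu()


class ResNetBackbone(Module):
    """Residual backbone truncated before any classification layer.

    `depth18=True` gives the standard 18-layer topology (7x7/2 stem with
    3-channel input, max-pool, stages 64/128/256/512 x two blocks,
    global average pool -> 512 features). The reduced variant takes a
    single-channel input through a 3x3/2 stem and two down-sampling
    stages (16 -> 32 channels), global average pool.
    """

    def __init__(self, rng: np.random.Generator, depth18: bool = False):
        super().__init__()
        self.depth18 = depth18
        if depth18:
            self.in_channels = 3
            self.stem = Conv2d(3, 64, 7, 2, 3, rng)
            self.stem_bn = BatchNorm2d(64)
            widths = [64, 128, 256, 512]
            self.stages = []
            c_in = 64
            for i, c_out in enumerate(widths):
                stride = 1 if i == 0 else 2
                self.stages.append(BasicBlock(c_in, c_out, stride, rng))
                self.stages.append(BasicBlock(c_out, c_out, 1, rng))
                c_in = c_out
            self.out_channels = 512
        else:
            self.in_channels = 1
            self.stem = Conv2d(1, 16, 3, 2, 1, rng)
            self.stem_bn = BatchNorm2d(16)
            self.stages = [BasicBlock(16, 16, 2, rng),
                           BasicBlock(16, 32, 2, rng)]
            self.out_channels = 32

    def forward(self, x: Tensor) -> Tensor:
        if x.data.ndim != 4 or x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"expected input (N, {self.in_channels}, H, W), "
                f"got {x.data.shape}")
        out = self.stem_bn(self.stem(x)).relu()
        if self.depth18:
            out = max_pool2d(out, 3, 2, 1)
        for block in self.stages:
            out = block(out)
        return out.mean(axis=(2, 3))        # global average pool -> (N, C)
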