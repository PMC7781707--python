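"""Layer modules over the autodiff core (conv, batch norm, linear, blocks)."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class with parameter collection and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params = [v for v in self.__dict__.values() if isinstance(v, Tensor) and v.is_param]
        for child in self._children():
            params.extend(child.parameters())
        return params

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for child in self._children():
            child.set_training(mode)

    def train(self) -> None:
        self.set_training(True)

    def eval(self) -> None:
        self.set_training(False)

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (for checkpoints)."""
        out: dict[str, np.ndarray] = {}
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.is_param:
                out[key] = value.data
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.state_arrays(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(prefix=f"{key}.{i}."))
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.is_param:
                value.data = np.asarray(state[key], dtype=value.data.dtype)
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                value[...] = state[key]
            elif isinstance(value, Module):
                value.load_state_arrays(state, prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, prefix=f"{key}.{i}.")


class Conv2d(Module):
    """Convolution with He-normal initialisation."""

    def __init__(self, cin, cout, k, rng, stride=1, pad=0, bias=True, dtype=np.float32):
        super().__init__()
        self.stride = stride
        self.pad = pad
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(
            (rng.standard_normal((cout, cin, k, k)) * std).astype(dtype), is_param=True
        )
        self.bias = Tensor(np.zeros(cout, dtype=dtype), is_param=True) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, c, dtype=np.float32, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(c, dtype=dtype), is_param=True)
        self.beta = Tensor(np.zeros(c, dtype=dtype), is_param=True)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def forward(self, x):
        return ag.batch_norm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class Linear(Module):
    def __init__(self, din, dout, rng, dtype=np.float32):
        super().__init__()
        std = np.sqrt(2.0 / din)
        self.weight = Tensor(
            (rng.standard_normal((din, dout)) * std).astype(dtype), is_param=True
        )
        self.bias = Tensor(np.zeros(dout, dtype=dtype), is_param=True)

    def forward(self, x):
        return ag.linear(x, self.weight, self.bias)


class ConvBNRelu(Module):
    def __init__(self, cin, cout, k, rng, stride=1, pad=0, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, rng, stride=stride, pad=pad, bias=False, dtype=dtype)
        self.bn = BatchNorm2d(cout, dtype=dtype)

    def forward(self, x):
        return ag.relu(self.bn(self.conv(x)))


class Bottleneck(Module):
    """Post-activation bottleneck residual unit: 1x1 w -> 3x3 w -> 1x1 4w."""

    expansion = 4

    def __init__(self, cin, width, rng, stride=1, dtype=np.float32):
        super().__init__()
        cout = width * self.expansion
        self.conv1 = Conv2d(cin, width, 1, rng, bias=False, dtype=dtype)
        self.bn1 = BatchNorm2d(width, dtype=dtype)
        self.conv2 = Conv2d(width, width, 3, rng, stride=stride, pad=1, bias=False, dtype=dtype)
        self.bn2 = BatchNorm2d(width, dtype=dtype)
        self.conv3 = Conv2d(width, cout, 1, rng, bias=False, dtype=dtype)
        self.bn3 = BatchNorm2d(cout, dtype=dtype)
        if cin != cout or stride != 1:
            self.shortcut_conv = Conv2d(cin, cout, 1, rng, stride=stride, bias=False, dtype=dtype)
            self.shortcut_bn = BatchNorm2d(cout, dtype=dtype)
        else:
            self.shortcut_conv = None
            self.shortcut_bn = None

    def forward(self, x):
        h = ag.relu(self.bn1(self.conv1(x)))
        h = ag.relu(self.bn2(self.conv2(h)))
        h = self.bn3(self.conv3(h))
        if self.shortcut_conv is not None:
            sc = self.shortcut_bn(self.shortcut_conv(x))
        else:
            sc = x
        return ag.relu(ag.add(h, sc))


class AttentionBlock(Module):
    """Residual attention: trunk features gated by a bottom-up/top-down mask.

    The mask branch downsamples, processes at the coarser scale, upsamples
    back and passes through a sigmoid; the output is ``(1 + mask) * trunk``
    so an all-zero mask leaves the trunk untouched (attention residual
    learning).
    """

    def __init__(self, channels, width, rng, dtype=np.float32):
        super().__init__()
        self.trunk = Bottleneck(channels, width, rng, dtype=dtype)
        self.mask_unit = Bottleneck(channels, width, rng, dtype=dtype)
        self.mask_conv = Conv2d(channels, channels, 1, rng, bias=True, dtype=dtype)

    def forward(self, x):
        t = self.trunk(x)
        m = ag.maxpool2d(x, 2, 2)
        m = self.mask_unit(m)
        m = ag.upsample_nearest2(m)
        m = ag.sigmoid(self.mask_conv(m))
        return ag.mul(ag.add_scalar(m, 1.0), t)
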