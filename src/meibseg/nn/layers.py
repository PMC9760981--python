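"""Neural-network modules built on the autograd engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, max_pool2d, relu, upsample_bilinear2d

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "Upsample",
           "Sequential", "Identity"]


class Module:
    """Minimal module base: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    yield v

    def named_parameters(self, prefix=""):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # state dict includes buffers (running stats) alongside parameters
    def state_dict(self, prefix="", out=None):
        if out is None:
            out = {}
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[f"{prefix}{name}"] = v.data.copy()
            elif isinstance(v, np.ndarray):
                out[f"{prefix}{name}"] = v.copy()
            elif isinstance(v, Module):
                v.state_dict(f"{prefix}{name}.", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.state_dict(f"{prefix}{name}.{i}.", out)
        return out

    def load_state_dict(self, state: dict) -> None:
        own = {}
        self._collect_slots("", own)
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)[:5]} ...")
        for key, (holder, attr) in own.items():
            value = np.asarray(state[key])
            current = getattr(holder, attr)
            if isinstance(current, Tensor):
                current.data = value.astype(current.data.dtype).reshape(current.data.shape)
            else:
                setattr(holder, attr, value.astype(current.dtype).reshape(current.shape))

    def _collect_slots(self, prefix, out):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[f"{prefix}{name}"] = (self, name)
            elif isinstance(v, np.ndarray):
                out[f"{prefix}{name}"] = (self, name)
            elif isinstance(v, Module):
                v._collect_slots(f"{prefix}{name}.", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_slots(f"{prefix}{name}.{i}.", out)


class Conv2d(Module):
    """2-D convolution, He-initialized (fan-in, ReLU gain)."""

    def __init__(self, in_channels, out_channels, kernel_size, *, stride=1,
                 padding=0, dilation=1, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(out_channels, in_channels,
                                                        kernel_size, kernel_size)
                                        ).astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32),
                           requires_grad=True) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, num_features, *, eps=1e-5, momentum=0.1):
        super().__init__()
        self.gamma = Tensor(np.ones((1, num_features, 1, 1), dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, num_features, 1, 1), dtype=np.float32),
                           requires_grad=True)
        self.running_mean = np.zeros((1, num_features, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, num_features, 1, 1), dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return max_pool2d(x, kernel_size=self.kernel_size, stride=self.stride,
                          padding=self.padding)


class Upsample(Module):
    def __init__(self, scale_factor=2):
        super().__init__()
        self.scale_factor = scale_factor

    def forward(self, x):
        return upsample_bilinear2d(x, self.scale_factor)


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.items = list(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x
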