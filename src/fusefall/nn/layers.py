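"""Layer/module abstractions over the autodiff tensors."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batchnorm2d, clip, conv2d, depthwise_conv2d, relu

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "Dropout",
    "ReLU",
    "ReLU6",
    "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module tree: parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat named views of all parameters and batch-norm statistics."""
        out: dict[str, np.ndarray] = {}
        for i, m in enumerate(self.modules()):
            for name, v in vars(m).items():
                if isinstance(v, Parameter):
                    out[f"m{i}.{name}"] = v.data
                elif isinstance(v, np.ndarray) and name.startswith("running_"):
                    out[f"m{i}.{name}"] = v
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        if set(own) != set(arrays):
            raise ValueError("state keys do not match module structure")
        for key, arr in arrays.items():
            own[key][...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_he_normal(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        rng: np.random.Generator,
        stride=(1, 1),
        padding=(0, 0),
        bias: bool = True,
    ):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if np.isscalar(kernel_size) else kernel_size
        self.stride = (stride, stride) if np.isscalar(stride) else tuple(stride)
        self.padding = (padding, padding) if np.isscalar(padding) else tuple(padding)
        fan_in = in_channels * kh * kw
        self.weight = Parameter(_he_normal(rng, (out_channels, in_channels, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(
        self,
        channels: int,
        kernel_size,
        rng: np.random.Generator,
        stride=(1, 1),
        padding=(0, 0),
    ):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if np.isscalar(kernel_size) else kernel_size
        self.stride = (stride, stride) if np.isscalar(stride) else tuple(stride)
        self.padding = (padding, padding) if np.isscalar(padding) else tuple(padding)
        self.weight = Parameter(_he_normal(rng, (channels, kh, kw), kh * kw))

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight, self.stride, self.padding)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x.data - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu.ravel()
            self.running_var[...] = (1 - m) * self.running_var + m * var.ravel()
            inv_sd = 1.0 / np.sqrt(var + self.eps)
            return batchnorm2d(x, self.gamma, self.beta, mu, inv_sd, True)
        mu = self.running_mean[None, :, None, None].astype(x.data.dtype)
        inv_sd = (1.0 / np.sqrt(self.running_var + self.eps))[
            None, :, None, None
        ].astype(x.data.dtype)
        return batchnorm2d(x, self.gamma, self.beta, mu, inv_sd, False)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class ReLU6(Module):
    def forward(self, x: Tensor) -> Tensor:
        return clip(x, 0.0, 6.0)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
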