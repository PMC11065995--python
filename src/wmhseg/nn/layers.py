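"""Layer modules over the autodiff core: conv, batch-norm, containers."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batchnorm2d, conv2d, instancenorm2d

__all__ = ["Module", "Conv2d", "BatchNorm2d", "InstanceNorm2d", "Sequential", "trim_memory"]


class Module:
    """Base class: parameter discovery by attribute walk, train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def parameters(self):
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        """Flat name -> array mapping of parameters and buffers."""
        state = {}

        def walk(mod, prefix):
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    state[prefix + k] = v.data.copy()
                elif isinstance(v, np.ndarray):
                    state[prefix + k] = v.copy()
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")
        return state

    def load_state_dict(self, state: dict):
        def walk(mod, prefix):
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    v.data = np.asarray(state[prefix + k], dtype=v.data.dtype).copy()
                elif isinstance(v, np.ndarray):
                    arr = np.asarray(state[prefix + k], dtype=v.dtype)
                    v[...] = arr
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")
        return self


class Conv2d(Module):
    """Stride-1 'same' convolution; He-initialised, optionally grouped."""

    def __init__(self, cin, cout, k=3, groups=1, bias=True, rng=None):
        super().__init__()
        if cin % groups or cout % groups:
            raise ValueError("channels must be divisible by groups")
        rng = rng or np.random.default_rng()
        fan_in = (cin // groups) * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin // groups, k, k))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None
        self.padding = k // 2
        self.groups = groups

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class InstanceNorm2d(Module):
    """Affine instance norm; statistics per sample, identical train/eval."""

    def __init__(self, c, eps=1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return instancenorm2d(x, self.gamma, self.beta, self.eps)


def trim_memory():
    """Release collectible graph garbage and return freed arenas to the OS.

    Cheap; called between epochs and after batched inference to keep the
    resident set small on long CPU runs.
    """
    import ctypes
    import gc

    gc.collect()
    try:
        ctypes.CDLL("libc.so.6").malloc_trim(0)
    except OSError:  # non-glibc platform
        pass


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x
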