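"""Layer/module abstractions on top of the autograd engine.

Modules hold named parameter :class:`Tensor` objects and expose flat
``get_params``/``set_params`` dictionaries of numpy arrays, which is the
currency of the federated aggregation code.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Linear", "Conv2d", "ParamMismatchError", "layer_norm"]


def layer_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample standardization over the feature axis (no trainable affine).

    Deterministic per sample (no batch statistics)."""
    m = x.mean(axis=1, keepdims=True)
    c = x - m
    v = (c * c).mean(axis=1, keepdims=True)
    return c * ((v + eps) ** -0.5)


class ParamMismatchError(ValueError):
    """Shape or name mismatch when loading parameters."""


class Module:
    """Base class: children are discovered from instance attributes."""

    trainable: bool = True

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}" if prefix else name
            if isinstance(val, Tensor):
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        own = self.named_parameters()
        for name, arr in params.items():
            if name not in own:
                raise ParamMismatchError(f"unknown parameter {name!r}")
            if own[name].data.shape != np.asarray(arr).shape:
                raise ParamMismatchError(
                    f"shape mismatch for {name!r}: "
                    f"{own[name].data.shape} vs {np.asarray(arr).shape}"
                )
            own[name].data = np.asarray(arr, dtype=own[name].data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.named_parameters().values():
            p.grad = None


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)
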