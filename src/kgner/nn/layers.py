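"""Lightweight module system: named parameters, state dicts, common layers."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, embedding, parameter, xavier


class Module:
    """Base class: collects parameters from attributes, supports checkpoints."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=f"{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{name}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{name}.{i}", item

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> dict:
        """Copy arrays into parameters by name.

        Returns a report ``{"loaded": [...], "skipped": [...], "missing": [...]}``.
        In strict mode a shape mismatch or absent tensor raises ``ValueError``
        naming the first offending tensor.
        """
        own = dict(self.named_parameters())
        loaded, skipped = [], []
        for name, p in own.items():
            if name not in state:
                if strict:
                    raise ValueError(f"checkpoint missing tensor '{name}'")
                skipped.append(name)
                continue
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                if strict:
                    raise ValueError(
                        f"shape mismatch for tensor '{name}': "
                        f"checkpoint {arr.shape} vs model {p.data.shape}"
                    )
                skipped.append(name)
                continue
            p.data = arr.copy()
            loaded.append(name)
        missing = [k for k in state if k not in own]
        return {"loaded": loaded, "skipped": skipped, "missing": missing}

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = parameter(xavier(rng, d_in, d_out))
        self.b = parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Embedding(Module):
    def __init__(self, num: int, dim: int, rng: np.random.Generator, scale: float = 0.02):
        self.weight = parameter(rng.normal(0.0, scale, size=(num, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta
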