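"""Neural-network layers and the Adam optimizer on the autodiff engine.

Layers follow the familiar Module pattern: parameters are discoverable
recursively, ``train()``/``eval()`` toggle dropout and batch-norm
behaviour, and every stochastic layer draws from an explicit
``numpy.random.Generator`` so runs are reproducible bit for bit.
"""

from __future__ import annotations

import math
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from voxfuse._autodiff import Tensor, concat, frame1d, softmax
from voxfuse.errors import ValidationError


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> List[Tensor]:
        out: List[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def train(self) -> "Module":
        self.training = True
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.eval()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValidationError(
                        f"checkpoint shape mismatch for {name}: "
                        f"{value.shape} vs {params[name].data.shape}"
                    )
                params[name].data = value.copy()
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise ValidationError(f"unknown checkpoint entry {name!r}")

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.named_buffers(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{key}.{i}.")
            elif name.startswith("running_") and isinstance(v, np.ndarray):
                yield key, v


class Linear(Module):
    """Dense layer ``y = x W + b`` with He-uniform initialisation."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / d_in)
        self.W = Tensor(rng.uniform(-bound, bound, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= p < 1.0):
            raise ValidationError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class BatchNorm1d(Module):
    """Batch normalisation over the batch axis of (B, D) activations."""

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
            xhat = (x - mu) / (var + self.eps) ** 0.5
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    """Layer normalisation over the last axis."""

    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps) ** 0.5 * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention on (B, S, D) tokens."""

    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if d % heads != 0:
            raise ValidationError(f"model dim {d} not divisible by {heads} heads")
        self.d = d
        self.heads = heads
        self.d_head = d // heads
        self.Wq = Linear(d, d, rng)
        self.Wk = Linear(d, d, rng)
        self.Wv = Linear(d, d, rng)
        self.Wo = Linear(d, d, rng)
        self.last_attention: Optional[np.ndarray] = None  # (B, H, S, S), diagnostics

    def __call__(self, x: Tensor) -> Tensor:
        B, S, D = x.shape
        def split(t: Tensor) -> Tensor:  # (B, S, D) -> (B, H, S, d_head)
            return t.reshape(B, S, self.heads, self.d_head).permute(0, 2, 1, 3)

        q, k, v = split(self.Wq(x)), split(self.Wk(x)), split(self.Wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data
        out = attn @ v  # (B, H, S, d_head)
        out = out.permute(0, 2, 1, 3).reshape(B, S, D)
        return self.Wo(out)


class TransformerBlock(Module):
    """Pre-norm transformer block: x + MHSA(LN(x)), then x + FFN(LN(x))."""

    def __init__(self, d: int, heads: int, ffn_dim: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, heads, rng)
        self.ln2 = LayerNorm(d)
        self.ff1 = Linear(d, ffn_dim, rng)
        self.ff2 = Linear(ffn_dim, d, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.drop(self.attn(self.ln1(x)))
        return x + self.drop(self.ff2(self.ff1(self.ln2(x)).relu()))


class ConvStack(Module):
    """Strided 1-D convolution stack mapping (B, T, 1) audio to tokens.

    Each layer frames its input with (width, stride) and applies a dense
    map plus ReLU, i.e. a stride-s convolution.  The cumulative stride
    sets the token rate (320 at 16 kHz gives about 50 tokens/s).
    """

    def __init__(self, widths, strides, channels: int, rng: np.random.Generator):
        super().__init__()
        if len(widths) != len(strides):
            raise ValidationError("conv widths and strides must align")
        self.widths = tuple(widths)
        self.strides = tuple(strides)
        self.layers = []
        c_in = 1
        for w, s in zip(widths, strides):
            self.layers.append(Linear(w * c_in, channels, rng))
            c_in = channels

    @property
    def total_stride(self) -> int:
        return int(np.prod(self.strides))

    @property
    def receptive_field(self) -> int:
        rf, stride = 1, 1
        for w, s in zip(self.widths, self.strides):
            rf += (w - 1) * stride
            stride *= s
        return rf

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] < self.receptive_field:
            raise ValidationError(
                f"input of {x.shape[1]} samples is shorter than the conv "
                f"receptive field ({self.receptive_field})"
            )
        for layer, w, s in zip(self.layers, self.widths, self.strides):
            x = layer(frame1d(x, w, s)).relu()
        return x


class Adam:
    """Adam with decoupled-from-schedule L2 weight decay."""

    def __init__(self, params: List[Tensor], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
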