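"""Trainable layers composed from the autograd primitives."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Var


class Module:
    """Base class: tracks child modules and named parameters."""

    def named_parameters(self) -> list[tuple[str, Var]]:
        out: list[tuple[str, Var]] = []
        for name, attr in vars(self).items():
            if isinstance(attr, Var) and attr.requires_grad:
                out.append((name, attr))
            elif isinstance(attr, Module):
                out.extend((f"{name}.{n}", p)
                           for n, p in attr.named_parameters())
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.extend((f"{name}.{i}.{n}", p)
                                   for n, p in item.named_parameters())
        return out

    def parameters(self) -> list[Var]:
        return [p for _, p in self.named_parameters()]

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _param(data: np.ndarray) -> Var:
    return Var(data.astype(np.float32), requires_grad=True)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = 0.02
        self.w = _param(rng.normal(0.0, scale, (d_in, d_out)))
        self.b = _param(np.zeros(d_out))

    def __call__(self, x: Var) -> Var:
        return ag.matmul(x, self.w) + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = _param(np.ones(dim))
        self.beta = _param(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Var) -> Var:
        m = ag.vmean(x, axis=-1, keepdims=True)
        d = x - m
        v = ag.vmean(ag.mul(d, d), axis=-1, keepdims=True)
        inv = ag.power(v + self.eps, -0.5)
        return ag.mul(ag.mul(d, inv), self.gamma) + self.beta


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over spatial dims, affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = _param(np.ones((1, channels, 1, 1, 1)))
        self.beta = _param(np.zeros((1, channels, 1, 1, 1)))
        self.eps = eps

    def __call__(self, x: Var) -> Var:
        ax = (-3, -2, -1)
        m = ag.vmean(x, axis=ax, keepdims=True)
        d = x - m
        v = ag.vmean(ag.mul(d, d), axis=ax, keepdims=True)
        inv = ag.power(v + self.eps, -0.5)
        return ag.mul(ag.mul(d, inv), self.gamma) + self.beta


class Conv3(Module):
    """3x3x3 convolution, stride 1, padding 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 27
        self.w = _param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                   (c_out, c_in, 3, 3, 3)))
        self.b = _param(np.zeros(c_out))

    def __call__(self, x: Var) -> Var:
        return ag.conv3d(x, self.w, self.b)


class Conv1(Module):
    """1x1x1 convolution (the classification head)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = _param(rng.normal(0.0, np.sqrt(2.0 / c_in), (c_out, c_in)))
        self.b = _param(np.zeros(c_out))

    def __call__(self, x: Var) -> Var:
        return ag.conv1x1(x, self.w, self.b)


class Deconv2(Module):
    """Transposed convolution, kernel 2, stride 2 (x2 upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = _param(rng.normal(0.0, np.sqrt(2.0 / (c_in * 8)),
                                   (c_in, c_out, 2, 2, 2)))
        self.b = _param(np.zeros(c_out))

    def __call__(self, x: Var) -> Var:
        return ag.deconv2x2(x, self.w, self.b)


def gelu(x: Var) -> Var:
    inner = ag.erf(ag.mul_scalar(x, 1.0 / np.sqrt(2.0)))
    return ag.mul_scalar(ag.mul(x, inner + 1.0), 0.5)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"embed dim {dim} not divisible by {heads} heads")
        self.heads = heads
        self.head_dim = dim // heads
        self.q = Dense(dim, dim, rng)
        self.k = Dense(dim, dim, rng)
        self.v = Dense(dim, dim, rng)
        self.proj = Dense(dim, dim, rng)

    def __call__(self, x: Var, drop: float = 0.0,
                 rng: np.random.Generator | None = None) -> Var:
        B, N, K = x.shape
        h, dh = self.heads, self.head_dim

        def split(t: Var) -> Var:  # (B,N,K) -> (B,h,N,dh)
            return ag.transpose(ag.reshape(t, (B, N, h, dh)), (0, 2, 1, 3))

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = ag.mul_scalar(
            ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
        attn = ag.softmax(scores, axis=-1)
        out = ag.matmul(attn, v)  # (B,h,N,dh)
        out = ag.reshape(ag.transpose(out, (0, 2, 1, 3)), (B, N, K))
        out = self.proj(out)
        if drop > 0 and rng is not None:
            out = ag.dropout(out, drop, rng)
        return out


class EncoderBlock(Module):
    """Pre-norm transformer block: LN -> MHSA -> LN -> MLP, residual."""

    def __init__(self, dim: int, heads: int, mlp_dim: int,
                 rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Dense(dim, mlp_dim, rng)
        self.fc2 = Dense(mlp_dim, dim, rng)

    def __call__(self, x: Var, drop: float = 0.0,
                 rng: np.random.Generator | None = None) -> Var:
        x = x + self.attn(self.ln1(x), drop, rng)
        h = gelu(self.fc1(self.ln2(x)))
        if drop > 0 and rng is not None:
            h = ag.dropout(h, drop, rng)
        return x + self.fc2(h)
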