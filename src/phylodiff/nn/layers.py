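"""Neural-network building blocks on top of the autodiff engine.

Initialisation follows the usual fan-in scaling; every module draws its
parameters from a caller-supplied :class:`numpy.random.Generator` so that
model construction is fully reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concatenate

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiheadSelfAttention",
    "TransformerEncoderLayer",
    "BlockConv1d",
    "GRU",
    "diffusion_step_embedding",
]


class Module:
    """Base class: parameter collection and train/eval bookkeeping."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        from .autograd import get_dtype
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=get_dtype())


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = 1.0 / math.sqrt(d_in)
        self.W = Tensor(rng.uniform(-scale, scale, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim > 2:
            # one flat GEMM is much faster than a broadcast batched matmul
            lead = x.shape[:-1]
            flat = x.reshape(int(np.prod(lead)), x.shape[-1])
            return (flat @ self.W + self.b).reshape(*lead, self.W.shape[1])
        return x @ self.W + self.b


class LayerNorm(Module):
    """Normalisation over the trailing axis, fused into one tape node."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        centered = x.data - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = centered * inv
        out_data = xhat * self.gamma.data + self.beta.data
        gamma, beta = self.gamma, self.beta

        def backward(g):
            gg = g * gamma.data
            m1 = gg.mean(axis=-1, keepdims=True)
            m2 = (gg * xhat).mean(axis=-1, keepdims=True)
            dx = (gg - m1 - xhat * m2) * inv
            axes = tuple(range(g.ndim - 1))
            return (dx, (g * xhat).sum(axis=axes), g.sum(axis=axes))

        return x._make(out_data, (x, gamma, beta), backward)


class MultiheadSelfAttention(Module):
    def __init__(self, d_model: int, heads: int, rng: np.random.Generator):
        if d_model % heads:
            raise ValueError("d_model must be divisible by heads")
        self.heads = heads
        self.d_head = d_model // heads
        self.qkv = Linear(d_model, 3 * d_model, rng)   # fused projection
        self.out = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        # x: [B, S, d_model]
        B, S, D = x.shape
        h, dh = self.heads, self.d_head
        qkv = self.qkv(x)

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, S, h, dh).transpose(0, 2, 1, 3)  # [B,h,S,dh]

        q = split(qkv[:, :, :D])
        k = split(qkv[:, :, D:2 * D])
        v = split(qkv[:, :, 2 * D:])
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, S, D)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Single pre-norm transformer encoder block."""

    def __init__(self, d_model: int, heads: int, d_ff: int, rng: np.random.Generator):
        self.attn = MultiheadSelfAttention(d_model, heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.ff2(self.ff1(self.norm2(x)).relu())
        return x


class BlockConv1d(Module):
    """Per-block 1-D convolution along the last (feature) axis.

    Each contiguous feature block gets its own kernel of odd width with
    same-padding; block outputs are concatenated back to the full width.
    Input ``[B, C_in, L, K]`` -> output ``[B, C_out, L, K]``.
    """

    def __init__(self, blocks: list[tuple[int, int]], c_in: int, c_out: int,
                 kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel width must be odd")
        self.blocks = list(blocks)  # (start, stop) half-open per block
        self.kernel = kernel
        scale = 1.0 / math.sqrt(c_in * kernel)
        self.weights = [
            Tensor(rng.uniform(-scale, scale, (kernel, c_in, c_out)), requires_grad=True)
            for _ in self.blocks
        ]
        self.biases = [
            Tensor(np.zeros(c_out), requires_grad=True) for _ in self.blocks
        ]

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def __call__(self, x: Tensor) -> Tensor:
        half = self.kernel // 2
        outs = []
        for (start, stop), W, b in zip(self.blocks, self.weights, self.biases):
            seg = x[:, :, :, start:stop]            # [B,Cin,L,w]
            padded = seg.pad_axis(3, half, half)
            w = stop - start
            # y[...,j] = sum_o W[o] applied at padded position j+o
            acc = None
            for o in range(self.kernel):
                window = padded[:, :, :, o:o + w]    # [B,Cin,L,w]
                # contract channel axis: [B,Cin,L,w] x [Cin,Cout] -> [B,Cout,L,w]
                term = (window.transpose(0, 2, 3, 1) @ W[o]).transpose(0, 3, 1, 2)
                acc = term if acc is None else acc + term
            outs.append(acc + b.reshape(1, -1, 1, 1))
        return concatenate(outs, axis=3)


class GRU(Module):
    """Unidirectional gated recurrent unit over ``[B, L, d_in]`` sequences."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.x2g = Linear(d_in, 3 * d_hidden, rng)   # reset, update, candidate
        self.h2g = Linear(d_hidden, 3 * d_hidden, rng)

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        """Return the final hidden state [B, d_hidden]."""
        B, L, _ = x.shape
        H = self.d_hidden
        h = Tensor(np.zeros((B, H)))
        steps = range(L - 1, -1, -1) if reverse else range(L)
        for l in steps:
            xt = x[:, l, :]
            gx = self.x2g(xt)
            gh = self.h2g(h)
            r = (gx[:, :H] + gh[:, :H]).sigmoid()
            z = (gx[:, H:2 * H] + gh[:, H:2 * H]).sigmoid()
            n = (gx[:, 2 * H:] + r * gh[:, 2 * H:]).tanh()
            h = (1.0 - z) * n + z * h
        return h


def diffusion_step_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal embedding of diffusion steps ``t`` (array of ints) -> [B, dim]."""
    half = dim // 2
    t = np.asarray(t, dtype=np.float64).reshape(-1, 1)
    freqs = 10.0 ** (np.arange(half) / max(half - 1, 1) * 4.0)
    angles = t / freqs[None, :]
    return np.concatenate([np.sin(angles), np.cos(angles)], axis=1)
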