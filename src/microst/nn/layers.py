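"""Layers for the spatio-temporal forecaster, built on the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, einsum2

__all__ = [
    "Module",
    "Linear",
    "TemporalConvGLU",
    "SpatialMix",
    "StackedLSTM",
]


class Module:
    """Parameter container with recursive discovery, torch-style."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    """Affine map on the last axis: y = x @ W + b, W of shape (in, out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.weight) + self.bias


class TemporalConvGLU(Module):
    """Causal 1-D convolution along the time axis with a gated output.

    Input layout (B, C_in, N, T). The time axis is left-padded with k-1
    zeros so the output keeps length T and entry t only sees inputs at
    times <= t. With ``activation='glu'`` the convolution produces 2*C_out
    channels split into a linear path P and gate path Q, returning
    P * sigmoid(Q) — the "linear and non-linear activations" of the block.
    ``activation='linear'`` returns the raw convolution (used in tests and
    as the final projection of a stream).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel_size: int,
        rng: np.random.Generator,
        activation: str = "glu",
    ):
        if activation not in ("glu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.c_out = c_out
        self.kernel_size = kernel_size
        mult = 2 if activation == "glu" else 1
        fan_in = c_in * kernel_size
        self.weight = _glorot(
            rng, (mult * c_out, c_in, kernel_size), fan_in, c_out
        )
        self.bias = Tensor(np.zeros(mult * c_out), requires_grad=True)

    def conv(self, x: Tensor) -> Tensor:
        """Pre-activation causal convolution, output (B, mult*C_out, N, T)."""
        k = self.kernel_size
        t = x.shape[-1]
        if k > t + (k - 1):
            raise ValueError("kernel larger than padded time axis")
        xp = x.pad_last(k - 1)
        out = None
        # sum_j W[:, :, j] * x[..., t - j]: tap j uses lag j
        for j in range(k):
            shifted = xp[:, :, :, k - 1 - j : k - 1 - j + t]
            term = einsum2("oc,bcnt->bont", self.weight[:, :, j], shifted)
            out = term if out is None else out + term
        return out + self.bias.reshape(1, -1, 1, 1)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.activation == "linear":
            return y
        p = y[:, : self.c_out]
        q = y[:, self.c_out :]
        return p * q.sigmoid()


class SpatialMix(Module):
    """Graph aggregation over the normalized adjacency plus a channel mix.

    lfs[b, c, i, t] = sum_j Ahat[i, j] * x[b, c, j, t], followed by a
    learned 1x1 channel mixing and a ReLU. The contraction is the only
    place information crosses nodes.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.weight = _glorot(rng, (c_out, c_in), c_in, c_out)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor, a_hat: np.ndarray) -> Tensor:
        if a_hat.shape[0] != x.shape[2]:
            raise ValueError(
                f"adjacency is {a_hat.shape[0]}x{a_hat.shape[1]} but input "
                f"has {x.shape[2]} nodes"
            )
        lfs = einsum2("ij,bcjt->bcit", Tensor(a_hat), x)
        mixed = einsum2("oc,bcnt->bont", self.weight, lfs)
        return (mixed + self.bias.reshape(1, -1, 1, 1)).relu()


class _LSTMLayer(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        # gate order: input, forget, cell, output
        self.w_ih = _glorot(rng, (n_in, 4 * hidden), n_in, hidden)
        self.w_hh = _glorot(rng, (hidden, 4 * hidden), hidden, hidden)
        self.bias = Tensor(np.zeros(4 * hidden), requires_grad=True)

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        gates = (x_t @ self.w_ih) + (h @ self.w_hh) + self.bias
        hs = self.hidden
        i = gates[:, 0 * hs : 1 * hs].sigmoid()
        f = gates[:, 1 * hs : 2 * hs].sigmoid()
        g = gates[:, 2 * hs : 3 * hs].tanh()
        o = gates[:, 3 * hs : 4 * hs].sigmoid()
        c_new = (f * c) + (i * g)
        h_new = o * c_new.tanh()
        return h_new, c_new


class StackedLSTM(Module):
    """Deep recurrent branch: `n_layers` gated layers over the time axis.

    Each unit has input, forget and output gates plus a memory cell; the
    output of every layer feeds the next. Returns the top layer's hidden
    state at the final step, whose entries are bounded in (-1, 1) by the
    tanh cell output times a sigmoid gate.
    """

    def __init__(
        self,
        n_in: int,
        hidden: int,
        n_layers: int,
        rng: np.random.Generator,
    ):
        self.hidden = hidden
        self.layers = [
            _LSTMLayer(n_in if i == 0 else hidden, hidden, rng)
            for i in range(n_layers)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, T, n_in) -> last hidden state (B, hidden)."""
        batch, t_steps, _ = x.shape
        h = [Tensor(np.zeros((batch, self.hidden))) for _ in self.layers]
        c = [Tensor(np.zeros((batch, self.hidden))) for _ in self.layers]
        for t in range(t_steps):
            inp = x[:, t, :]
            for li, layer in enumerate(self.layers):
                h[li], c[li] = layer.step(inp, h[li], c[li])
                inp = h[li]
        return h[-1]
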