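"""Neural-network layers and the Adam optimizer on top of the autodiff core.

Layers follow the usual Module convention: parameters are discovered by
recursion over attributes, ``train()``/``eval()`` toggle batch-norm
behaviour, and forward passes build an autodiff graph.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, conv2d_patches

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm1d",
    "BiLSTM",
    "AttentionPool",
    "Adam",
]


class Module:
    """Base class; children and parameters are found by attribute scan."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        for mod in self.modules():
            prefix = mod.__class__.__name__
            for name, value in mod.__dict__.items():
                if isinstance(value, Tensor) and value.requires_grad:
                    yield f"{prefix}.{name}@{id(value)}", value

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self):
        for mod in self.modules():
            mod.training = True

    def eval(self):
        for mod in self.modules():
            mod.training = False

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.data.copy()
        for j, mod in enumerate(self.modules()):
            if isinstance(mod, BatchNorm1d):
                state[f"bn_{j}_mean"] = mod.running_mean.copy()
                state[f"bn_{j}_var"] = mod.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for i, p in enumerate(self.parameters()):
            p.data = state[f"param_{i}"].copy()
        for j, mod in enumerate(self.modules()):
            if isinstance(mod, BatchNorm1d):
                mod.running_mean = state[f"bn_{j}_mean"].copy()
                mod.running_var = state[f"bn_{j}_var"].copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(in_features, out_features)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """k x k convolution via im2col + matmul; optional stride and padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
    ):
        super().__init__()
        self.k = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            _kaiming(rng, fan_in, (fan_in, out_channels)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        patches, ho, wo = conv2d_patches(x, self.k, self.stride, self.padding)
        out = patches @ self.weight + self.bias  # (N, Ho*Wo, Cout)
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)


class BatchNorm1d(Module):
    """Feature-wise normalization over the batch axis of (N, F) input."""

    def __init__(self, num_features: int, momentum: float = 0.2, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mean = x.mean(axis=0, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mean.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.ravel()
            )
            xhat = (x - mean) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * (
                Tensor(self.running_var + self.eps) ** -0.5
            )
        return xhat * self.gamma + self.beta


class _LSTMCellParams(Module):
    """Gate weights for one direction of one LSTM layer (i, f, g, o stacked)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / math.sqrt(hidden_size)
        self.w_x = Tensor(
            rng.uniform(-bound, bound, size=(input_size, 4 * hidden_size)),
            requires_grad=True,
        )
        self.w_h = Tensor(
            rng.uniform(-bound, bound, size=(hidden_size, 4 * hidden_size)),
            requires_grad=True,
        )
        bias = np.zeros(4 * hidden_size)
        bias[hidden_size : 2 * hidden_size] = 1.0  # forget-gate bias init
        self.bias = Tensor(bias, requires_grad=True)
        self.hidden_size = hidden_size

    def run(self, xs: list[Tensor]) -> list[Tensor]:
        """Run the recurrence over a list of (B, F) timesteps."""
        h_size = self.hidden_size
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, h_size)))
        c = Tensor(np.zeros((batch, h_size)))
        outs = []
        for x_t in xs:
            gates = x_t @ self.w_x + h @ self.w_h + self.bias
            i = gates[:, 0 * h_size : 1 * h_size].sigmoid()
            f = gates[:, 1 * h_size : 2 * h_size].sigmoid()
            g = gates[:, 2 * h_size : 3 * h_size].tanh()
            o = gates[:, 3 * h_size : 4 * h_size].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return outs


class BiLSTM(Module):
    """Stack of bidirectional LSTM layers over a slice sequence.

    Input: list of D tensors of shape (B, F); output: list of D tensors of
    shape (B, 2*hidden) with forward and backward states concatenated.
    """

    def __init__(
        self,
        input_size: int,
        hidden_size: int,
        num_layers: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.layers: list[tuple[_LSTMCellParams, _LSTMCellParams]] = []
        size = input_size
        for _ in range(num_layers):
            fwd = _LSTMCellParams(size, hidden_size, rng)
            bwd = _LSTMCellParams(size, hidden_size, rng)
            self.layers.append((fwd, bwd))
            size = 2 * hidden_size
        self.output_size = size

    def modules(self):
        yield self
        for fwd, bwd in self.layers:
            yield from fwd.modules()
            yield from bwd.modules()

    def forward(self, xs: list[Tensor]) -> list[Tensor]:
        seq = xs
        for fwd, bwd in self.layers:
            out_f = fwd.run(seq)
            out_b = bwd.run(seq[::-1])[::-1]
            seq = [concat([f, b], axis=1) for f, b in zip(out_f, out_b)]
        return seq


class AttentionPool(Module):
    """Gated tanh-scored softmax attention over per-slice hidden states.

    score_i = w2 . tanh(W1 h_i); weights = softmax over slices; the pooled
    exam representation is the weighted sum of hidden states.
    """

    def __init__(self, in_features: int, attention_dim: int, rng: np.random.Generator):
        super().__init__()
        self.w1 = Linear(in_features, attention_dim, rng)
        self.w2 = Linear(attention_dim, 1, rng)

    def forward(self, hidden: Tensor):
        """hidden: (B, D, F) -> pooled (B, F), weights (B, D)."""
        b, d, f = hidden.shape
        scores = self.w2(self.w1(hidden.reshape(b * d, f)).tanh())
        weights = scores.reshape(b, d).softmax(axis=1)
        pooled = (hidden * weights.reshape(b, d, 1)).sum(axis=1)
        return pooled, weights


class Adam:
    """Adam with the standard bias correction; lr is mutable between steps."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
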