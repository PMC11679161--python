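"""Neural-network layers for 1-D biosignal sequences, built on the autodiff core.

Layout convention is channels-last: activations are ``(batch, length,
channels)``.  Convolutions are implemented by gathering dilated patches
(im2col) and a single matmul, which keeps the per-step cost dominated by BLAS.

Two padding modes exist:

* ``"same"`` — symmetric zero padding so output length equals input length
  (used inside the multi-branch front end);
* ``"causal"`` — left-only zero padding so the output at time ``t`` depends
  only on inputs at times ``<= t`` (used inside the TCN residual blocks).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate

__all__ = [
    "Layer", "Conv1d", "MaxPool1d", "BatchNorm1d", "Dense", "Dropout",
    "ReLU", "MultiHeadAttention", "Flatten", "Sequential", "glorot_uniform",
    "conv1d", "maxpool1d",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def conv1d(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1,
           padding: str = "same") -> Tensor:
    """Dilated 1-D convolution, y_t = sum_i f_i * x_{t - d*i} (causal form).

    ``x``: (B, L, Cin); ``w``: (k, Cin, Cout); ``b``: (Cout,).
    Output length equals input length for both padding modes.
    """
    B, L, Cin = x.shape
    k, _, Cout = w.shape
    eff = (k - 1) * dilation + 1
    if padding == "causal":
        left, right = eff - 1, 0
    elif padding == "same":
        left = (eff - 1) // 2
        right = eff - 1 - left
    else:  # pragma: no cover
        raise ValueError(f"unknown padding {padding!r}")

    xp = np.pad(x.data, ((0, 0), (left, right), (0, 0)))
    # tap i multiplies x_{t - d*i} (causal orientation); in the padded
    # signal that is position t + (k-1-i)*d — gathered as a contiguous
    # slice per tap (far cheaper than fancy indexing)
    cols = np.empty((B, L, k, Cin))
    for i in range(k):
        off = (k - 1 - i) * dilation
        cols[:, :, i, :] = xp[:, off:off + L, :]
    cols2 = cols.reshape(B * L, k * Cin)
    wmat = w.data.reshape(k * Cin, Cout)
    out_data = (cols2 @ wmat).reshape(B, L, Cout) + b.data

    prev = tuple(t for t in (x, w, b) if t.requires_grad)
    out = Tensor(out_data, requires_grad=bool(prev), _prev=prev)

    if prev:
        def backward(g):                       # g: (B, L, Cout)
            g2 = g.reshape(B * L, Cout)
            if w.requires_grad:
                w._accumulate((cols2.T @ g2).reshape(k, Cin, Cout))
            if b.requires_grad:
                b._accumulate(g2.sum(axis=0))
            if x.requires_grad:
                gcols = (g2 @ wmat.T).reshape(B, L, k, Cin)
                gxp = np.zeros_like(xp)
                for i in range(k):
                    off = (k - 1 - i) * dilation
                    gxp[:, off:off + L, :] += gcols[:, :, i, :]
                x._accumulate(gxp[:, left:left + L, :])

        out._backward = backward
    return out


def maxpool1d(x: Tensor, pool: int = 2, stride: int = 2) -> Tensor:
    """Non-overlapping max pooling (pool == stride); output length floor(L/pool)."""
    if pool != stride:  # pragma: no cover
        raise ValueError("only pool == stride is supported")
    B, L, C = x.shape
    Lo = L // pool
    xt = x.data[:, :Lo * pool, :].reshape(B, Lo, pool, C)
    arg = xt.argmax(axis=2)                    # (B, Lo, C)
    out_data = np.take_along_axis(xt, arg[:, :, None, :], axis=2)[:, :, 0, :]

    out = Tensor(out_data, requires_grad=x.requires_grad,
                 _prev=(x,) if x.requires_grad else ())
    if x.requires_grad:
        def backward(g):
            gx = np.zeros((B, Lo, pool, C))
            np.put_along_axis(gx, arg[:, :, None, :], g[:, :, None, :], axis=2)
            full = np.zeros_like(x.data)
            full[:, :Lo * pool, :] = gx.reshape(B, Lo * pool, C)
            x._accumulate(full)

        out._backward = backward
    return out


class Layer:
    """Base class: parameter registry plus train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        return []

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All persistent arrays (trainable + running statistics)."""
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def set_training(self, flag: bool) -> None:
        self.training = flag

    def __call__(self, x: Tensor) -> Tensor:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int = 1, padding: str = "same", *,
                 rng: np.random.Generator):
        super().__init__()
        self.dilation = dilation
        self.padding = padding
        fan_in = kernel_size * in_channels
        self.w = Tensor(glorot_uniform(rng, (kernel_size, in_channels,
                                             out_channels),
                                       fan_in, out_channels),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_channels), requires_grad=True)

    def parameters(self):
        return [self.w, self.b]

    def __call__(self, x):
        return conv1d(x, self.w, self.b, self.dilation, self.padding)


class MaxPool1d(Layer):
    def __init__(self, pool: int = 2, stride: int = 2):
        super().__init__()
        self.pool, self.stride = pool, stride

    def __call__(self, x):
        return maxpool1d(x, self.pool, self.stride)


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, time); channels-last input."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.99):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._epoch_mean = np.zeros(channels)
        self._epoch_var = np.zeros(channels)
        self._epoch_batches = 0

    def parameters(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return {"gamma": self.gamma.data, "beta": self.beta.data,
                "running_mean": self.running_mean,
                "running_var": self.running_var}

    def __call__(self, x):
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.ravel()
            self.running_var = m * self.running_var + (1 - m) * var.data.ravel()
            self._epoch_mean += mu.data.ravel()
            self._epoch_var += var.data.ravel()
            self._epoch_batches += 1
            xhat = centered * (var + self.eps).pow(-0.5)
        else:
            xhat = (x - self.running_mean) * \
                (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta

    def commit_epoch_stats(self) -> None:
        """Snap running statistics to the average of this epoch's batch
        statistics ('precise' re-estimation), then reset the accumulator.

        The EMA update with the configured momentum needs many hundreds of
        steps to forget its (0, 1) initialization; averaging the epoch's
        batch moments gives inference-mode statistics that match the trained
        network at any training scale.
        """
        if self._epoch_batches > 0:
            self.running_mean = self._epoch_mean / self._epoch_batches
            self.running_var = self._epoch_var / self._epoch_batches
        self._epoch_mean[...] = 0.0
        self._epoch_var[...] = 0.0
        self._epoch_batches = 0


class ReLU(Layer):
    def __call__(self, x):
        return x.relu()


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.w = Tensor(glorot_uniform(rng, (in_features, out_features),
                                       in_features, out_features),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_features), requires_grad=True)

    def parameters(self):
        return [self.w, self.b]

    def __call__(self, x):
        return x @ self.w + self.b


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. Draws from a shared RNG."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def __call__(self, x):
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * mask


class Flatten(Layer):
    def __call__(self, x):
        return x.reshape(x.shape[0], -1)


class MultiHeadAttention(Layer):
    """Scaled dot-product self-attention with h heads over a (B, L, d) sequence.

    Per head i: Q_i = X W_i^Q, K_i = X W_i^K, V_i = X W_i^V, each d x d_k with
    d_k = d / h; head_i = softmax(Q_i K_i^T / sqrt(d_k)) V_i; the heads are
    concatenated and projected by W^O of shape (h*d_k, d).  The last computed
    attention weights are kept on ``last_attention`` for inspection.
    """

    def __init__(self, d_model: int, num_heads: int, *, rng: np.random.Generator):
        super().__init__()
        if d_model % num_heads != 0:
            raise ValueError(
                f"model dimension {d_model} not divisible by heads {num_heads}")
        self.h = num_heads
        self.d = d_model
        self.d_k = d_model // num_heads
        def mk():
            return Tensor(glorot_uniform(rng, (d_model, d_model),
                                         d_model, d_model), requires_grad=True)
        self.w_q, self.w_k, self.w_v, self.w_o = mk(), mk(), mk(), mk()
        self.last_attention: np.ndarray | None = None

    def parameters(self):
        return [self.w_q, self.w_k, self.w_v, self.w_o]

    def _split(self, t: Tensor, B: int, L: int) -> Tensor:
        return t.reshape(B, L, self.h, self.d_k).transpose((0, 2, 1, 3))

    def __call__(self, x):
        B, L, _ = x.shape
        q = self._split(x @ self.w_q, B, L)       # (B, h, L, d_k)
        k = self._split(x @ self.w_k, B, L)
        v = self._split(x @ self.w_v, B, L)
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(self.d_k))
        attn = scores.softmax(axis=-1)            # rows sum to 1
        self.last_attention = attn.data
        heads = attn @ v                          # (B, h, L, d_k)
        merged = heads.transpose((0, 2, 1, 3)).reshape(B, L, self.d)
        return merged @ self.w_o


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def parameters(self):
        return [p for lay in self.layers for p in lay.parameters()]

    def state_arrays(self):
        out = {}
        for i, lay in enumerate(self.layers):
            for name, arr in lay.state_arrays().items():
                out[f"{i}.{lay.__class__.__name__}.{name}"] = arr
        return out

    def set_training(self, flag):
        super().set_training(flag)
        for lay in self.layers:
            lay.set_training(flag)

    def __call__(self, x):
        for lay in self.layers:
            x = lay(x)
        return x
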