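"""The MB-MHA-TCN network: multi-branch dilated convolutions, multi-head
self-attention, and a lightweight dilated-causal TCN with residual blocks.

Architecture (input: one beat of 250 samples, single channel):

1. **Three parallel branches.**  Each branch applies conv(kernel_1, dilation 1)
   -> ReLU -> batch-norm -> max-pool(2,2) -> conv(kernel_1 // 2, dilation_2)
   -> ReLU -> batch-norm -> max-pool(2,2), with length-preserving padding, so
   each branch emits floor(floor(L/2)/2) time steps.  Default kernels are
   4 / 14 / 62 with second-layer dilations 1 / 2 / 4 — small kernels see
   QRS-scale detail, large kernels see P/T-scale context.
2. **Concatenation + normalization** of the branch feature maps along
   channels.
3. **Multi-head self-attention** (default 4 heads) re-weights and mixes the
   fused features; no positional encoding is injected, so the attention
   stage is permutation-equivariant over time steps.
4. **TCN stack**: residual blocks of two dilated causal convolutions each
   (ReLU, batch-norm, dropout), dilation doubling 1, 2, 4, 8 so the
   receptive field grows exponentially with depth.
5. **Flatten -> dense softmax head** over the five AAMI classes, with an L2
   penalty on the dense weights.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn.autodiff import Tensor, concatenate
from .nn.layers import (BatchNorm1d, Conv1d, Dense, Dropout, Flatten, Layer,
                        MaxPool1d, MultiHeadAttention, ReLU, Sequential,
                        conv1d)

__all__ = [
    "BranchConfig", "ModelConfig", "Model", "ResidualBlock", "build_model",
    "param_count", "receptive_field", "dilated_causal_conv",
    "concat_branches", "branch_output_length", "branch_forward",
    "multi_head_attention",
]


@dataclass(frozen=True)
class BranchConfig:
    """One convolutional branch; the second kernel is half the first."""

    kernel_1: int
    filters: int = 16
    dilation_2: int = 1
    filters_2: int | None = None      # defaults to ``filters``
    pool: int = 2

    def __post_init__(self):
        if self.kernel_1 < 2:
            raise ValueError("kernel_1 must be >= 2")
        if self.dilation_2 not in (1, 2, 4):
            raise ValueError("dilation_2 must be one of 1, 2, 4")

    @property
    def kernel_2(self) -> int:
        return max(self.kernel_1 // 2, 1)

    @property
    def out_channels(self) -> int:
        return self.filters_2 if self.filters_2 is not None else self.filters


@dataclass(frozen=True)
class ModelConfig:
    """Full architecture description with the tuned defaults."""

    input_length: int = 250
    branches: tuple[BranchConfig, ...] = (
        BranchConfig(kernel_1=4, dilation_2=1),
        BranchConfig(kernel_1=14, dilation_2=2),
        BranchConfig(kernel_1=62, dilation_2=4),
    )
    heads: int = 4
    tcn_layers: int = 4
    tcn_filters: int = 10
    tcn_kernel: int = 8
    dropout_rate: float = 0.4
    l2_lambda: float = 1e-4
    n_classes: int = 5

    def __post_init__(self):
        if len(self.branches) < 1:
            raise ValueError("need at least one branch")
        d = self.d_model
        if d % self.heads != 0:
            raise ValueError(
                f"fused channel count {d} not divisible by heads={self.heads}")
        if self.n_classes != 5:
            raise ValueError("the classifier is defined for the 5 AAMI classes")
        if self.input_length < 4:
            raise ValueError("input too short to pool twice")

    @property
    def d_model(self) -> int:
        return sum(b.out_channels for b in self.branches)

    @property
    def seq_length(self) -> int:
        return branch_output_length(self.input_length)

    @property
    def tcn_dilations(self) -> tuple[int, ...]:
        return tuple(2 ** i for i in range(self.tcn_layers))

    @classmethod
    def optimized(cls) -> "ModelConfig":
        """The tuned compact configuration (the package default)."""
        return cls()

    @classmethod
    def wide_template(cls) -> "ModelConfig":
        """The wider published layer template: kernels 12/22/48 with 48->64
        channel growth per branch and a 6-filter TCN."""
        return cls(branches=(
            BranchConfig(kernel_1=12, filters=48, filters_2=64, dilation_2=1),
            BranchConfig(kernel_1=22, filters=48, filters_2=64, dilation_2=2),
            BranchConfig(kernel_1=48, filters=48, filters_2=64, dilation_2=4),
        ), tcn_filters=6)

    def to_json(self) -> str:
        d = asdict(self)
        d["branches"] = [asdict(b) for b in self.branches]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["branches"] = tuple(BranchConfig(**b) for b in d["branches"])
        return cls(**d)


def branch_output_length(L: int, pool: int = 2) -> int:
    """Temporal length after two (2,2) max-pools: floor(floor(L/2)/2)."""
    return (L // pool) // pool


def dilated_causal_conv(x: np.ndarray, taps: np.ndarray,
                        dilation: int = 1) -> np.ndarray:
    """Reference dilated causal convolution on a plain 1-D sequence.

    y_t = sum_{i=0}^{k-1} f_i * x_{t - d*i}, with left zero-padding; the
    output has the input's length and y_t depends only on x_{<=t}.
    """
    x = np.asarray(x, dtype=np.float64)
    taps = np.asarray(taps, dtype=np.float64)
    if dilation < 1 or taps.size < 1:
        raise ValueError("need dilation >= 1 and at least one tap")
    y = np.zeros_like(x)
    for i, f in enumerate(taps):
        shift = dilation * i
        if shift == 0:
            y += f * x
        elif shift < x.size:
            y[shift:] += f * x[:-shift]
    return y


def branch_forward(x: np.ndarray, cfg: BranchConfig,
                   seed: int = 0) -> np.ndarray:
    """Run one freshly initialized branch over a (B, L) or (B, L, 1) batch.

    Convenience wrapper realizing the branch as a standalone operation;
    inside a full model the branches are stateful submodules.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, :, None]
    L = x.shape[1]
    if branch_output_length(L, cfg.pool) < 1:
        raise ValueError(f"input length {L} too short to pool twice")
    rng = np.random.default_rng(seed)
    branch = Sequential(
        Conv1d(1, cfg.filters, cfg.kernel_1, dilation=1, padding="same",
               rng=rng),
        ReLU(), BatchNorm1d(cfg.filters), MaxPool1d(cfg.pool, cfg.pool),
        Conv1d(cfg.filters, cfg.out_channels, cfg.kernel_2,
               dilation=cfg.dilation_2, padding="same", rng=rng),
        ReLU(), BatchNorm1d(cfg.out_channels), MaxPool1d(cfg.pool, cfg.pool),
    )
    return branch(Tensor(x)).data


def multi_head_attention(X: np.ndarray, heads: int,
                         seed: int = 0) -> np.ndarray:
    """Self-attention over an (n, d) sequence (or a batch of them) with
    freshly initialized projections; see
    :class:`mbtcn.nn.layers.MultiHeadAttention` for the stateful layer."""
    X = np.asarray(X, dtype=np.float64)
    batched = X.ndim == 3
    if not batched:
        X = X[None]
    mha = MultiHeadAttention(X.shape[-1], heads,
                             rng=np.random.default_rng(seed))
    out = mha(Tensor(X)).data
    return out if batched else out[0]


def concat_branches(maps: list[np.ndarray]) -> np.ndarray:
    """Merge branch feature maps along channels; lengths must agree."""
    lengths = {m.shape[-2] for m in maps}
    if len(lengths) != 1:
        raise RuntimeError(
            f"branch temporal lengths differ: {sorted(lengths)} "
            "(padding bug upstream)")
    return np.concatenate(maps, axis=-1)


class ResidualBlock(Layer):
    """Two dilated causal convolutions (ReLU, batch-norm, dropout each) with
    an additive skip; output = ReLU(F(x) + skip(x))."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 dilation: int, dropout: float, *, rng: np.random.Generator,
                 dropout_rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(in_channels, filters, kernel, dilation=dilation,
                            padding="causal", rng=rng)
        self.bn1 = BatchNorm1d(filters)
        self.conv2 = Conv1d(filters, filters, kernel, dilation=dilation,
                            padding="causal", rng=rng)
        self.bn2 = BatchNorm1d(filters)
        self.drop1 = Dropout(dropout, dropout_rng)
        self.drop2 = Dropout(dropout, dropout_rng)
        self.skip = (Conv1d(in_channels, filters, 1, rng=rng)
                     if in_channels != filters else None)
        self._children = [self.conv1, self.bn1, self.drop1,
                          self.conv2, self.bn2, self.drop2] + \
            ([self.skip] if self.skip is not None else [])

    def parameters(self):
        return [p for lay in self._children for p in lay.parameters()]

    def state_arrays(self):
        out = {}
        for i, lay in enumerate(self._children):
            for name, arr in lay.state_arrays().items():
                out[f"{i}.{lay.__class__.__name__}.{name}"] = arr
        return out

    def set_training(self, flag):
        super().set_training(flag)
        for lay in self._children:
            lay.set_training(flag)

    def __call__(self, x: Tensor) -> Tensor:
        f = self.drop1(self.bn1(self.conv1(x).relu()))
        f = self.drop2(self.bn2(self.conv2(f).relu()))
        s = self.skip(x) if self.skip is not None else x
        return (f + s).relu()


class Model:
    """A realized MB-MHA-TCN network with seeded initialization."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(seed + 1)
        self.branches: list[Sequential] = []
        for b in config.branches:
            self.branches.append(Sequential(
                Conv1d(1, b.filters, b.kernel_1, dilation=1, padding="same",
                       rng=rng),
                ReLU(), BatchNorm1d(b.filters), MaxPool1d(b.pool, b.pool),
                Conv1d(b.filters, b.out_channels, b.kernel_2,
                       dilation=b.dilation_2, padding="same", rng=rng),
                ReLU(), BatchNorm1d(b.out_channels), MaxPool1d(b.pool, b.pool),
            ))
        d = config.d_model
        self.concat_norm = BatchNorm1d(d)
        self.attention = MultiHeadAttention(d, config.heads, rng=rng)
        self.tcn: list[ResidualBlock] = []
        in_ch = d
        for dil in config.tcn_dilations:
            self.tcn.append(ResidualBlock(
                in_ch, config.tcn_filters, config.tcn_kernel, dil,
                config.dropout_rate, rng=rng, dropout_rng=self.dropout_rng))
            in_ch = config.tcn_filters
        self.flatten = Flatten()
        self.head = Dense(config.seq_length * config.tcn_filters,
                          config.n_classes, rng=rng)
        self._layers: list[Layer] = [*self.branches, self.concat_norm,
                                     self.attention, *self.tcn, self.flatten,
                                     self.head]
        self.training = True

    # -- bookkeeping -------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return [p for lay in self._layers for p in lay.parameters()]

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, lay in enumerate(self._layers):
            for name, arr in lay.state_arrays().items():
                out[f"L{i}.{lay.__class__.__name__}.{name}"] = arr
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for lay in self._layers:
            lay.set_training(flag)

    def batchnorm_layers(self) -> list[BatchNorm1d]:
        out = []
        for lay in self._layers:
            if isinstance(lay, BatchNorm1d):
                out.append(lay)
            elif isinstance(lay, Sequential):
                out.extend(l for l in lay.layers if isinstance(l, BatchNorm1d))
            elif isinstance(lay, ResidualBlock):
                out.extend([lay.bn1, lay.bn2])
        return out

    def commit_batchnorm_epoch(self) -> None:
        """Re-estimate inference statistics from the finished epoch."""
        for bn in self.batchnorm_layers():
            bn.commit_epoch_stats()

    def reseed_dropout(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self.dropout_rng.bit_generator.state = rng.bit_generator.state

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        state = self.state_arrays()
        if set(state) != set(weights):
            raise ValueError("weight dictionary does not match architecture")
        for k, arr in state.items():
            arr[...] = weights[k]

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """Class logits for a batch; ``x`` is (B, L) or (B, L, 1)."""
        if not isinstance(x, Tensor):
            x = np.asarray(x, dtype=np.float64)
            if x.ndim == 2:
                x = x[:, :, None]
            x = Tensor(x)
        maps = [branch(x) for branch in self.branches]
        fused = self.concat_norm(concatenate(maps, axis=-1))
        att = self.attention(fused)
        h = att
        for block in self.tcn:
            h = block(h)
        return self.head(self.flatten(h))

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax class probabilities in eval mode (rows sum to 1)."""
        was_training = self.training
        self.set_training(False)
        outs = []
        for lo in range(0, len(x), batch_size):
            logits = self.forward(x[lo:lo + batch_size])
            outs.append(logits.softmax(axis=-1).data)
        self.set_training(was_training)
        return np.vstack(outs)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- persistence -------------------------------------------------------

    def save(self, path: Path) -> None:
        """Single-file checkpoint: weights plus the embedded config JSON."""
        path = Path(path)
        buf = io.BytesIO()
        np.savez(buf, **self.state_arrays())
        with zipfile.ZipFile(path, "w") as z:
            z.writestr("config.json", self.config.to_json())
            z.writestr("seed.json", json.dumps({"seed": self.seed}))
            z.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path: Path) -> "Model":
        with zipfile.ZipFile(Path(path)) as z:
            config = ModelConfig.from_json(z.read("config.json").decode())
            seed = json.loads(z.read("seed.json").decode())["seed"]
            with np.load(io.BytesIO(z.read("weights.npz"))) as w:
                weights = {k: w[k] for k in w.files}
        model = cls(config, seed=seed)
        model.set_weights(weights)
        return model


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> Model:
    """Assemble the network from its configuration with seeded init."""
    return Model(config, seed=seed)


def param_count(model: Model) -> int:
    """Total persisted parameters (trainable weights plus batch-norm
    running statistics), matching framework-style 'total params' counts."""
    return int(sum(arr.size for arr in model.state_arrays().values()))


def float32_megabytes(model: Model) -> float:
    """Checkpoint footprint in MB if stored as float-32."""
    return param_count(model) * 4 / (1024 * 1024)


def receptive_field(config: ModelConfig) -> int:
    """Receptive field (in time steps) of the TCN stack alone.

    Each residual block holds two causal convolutions at dilation d, each
    adding (k-1)*d steps of history: rf = 1 + sum_l 2*(k-1)*2^l.
    """
    k = config.tcn_kernel
    return 1 + sum(2 * (k - 1) * d for d in config.tcn_dilations)
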