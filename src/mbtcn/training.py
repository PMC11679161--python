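"""Training machinery: multi-class focal loss, warmup + exponential-decay
learning-rate schedule, L2 penalty, early stopping, Adam, and the seeded
training loop.

The user-facing surface follows the model/results pattern:
:class:`BeatClassifier` is built from training and validation beat tables,
``fit()`` runs the loop and returns :class:`BeatClassifierResults` carrying
the per-epoch history, the restored best weights, and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Model, ModelConfig, build_model
from .nn.autodiff import Tensor
from .preprocess import CLASSES, BeatMatrix

__all__ = [
    "FocalConfig", "ScheduleConfig", "TrainConfig", "focal_loss",
    "warmup_step_count", "lr_at_step", "l2_penalized_loss", "early_stopping",
    "focal_loss_from_logits", "Adam", "fit", "BeatClassifier",
    "BeatClassifierResults",
]


# ---------------------------------------------------------------------------
# Loss and schedule primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FocalConfig:
    """Focal loss -alpha_t (1 - p_t)^gamma log(p_t), averaged over the batch.

    ``alpha`` may be a scalar applied to every true class (the default,
    matching the single tuned balance factor) or a length-5 per-class vector.
    """

    alpha: float | tuple[float, ...] = 0.76943
    gamma: float = 2.0
    eps: float = 1e-7

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.alpha, dtype=np.float64))
        if (a <= 0).any():
            raise ValueError("alpha must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")

    def alpha_for(self, y: np.ndarray) -> np.ndarray:
        a = np.asarray(self.alpha, dtype=np.float64)
        return np.full(len(y), float(a)) if a.ndim == 0 else a[y]


def focal_loss(probs: Tensor | np.ndarray, y: np.ndarray,
               cfg: FocalConfig = FocalConfig()):
    """Mean focal loss of a batch of class-probability rows.

    ``probs`` rows must be valid probability vectors; they are clipped to
    [eps, 1-eps] before the log.  Returns a float for array input or a graph
    :class:`Tensor` for tensor input (used inside the training loop).
    At gamma=0, alpha=1 this is exactly categorical cross-entropy.
    """
    y = np.asarray(y, dtype=np.int64)
    raw = probs.data if isinstance(probs, Tensor) else np.asarray(probs)
    if raw.ndim != 2 or (raw < -1e-9).any() or \
            (np.abs(raw.sum(axis=1) - 1.0) > 1e-6).any():
        raise ValueError("probs rows must be probability vectors summing to 1")
    if (y < 0).any() or (y >= raw.shape[1]).any():
        raise ValueError("class index out of range")
    t = probs if isinstance(probs, Tensor) else Tensor(raw)
    onehot = np.zeros_like(raw)
    onehot[np.arange(len(y)), y] = 1.0
    pt = (t.clip(cfg.eps, 1.0 - cfg.eps) * onehot).sum(axis=1)
    alpha_t = cfg.alpha_for(y)
    loss = ((1.0 - pt).pow(cfg.gamma) * pt.log() * alpha_t).mean() * (-1.0)
    return loss if isinstance(probs, Tensor) else float(loss.data)


def focal_loss_from_logits(logits: Tensor, y: np.ndarray,
                           cfg: FocalConfig = FocalConfig()) -> Tensor:
    """Focal loss computed from raw logits via log-softmax.

    Numerically equivalent to :func:`focal_loss` on the softmax
    probabilities, but the gradient of ``log p_t`` stays bounded as
    ``p_t -> 0`` (clipping probabilities before the log silently kills the
    gradient of confidently-wrong samples, which can leave a whole class
    permanently dead during training).
    """
    y = np.asarray(y, dtype=np.int64)
    zmax = logits.data.max(axis=1, keepdims=True)   # constant shift
    zs = logits - zmax
    lse = zs.exp().sum(axis=1, keepdims=True).log()
    logp = zs - lse
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(y)), y] = 1.0
    log_pt = (logp * onehot).sum(axis=1)
    pt = log_pt.exp()
    alpha_t = cfg.alpha_for(y)
    return ((1.0 - pt).pow(cfg.gamma) * log_pt * alpha_t).mean() * (-1.0)


def warmup_step_count(epochs: int, n_train: int, batch_size: int) -> int:
    """Total warmup steps: floor(epochs * n_train / batch_size)."""
    if min(epochs, n_train, batch_size) <= 0:
        raise ValueError("epochs, n_train and batch_size must be positive")
    return (epochs * n_train) // batch_size


@dataclass(frozen=True)
class ScheduleConfig:
    """Linear warmup to ``target_lr`` then exponential decay, floored.

    ``warmup_steps`` is normally derived from the training geometry via
    :func:`warmup_step_count`.  ``staircase=False`` uses the real-valued
    decay exponent (step - warmup_steps) / decay_steps.
    """

    initial_lr: float = 0.0001
    target_lr: float = 0.0007
    decay_steps: int = 1500
    decay_rate: float = 0.97
    min_lr: float = 0.00001
    warmup_steps: int = 1000
    staircase: bool = False

    def __post_init__(self):
        if not 0 < self.initial_lr <= self.target_lr:
            raise ValueError("need 0 < initial_lr <= target_lr")
        if not 0 < self.decay_rate < 1:
            raise ValueError("decay_rate must lie in (0, 1)")
        if self.min_lr >= self.target_lr:
            raise ValueError("min_lr must be below target_lr")


def lr_at_step(step: int, cfg: ScheduleConfig) -> float:
    """Learning rate at a global training step (continuous at the boundary)."""
    if step < 0:
        raise ValueError("step must be non-negative")
    if cfg.warmup_steps > 0 and step < cfg.warmup_steps:
        frac = step / cfg.warmup_steps
        return cfg.initial_lr + (cfg.target_lr - cfg.initial_lr) * frac
    exponent = (step - cfg.warmup_steps) / cfg.decay_steps
    if cfg.staircase:
        exponent = float(np.floor(exponent))
    return max(cfg.target_lr * cfg.decay_rate ** exponent, cfg.min_lr)


def l2_penalized_loss(base_loss, weights, lam: float):
    """base_loss + lam * sum_i w_i^2 over the given weight arrays/tensors."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if isinstance(weights, (Tensor, np.ndarray)):
        weights = [weights]
    if lam == 0:
        return base_loss
    penalty = None
    for w in weights:
        term = ((w * w).sum() if isinstance(w, Tensor)
                else float((np.asarray(w) ** 2).sum()))
        penalty = term if penalty is None else penalty + term
    return base_loss + lam * penalty


def early_stopping(val_loss_history, patience: int = 10,
                   min_delta: float = 1e-4) -> dict:
    """Replay an improvement ledger over a validation-loss history.

    Returns ``{"stop_epoch": int | None, "best_epoch": int}`` where
    ``stop_epoch`` is the 0-based epoch after which training halts (None if
    the history never triggers the patience), and ``best_epoch`` indexes the
    minimum validation loss seen up to the stop.
    """
    hist = list(val_loss_history)
    if not hist:
        raise ValueError("history must be non-empty")
    best = hist[0]
    best_epoch = 0
    bad = 0
    for epoch, loss in enumerate(hist[1:], start=1):
        if best - loss > min_delta:
            best = loss
            best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if loss < best:        # still track the minimum for restoration
                best, best_epoch = loss, epoch
            if bad >= patience:    # patience=0 stops at the first bad epoch
                return {"stop_epoch": epoch, "best_epoch": best_epoch}
    return {"stop_epoch": None, "best_epoch": int(np.argmin(hist))}


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with an externally supplied per-step learning rate."""

    def __init__(self, params: list[Tensor], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 80
    batch_size: int = 64
    optimizer: str = "adam"
    patience: int = 10
    min_delta: float = 1e-4
    l2_lambda: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.patience < 0:
            raise ValueError("patience must be non-negative")


@dataclass
class TrainingHistory:
    """Per-epoch log plus the per-step learning-rate trace."""

    epochs: list[dict] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


def _batch_loss(model: Model, xb: np.ndarray, yb: np.ndarray,
                focal: FocalConfig, lam: float) -> Tensor:
    logits = model.forward(xb)
    loss = focal_loss_from_logits(logits, yb, focal)
    return l2_penalized_loss(loss, model.head.w, lam)


def _eval_loss_acc(model: Model, X: np.ndarray, y: np.ndarray,
                   focal: FocalConfig, batch_size: int = 64
                   ) -> tuple[float, float]:
    probs = model.predict_proba(X, batch_size)
    loss = focal_loss(probs, y, focal)
    acc = float((probs.argmax(axis=1) == y).mean())
    return float(loss), acc


def fit(model: Model, train: BeatMatrix, val: BeatMatrix,
        cfg: TrainConfig = TrainConfig(),
        schedule: ScheduleConfig | None = None,
        focal: FocalConfig = FocalConfig(),
        verbose: bool = False) -> tuple[TrainingHistory, dict]:
    """Seeded training with scheduled Adam, early stopping and best-weight
    restoration.  Returns (history, best_weights); the model is left holding
    the best-validation-loss weights.
    """
    if not train.standardized:
        warnings.warn("training beats are not standardized; the network "
                      "expects z-scored inputs")
    X, y = train.beats, train.y_indices()
    Xv, yv = val.beats, val.y_indices()
    n = len(X)
    if schedule is None:
        schedule = ScheduleConfig(warmup_steps=warmup_step_count(
            cfg.epochs, n, cfg.batch_size))
    rng = np.random.default_rng(cfg.seed)
    model.reseed_dropout(cfg.seed + 1)
    model.set_training(True)
    opt = Adam(model.parameters())
    history = TrainingHistory()
    best_loss = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    bad = 0
    step = 0
    stopped_early = False
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            lr = lr_at_step(step, schedule)
            loss = _batch_loss(model, X[idx], y[idx], focal, cfg.l2_lambda)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, step {step}: "
                    f"loss={float(loss.data)}")
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            history.lr_trace.append(lr)
            losses.append(float(loss.data))
            step += 1
        model.commit_batchnorm_epoch()
        val_loss, val_acc = _eval_loss_acc(model, Xv, yv, focal)
        model.set_training(True)
        record = {"epoch": epoch, "step": step,
                  "lr": history.lr_trace[-1],
                  "train_loss": float(np.mean(losses)),
                  "val_loss": val_loss, "val_acc": val_acc}
        history.epochs.append(record)
        if verbose:  # pragma: no cover
            print(f"epoch {epoch:3d}  train {record['train_loss']:.4f}  "
                  f"val {val_loss:.4f}  acc {val_acc:.4f}")
        if best_loss - val_loss > cfg.min_delta:
            best_loss, best_epoch, bad = val_loss, epoch, 0
            best_weights = model.get_weights()
        else:
            if val_loss < best_loss:
                best_loss, best_epoch = val_loss, epoch
                best_weights = model.get_weights()
            bad += 1
            if bad >= cfg.patience:
                stopped_early = True
                break
    model.set_weights(best_weights)
    model.set_training(False)
    history.epochs[-1]["stopped_early"] = stopped_early
    history.epochs[-1]["best_epoch"] = best_epoch
    return history, best_weights


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class BeatClassifier:
    """Five-class arrhythmia beat classifier built from beat tables.

    Parameters
    ----------
    train, val : BeatMatrix
        Standardized training and validation beats; the training split may
        contain augmentation-synthesized rows, the validation split must not.
    config : ModelConfig
        Architecture description (defaults to the tuned configuration).
    seed : int
        Seed for weight initialization and dropout.
    """

    def __init__(self, train: BeatMatrix, val: BeatMatrix,
                 config: ModelConfig = ModelConfig(), seed: int = 0):
        self.train_data = train
        self.val_data = val
        self.config = config
        self.seed = seed
        self.model = build_model(config, seed=seed)

    @classmethod
    def from_splits(cls, splits: dict[str, BeatMatrix],
                    config: ModelConfig = ModelConfig(),
                    seed: int = 0) -> "BeatClassifier":
        return cls(splits["train"], splits["val"], config, seed)

    def fit(self, train_config: TrainConfig | None = None,
            schedule: ScheduleConfig | None = None,
            focal: FocalConfig = FocalConfig(),
            verbose: bool = False) -> "BeatClassifierResults":
        cfg = train_config or TrainConfig(seed=self.seed)
        history, _ = fit(self.model, self.train_data, self.val_data,
                         cfg, schedule, focal, verbose)
        return BeatClassifierResults(self, history, cfg, focal)


class BeatClassifierResults:
    """Fitted-model results: history, diagnostics and prediction helpers."""

    def __init__(self, classifier: BeatClassifier, history: TrainingHistory,
                 train_config: TrainConfig, focal: FocalConfig):
        self.classifier = classifier
        self.model = classifier.model
        self.history = history
        self.train_config = train_config
        self.focal = focal

    @property
    def best_epoch(self) -> int:
        return self.history.epochs[-1].get("best_epoch",
                                           len(self.history.epochs) - 1)

    def predict_proba(self, beats: BeatMatrix | np.ndarray) -> np.ndarray:
        X = beats.beats if isinstance(beats, BeatMatrix) else beats
        return self.model.predict_proba(X)

    def predict(self, beats: BeatMatrix | np.ndarray) -> np.ndarray:
        """Predicted AAMI class labels."""
        idx = self.predict_proba(beats).argmax(axis=1)
        return np.array(CLASSES)[idx]

    def evaluate(self, beats: BeatMatrix):
        """Confusion matrix and metrics report on a held-out beat table."""
        from .evaluation import ConfusionMatrix, metrics_from_cm, roc_auc_ovr
        probs = self.predict_proba(beats)
        y_pred = np.array(CLASSES)[probs.argmax(axis=1)]
        cm = ConfusionMatrix.from_predictions(beats.labels, y_pred)
        report = metrics_from_cm(cm)
        auc_per, auc_macro = roc_auc_ovr(probs, beats.labels)
        report.auc_per_class = auc_per
        report.macro_auc = auc_macro
        return report

    def summary(self) -> str:
        """Human-readable fitting summary table."""
        h = self.history.to_frame()
        last = h.iloc[-1]
        cfg = self.classifier.config
        lines = [
            "MB-MHA-TCN beat classifier — fit summary",
            "=" * 48,
            f"{'training beats':28s} {len(self.classifier.train_data):>10d}",
            f"{'validation beats':28s} {len(self.classifier.val_data):>10d}",
            f"{'branch kernels':28s} "
            f"{'/'.join(str(b.kernel_1) for b in cfg.branches):>10s}",
            f"{'attention heads':28s} {cfg.heads:>10d}",
            f"{'TCN layers x filters':28s} "
            f"{f'{cfg.tcn_layers}x{cfg.tcn_filters}':>10s}",
            f"{'epochs run':28s} {len(h):>10d}",
            f"{'best epoch (val loss)':28s} {self.best_epoch:>10d}",
            f"{'final train loss':28s} {last['train_loss']:>10.5f}",
            f"{'final val loss':28s} {last['val_loss']:>10.5f}",
            f"{'final val accuracy':28s} {last['val_acc']:>10.4f}",
            f"{'focal alpha / gamma':28s} "
            f"{f'{self.focal.alpha}/{self.focal.gamma:g}':>10s}",
            "=" * 48,
        ]
        return "\n".join(lines)
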