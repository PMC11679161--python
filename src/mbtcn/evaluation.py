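"""Evaluation: confusion matrices, per-class and macro metrics, one-vs-rest
ROC/AUC, and the k-fold cross-validation harness.

Metric definitions (per class, via one-vs-rest reduction of the 5x5 matrix):
precision = TP/(TP+FP), sensitivity = TP/(TP+FN),
F1 = 2*Pre*Sen/(Pre+Sen), specificity = TN/(TN+FP); overall accuracy is
trace/total (the multi-class accuracy); macro values are unweighted means
over the five classes.  Display rounding is half-up to two decimals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .preprocess import CLASSES, BeatMatrix

__all__ = [
    "ConfusionMatrix", "MetricsReport", "confusion_matrix", "metrics_from_cm",
    "roc_auc_ovr", "roc_points", "cross_validate", "round2",
]


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals, for display parity with printed tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """5x5 count matrix; rows = true class, columns = predicted, order N,S,V,F,Q."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred,
                         classes: tuple[str, ...] = CLASSES
                         ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if len(y_true) != len(y_pred):
            raise ValueError("y_true and y_pred lengths differ")
        lut = {c: i for i, c in enumerate(classes)}
        bad = (set(np.unique(y_true)) | set(np.unique(y_pred))) - set(classes)
        if bad:
            raise ValueError(f"labels outside the class alphabet: {sorted(bad)}")
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[lut[t], lut[p]] += 1
        return cls(counts, classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class index i."""
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Tally counts[i][j] = #{samples with true class i predicted as j}."""
    return ConfusionMatrix.from_predictions(y_true, y_pred)


@dataclass
class MetricsReport:
    """Per-class and macro-averaged classification metrics (fractions in [0,1])."""

    per_class: dict[str, dict[str, float]]
    overall_accuracy: float
    macro_precision: float
    macro_sensitivity: float
    macro_f1: float
    macro_specificity: float
    auc_per_class: dict[str, float] | None = None
    macro_auc: float | None = None
    classes: tuple[str, ...] = CLASSES

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        """Per-class table, optionally in half-up-rounded percent."""
        rows = {}
        for c in self.classes:
            m = self.per_class[c]
            row = dict(m)
            if self.auc_per_class and c in self.auc_per_class:
                row["auc"] = self.auc_per_class[c]
            rows[c] = {k: round2(v * 100) if percent else v
                       for k, v in row.items()}
        return pd.DataFrame(rows).T

    def to_json(self) -> str:
        d = {"per_class": self.per_class,
             "overall_accuracy": self.overall_accuracy,
             "macro_precision": self.macro_precision,
             "macro_sensitivity": self.macro_sensitivity,
             "macro_f1": self.macro_f1,
             "macro_specificity": self.macro_specificity,
             "auc_per_class": self.auc_per_class,
             "macro_auc": self.macro_auc}
        return json.dumps(d, indent=2)

    def summary(self) -> str:
        table = self.to_frame().to_string()
        extra = (f"\nmacro AUC          {round2(self.macro_auc * 100):6.2f}"
                 if self.macro_auc is not None else "")
        return (f"{table}\n"
                f"overall accuracy   {round2(self.overall_accuracy * 100):6.2f}\n"
                f"macro precision    {round2(self.macro_precision * 100):6.2f}\n"
                f"macro sensitivity  {round2(self.macro_sensitivity * 100):6.2f}\n"
                f"macro F1           {round2(self.macro_f1 * 100):6.2f}"
                + extra)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"division by zero computing {what}; reporting 0")
        return 0.0
    return num / den


def metrics_from_cm(cm: ConfusionMatrix) -> MetricsReport:
    """Derive per-class precision/sensitivity/F1/specificity and macro means."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    for i, c in enumerate(cm.classes):
        tp, fp, fn, tn = cm.one_vs_rest(i)
        pre = _safe_div(tp, tp + fp, f"precision[{c}]")
        sen = _safe_div(tp, tp + fn, f"sensitivity[{c}]")
        f1 = _safe_div(2 * pre * sen, pre + sen, f"F1[{c}]")
        spe = _safe_div(tn, tn + fp, f"specificity[{c}]")
        per_class[c] = {"precision": pre, "sensitivity": sen,
                        "f1": f1, "specificity": spe}
    macro = {m: float(np.mean([per_class[c][m] for c in cm.classes]))
             for m in ("precision", "sensitivity", "f1", "specificity")}
    oa = np.trace(cm.counts) / cm.total
    return MetricsReport(per_class=per_class, overall_accuracy=float(oa),
                         macro_precision=macro["precision"],
                         macro_sensitivity=macro["sensitivity"],
                         macro_f1=macro["f1"],
                         macro_specificity=macro["specificity"],
                         classes=cm.classes)


def roc_auc_ovr(scores: np.ndarray, y_true,
                classes: tuple[str, ...] = CLASSES
                ) -> tuple[dict[str, float], float]:
    """One-vs-rest AUC per class (rank statistic, ties counted half) and the
    macro mean over the classes present in ``y_true``."""
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true)
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError("scores must be (n, n_classes)")
    aucs: dict[str, float] = {}
    for i, c in enumerate(classes):
        pos = y_true == c
        if not pos.any() or pos.all():
            warnings.warn(f"class {c!r} has no positives or no negatives; "
                          "AUC undefined and excluded from the macro mean")
            continue
        aucs[c] = float(roc_auc_score(pos.astype(int), scores[:, i]))
    macro = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    return aucs, macro


def roc_points(scores: np.ndarray, y_true,
               classes: tuple[str, ...] = CLASSES) -> pd.DataFrame:
    """One-vs-rest ROC coordinates for every class present in ``y_true``,
    as a long table (class, fpr, tpr, threshold) — exportable to CSV for
    plotting."""
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true)
    frames = []
    for i, c in enumerate(classes):
        pos = (y_true == c).astype(int)
        if pos.sum() in (0, len(pos)):
            continue
        fpr, tpr, thr = roc_curve(pos, scores[:, i])
        frames.append(pd.DataFrame({"class": c, "fpr": fpr, "tpr": tpr,
                                    "threshold": thr}))
    if not frames:
        return pd.DataFrame(columns=["class", "fpr", "tpr", "threshold"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _fold_assignments(labels: np.ndarray, k: int, seed: int,
                      stratified: bool = True) -> np.ndarray:
    """Fold id per sample; fold sizes differ by at most one.

    Stratified mode deals each class's shuffled members onto the folds with a
    pointer that continues across classes, so per-class and total fold sizes
    are both balanced.
    """
    rng = np.random.default_rng(seed)
    n = len(labels)
    fold = np.empty(n, dtype=int)
    if not stratified:
        perm = rng.permutation(n)
        fold[perm] = np.arange(n) % k
        return fold
    pointer = rng.integers(0, k)
    for c in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == c))
        for m in members:
            fold[m] = pointer % k
            pointer += 1
    return fold


def cross_validate(data: BeatMatrix, k: int = 5, seed: int = 0,
                   stratified: bool = True,
                   model_config=None, train_config=None, schedule=None,
                   focal=None, balance: bool = True,
                   balance_kwargs: dict | None = None,
                   ) -> tuple[list[MetricsReport], dict]:
    """k-fold cross-validation of the full pipeline.

    Folds partition the index set (each sample validates exactly once).
    Standardization and balancing are re-fit inside each training fold; the
    held-out fold is never oversampled.  Returns the per-fold reports and a
    dict of averaged metrics (arithmetic means over folds).
    """
    from .model import ModelConfig
    from .preprocess import apply_standardizer, fit_standardizer
    from .training import BeatClassifier, FocalConfig, TrainConfig
    from .balance import stratified_split

    if len(data) < k:
        raise ValueError("need at least k samples")
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    focal = focal or FocalConfig()
    balance_kwargs = balance_kwargs or {}
    fold = _fold_assignments(data.labels, k, seed, stratified)
    reports: list[MetricsReport] = []
    for f in range(k):
        held = np.flatnonzero(fold == f)
        rest = np.flatnonzero(fold != f)
        train_pool = data.subset(rest)
        test = data.subset(held)
        # inner validation split for early stopping
        tr_idx, val_idx = stratified_split(train_pool.labels, 0.2,
                                           seed + 17 * f, stratified)
        train, val = train_pool.subset(tr_idx), train_pool.subset(val_idx)
        stats = fit_standardizer(train, fitted_on=f"fold{f}-train")
        train = apply_standardizer(train, stats)
        val = apply_standardizer(val, stats)
        test_std = apply_standardizer(test, stats)
        if balance:
            train = _oversample_training_fold(
                train, seed=seed + 31 * f, **balance_kwargs)
        clf = BeatClassifier(train, val, model_config, seed=seed + f)
        res = clf.fit(train_config, schedule, focal)
        reports.append(res.evaluate(test_std))
    averages = {
        "overall_accuracy": float(np.mean(
            [r.overall_accuracy for r in reports])),
        "macro_precision": float(np.mean([r.macro_precision for r in reports])),
        "macro_sensitivity": float(np.mean(
            [r.macro_sensitivity for r in reports])),
        "macro_f1": float(np.mean([r.macro_f1 for r in reports])),
        "macro_auc": float(np.mean([r.macro_auc for r in reports
                                    if r.macro_auc is not None])),
    }
    return reports, averages


def _oversample_training_fold(train: BeatMatrix, seed: int,
                              k_neighbors: int = 5,
                              tomek_rounds: int = 1) -> BeatMatrix:
    """SMOTE minority classes up to the median class size, then Tomek-clean."""
    from .balance import SmoteParams, remove_links, smote

    counts = train.class_counts()
    present = sorted(v for v in counts.values() if v > 0)
    if not present:
        return train
    median = int(np.median(present))
    for ci, cls in enumerate(("S", "F")):
        have = counts.get(cls, 0)
        if 0 < have < median and have > 1:
            rows = np.flatnonzero(train.labels == cls)
            params = SmoteParams(k_neighbors=min(k_neighbors, have - 1),
                                 n_synthetic=median - have, seed=seed + ci)
            X_new = smote(train.beats[rows], params)
            synth = BeatMatrix(X_new, np.full(median - have, cls, dtype="U1"),
                               np.ones(median - have, dtype=bool),
                               train.standardized)
            train = train.concat(synth)
    _, _, kept = remove_links(train.beats, train.labels,
                              policy="majority", max_rounds=tomek_rounds)
    return train.subset(kept)
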