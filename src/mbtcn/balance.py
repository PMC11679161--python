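"""Class-imbalance handling: cluster-proportional undersampling of the
majority class, SMOTE oversampling of minority classes, Tomek-link cleaning,
and the leakage-safe split orchestration.

The strategy follows the workflow this package implements end to end:
K-means partitions the majority class (default K=10) and each cluster
contributes samples in proportion to its size, so undersampling preserves
morphological diversity instead of thinning the class uniformly at random.
Minority classes are then oversampled by SMOTE interpolation *inside the
training split only*, and Tomek links are removed to sharpen the class
boundary.  Validation and test sets never contain synthetic rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import CLASSES, BeatMatrix

__all__ = [
    "ClusterPlan", "ClusterConfig", "SmoteParams", "TomekPolicy", "SplitSpec",
    "kmeans", "proportional_undersample", "smote", "tomek_links",
    "remove_links", "stratified_split", "balance_dataset",
]


# ---------------------------------------------------------------------------
# K-means and proportional undersampling
# ---------------------------------------------------------------------------

@dataclass
class ClusterPlan:
    """Outcome of clustering the majority class plus the sampling quotas."""

    K: int
    assignments: np.ndarray          # (n,) cluster index per sample
    centroids: np.ndarray            # (K, L)
    inertia: float                   # final within-cluster sum of squares
    inertia_trace: list[float] = field(default_factory=list)
    proportions: np.ndarray | None = None   # P_k = size_k / n
    quotas: np.ndarray | None = None        # S_k, sums to n_target
    n_target: int | None = None

    def validate(self) -> None:
        if self.proportions is not None:
            assert abs(self.proportions.sum() - 1.0) < 1e-9
        if self.quotas is not None:
            sizes = np.bincount(self.assignments, minlength=self.K)
            assert self.quotas.sum() == self.n_target
            assert (self.quotas <= sizes).all() and (self.quotas >= 0).all()


@dataclass(frozen=True)
class ClusterConfig:
    K: int = 10
    max_iter: int = 300
    tol: float = 1e-4


def _inertia(X: np.ndarray, centroids: np.ndarray,
             assignments: np.ndarray) -> float:
    return float(((X - centroids[assignments]) ** 2).sum())


def kmeans(X: np.ndarray, K: int, seed: int = 0, max_iter: int = 300,
           tol: float = 1e-4) -> ClusterPlan:
    """Lloyd's algorithm minimizing the within-cluster sum of squared
    Euclidean distances.

    Iterates until the largest centroid displacement falls below ``tol`` or
    ``max_iter`` is reached.  An emptied cluster is re-seeded from the point
    farthest from its assigned centroid.  The objective value after every
    iteration is recorded in ``inertia_trace`` (non-increasing).
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"need 1 <= K <= n, got K={K}, n={n}")
    rng = np.random.default_rng(seed)
    centroids = _kmeanspp_init(X, K, rng)
    trace: list[float] = []
    assignments = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2) \
            if n * K * X.shape[1] < 2e7 else _chunked_d2(X, centroids)
        assignments = d2.argmin(axis=1)
        new_centroids = centroids.copy()
        for k in range(K):
            members = assignments == k
            if members.any():
                new_centroids[k] = X[members].mean(axis=0)
        # re-seed empty clusters from the globally farthest point
        empties = [k for k in range(K) if not (assignments == k).any()]
        if empties:
            dist_to_own = d2[np.arange(n), assignments]
            order = np.argsort(-dist_to_own)
            for k, far in zip(empties, order):
                new_centroids[k] = X[far]
                assignments[far] = k
        shift = np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max()
        centroids = new_centroids
        trace.append(_inertia(X, centroids, assignments))
        if shift < tol:
            break
    return ClusterPlan(K=K, assignments=assignments, centroids=centroids,
                       inertia=trace[-1], inertia_trace=trace)


def _kmeanspp_init(X: np.ndarray, K: int,
                   rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centroids by D^2 sampling."""
    n = X.shape[0]
    centroids = np.empty((K, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:
            centroids[k:] = X[rng.choice(n, size=K - k)]
            break
        centroids[k] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centroids[k]) ** 2).sum(axis=1))
    return centroids


def _chunked_d2(X: np.ndarray, C: np.ndarray, chunk: int = 2048) -> np.ndarray:
    out = np.empty((X.shape[0], C.shape[0]))
    for lo in range(0, X.shape[0], chunk):
        hi = min(lo + chunk, X.shape[0])
        out[lo:hi] = ((X[lo:hi, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    return out


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    raw = np.asarray(weights, dtype=np.float64) / np.sum(weights) * total
    base = np.floor(raw).astype(int)
    order = np.argsort(-(raw - base), kind="stable")
    base[order[: total - base.sum()]] += 1
    return base


def proportional_undersample(X: np.ndarray, K: int, n_target: int,
                             seed: int = 0, max_iter: int = 300,
                             tol: float = 1e-4
                             ) -> tuple[np.ndarray, ClusterPlan]:
    """Select ``n_target`` row indices of ``X``, cluster-proportionally.

    Clusters with K-means, computes per-cluster proportions P_k, assigns
    quotas S_k by largest-remainder rounding of P_k * n_target (so the quotas
    sum exactly to ``n_target``), and samples without replacement inside each
    cluster.  Returns the sorted indices and the annotated cluster plan.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n_target > n:
        raise ValueError(f"n_target={n_target} exceeds population {n}")
    plan = kmeans(X, K, seed=seed, max_iter=max_iter, tol=tol)
    sizes = np.bincount(plan.assignments, minlength=K)
    plan.proportions = sizes / n
    plan.quotas = largest_remainder(sizes, n_target)
    plan.n_target = n_target
    plan.validate()
    rng = np.random.default_rng(seed + 1)
    chosen: list[np.ndarray] = []
    for k in range(K):
        members = np.flatnonzero(plan.assignments == k)
        chosen.append(rng.choice(members, size=plan.quotas[k], replace=False))
    idx = np.sort(np.concatenate(chosen))
    return idx, plan


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoteParams:
    k_neighbors: int = 5
    lam_range: tuple[float, float] = (0.0, 1.0)
    n_synthetic: int = 0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lam_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("lam_range must lie within [0, 1]")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _pairwise_d2(A: np.ndarray, X: np.ndarray,
                 x_sq: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances via the dot-product expansion (one
    (len(A), len(X)) matrix; no (n, n, L) broadcast)."""
    d2 = (A ** 2).sum(axis=1)[:, None] + x_sq[None, :] - 2.0 * (A @ X.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def _knn_indices(X: np.ndarray, k: int, chunk: int = 1024) -> np.ndarray:
    """k nearest neighbors (excluding self) by Euclidean distance; ties broken
    toward the lowest index via stable argsort."""
    n = X.shape[0]
    x_sq = (X ** 2).sum(axis=1)
    out = np.empty((n, k), dtype=int)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d2 = _pairwise_d2(X[lo:hi], X, x_sq)
        d2[np.arange(hi - lo), np.arange(lo, hi)] = np.inf
        out[lo:hi] = np.argsort(d2, axis=1, kind="stable")[:, :k]
    return out


def smote(X_min: np.ndarray, params: SmoteParams,
          return_details: bool = False):
    """Generate synthetic minority rows x_new = x_i + lam * (x_j - x_i).

    ``x_j`` is one of x_i's ``k_neighbors`` nearest same-class neighbors and
    ``lam`` is drawn uniformly from ``lam_range``.
    """
    X_min = np.asarray(X_min, dtype=np.float64)
    m = X_min.shape[0]
    if m <= params.k_neighbors:
        raise ValueError(
            f"minority class has {m} samples but k_neighbors="
            f"{params.k_neighbors}; reduce k_neighbors below the class size")
    rng = np.random.default_rng(params.seed)
    nn = _knn_indices(X_min, params.k_neighbors)
    i_idx = rng.integers(0, m, size=params.n_synthetic)
    j_pick = rng.integers(0, params.k_neighbors, size=params.n_synthetic)
    j_idx = nn[i_idx, j_pick]
    lo, hi = params.lam_range
    lam = rng.uniform(lo, hi, size=params.n_synthetic)
    X_new = X_min[i_idx] + lam[:, None] * (X_min[j_idx] - X_min[i_idx])
    if return_details:
        return X_new, {"i": i_idx, "j": j_idx, "lam": lam}
    return X_new


# ---------------------------------------------------------------------------
# Tomek links
# ---------------------------------------------------------------------------

def _nearest_neighbor(X: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Index of each sample's single nearest neighbor (lowest index on ties)."""
    n = X.shape[0]
    x_sq = (X ** 2).sum(axis=1)
    out = np.empty(n, dtype=int)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d2 = _pairwise_d2(X[lo:hi], X, x_sq)
        d2[np.arange(hi - lo), np.arange(lo, hi)] = np.inf
        out[lo:hi] = d2.argmin(axis=1)       # argmin returns the lowest index
    return out


def tomek_links(X: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    """All mutual-nearest-neighbor pairs with different labels, as (i, j), i<j."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] < 2:
        return []
    nn = _nearest_neighbor(X)
    links = []
    for i in range(X.shape[0]):
        j = nn[i]
        if i < j and nn[j] == i and y[i] != y[j]:
            links.append((i, int(j)))
    return links


def remove_links(X: np.ndarray, y: np.ndarray, policy: str = "majority",
                 max_rounds: int = 1
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Delete Tomek-link members; returns (X_clean, y_clean, kept_indices).

    ``policy="majority"`` removes the link member whose class is globally more
    frequent (both members when the classes are equally frequent);
    ``policy="both"`` removes both members.  Repeats for up to ``max_rounds``
    or until no links remain.
    """
    if policy not in ("majority", "both"):
        raise ValueError(f"unknown removal policy {policy!r}")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    kept = np.arange(X.shape[0])
    for _ in range(max_rounds):
        links = tomek_links(X, y)
        if not links:
            break
        counts = {c: int((y == c).sum()) for c in np.unique(y)}
        drop: set[int] = set()
        for i, j in links:
            if policy == "both":
                drop.update((i, j))
            elif counts[y[i]] > counts[y[j]]:
                drop.add(i)
            elif counts[y[j]] > counts[y[i]]:
                drop.add(j)
            else:
                drop.update((i, j))
        keep = np.array([t for t in range(X.shape[0]) if t not in drop])
        X, y, kept = X[keep], y[keep], kept[keep]
    return X, y, kept


# ---------------------------------------------------------------------------
# Splits and orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """80:20 train-pool/test, then 80:20 train/validation by default."""

    test_fraction: float = 0.2
    val_fraction_of_train: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        for f in (self.test_fraction, self.val_fraction_of_train):
            if not 0.0 < f < 1.0:
                raise ValueError("split fractions must lie in (0, 1)")


def stratified_split(labels: np.ndarray, fraction: float, seed: int,
                     stratified: bool = True
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Partition indices into (rest, held_out) with ``fraction`` held out."""
    rng = np.random.default_rng(seed)
    n = len(labels)
    if not stratified:
        perm = rng.permutation(n)
        n_out = int(round(n * fraction))
        return np.sort(perm[n_out:]), np.sort(perm[:n_out])
    held = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        members = rng.permutation(members)
        n_out = int(round(len(members) * fraction))
        held.append(members[:n_out])
    held_idx = np.sort(np.concatenate(held))
    mask = np.ones(n, dtype=bool)
    mask[held_idx] = False
    return np.flatnonzero(mask), held_idx


def balance_dataset(beats: BeatMatrix, split: SplitSpec = SplitSpec(),
                    cluster: ClusterConfig = ClusterConfig(),
                    n_target_ratio: float = 2.3,
                    smote_params: SmoteParams = SmoteParams(),
                    smote_targets: dict[str, int] | None = None,
                    tomek_policy: str | None = "majority",
                    tomek_rounds: int = 1,
                    oversample: bool = True,
                    undersample: bool = True,
                    seed: int = 0) -> tuple[dict[str, BeatMatrix], dict]:
    """Run the full balancing workflow; returns splits and a balance report.

    Order of operations: (1) cluster-proportional undersampling of the
    majority class N on the whole dataset, with N_target =
    ``n_target_ratio`` x the largest minority-class count; (2) stratified
    test split; (3) stratified validation split of the remaining pool;
    (4) SMOTE oversampling of the training split (default: raise S and F to
    the median training class size) followed by Tomek-link cleaning.
    Synthetic rows exist only in the training split.
    """
    report: dict = {"seed": seed, "stages": {}}
    report["stages"]["input"] = beats.class_counts()

    # (1) undersample the majority class
    idx_all = np.arange(len(beats))
    missing = [c for c in CLASSES if (beats.labels == c).sum() == 0]
    if missing:
        warnings.warn(f"classes absent from input: {missing}; passed through")
    if undersample:
        counts = beats.class_counts()
        majority = max(counts, key=counts.get)
        minority_max = max((v for c, v in counts.items() if c != majority),
                           default=0)
        n_target = min(counts[majority],
                       int(round(n_target_ratio * minority_max)))
        maj_rows = np.flatnonzero(beats.labels == majority)
        if 0 < n_target < len(maj_rows):
            sub, plan = proportional_undersample(
                beats.beats[maj_rows], K=min(cluster.K, len(maj_rows)),
                n_target=n_target, seed=seed, max_iter=cluster.max_iter,
                tol=cluster.tol)
            keep = np.sort(np.concatenate(
                [maj_rows[sub], np.flatnonzero(beats.labels != majority)]))
            idx_all = keep
            report["stages"]["undersample"] = {
                "majority": majority, "n_target": int(n_target),
                "quotas": plan.quotas.tolist(),
                "proportions": plan.proportions.round(6).tolist(),
                "kmeans_inertia": plan.inertia,
            }
    pool = beats.subset(idx_all)

    # (2)+(3) stratified splits
    rest, test_idx = stratified_split(pool.labels, split.test_fraction,
                                      split.seed, split.stratified)
    train_pool = pool.subset(rest)
    test = pool.subset(test_idx)
    tr_rest, val_idx = stratified_split(train_pool.labels,
                                        split.val_fraction_of_train,
                                        split.seed + 1, split.stratified)
    train = train_pool.subset(tr_rest)
    val = train_pool.subset(val_idx)
    report["stages"]["split"] = {
        "train": train.class_counts(), "val": val.class_counts(),
        "test": test.class_counts(),
    }

    # (4) oversample + clean the training split only
    if oversample:
        counts = train.class_counts()
        if smote_targets is None:
            present = sorted(v for v in counts.values() if v > 0)
            median = int(np.median(present))
            smote_targets = {c: median for c in ("S", "F")
                             if 0 < counts[c] < median}
        added = {}
        for ci, (cls, target) in enumerate(sorted(smote_targets.items())):
            have = counts.get(cls, 0)
            n_new = target - have
            if have == 0 or n_new <= 0:
                continue
            rows = np.flatnonzero(train.labels == cls)
            params = SmoteParams(
                k_neighbors=min(smote_params.k_neighbors, len(rows) - 1),
                lam_range=smote_params.lam_range, n_synthetic=n_new,
                seed=seed + 100 + ci)
            X_new = smote(train.beats[rows], params)
            synth = BeatMatrix(X_new, np.full(n_new, cls, dtype="U1"),
                               np.ones(n_new, dtype=bool), train.standardized)
            train = train.concat(synth)
            added[cls] = n_new
        report["stages"]["smote"] = added
    if tomek_policy is not None:
        before = len(train)
        _, _, kept = remove_links(train.beats, train.labels,
                                  policy=tomek_policy, max_rounds=tomek_rounds)
        train = train.subset(kept)
        report["stages"]["tomek"] = {"removed": before - len(train),
                                     "policy": tomek_policy,
                                     "rounds": tomek_rounds}
    report["stages"]["output"] = {
        "train": train.class_counts(), "val": val.class_counts(),
        "test": test.class_counts(),
        "synthetic_in_train": int(train.synthetic_flags.sum()),
        "synthetic_in_val": int(val.synthetic_flags.sum()),
        "synthetic_in_test": int(test.synthetic_flags.sum()),
    }
    # SMOTE rows are appended to the training split only; when the input
    # carried no synthetic provenance, val/test must stay synthetic-free.
    if not beats.synthetic_flags.any():
        assert not val.synthetic_flags.any() and not test.synthetic_flags.any()
    return {"train": train, "val": val, "test": test}, report
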