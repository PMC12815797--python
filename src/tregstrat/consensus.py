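"""Subsampled consensus K-means with PAC-based selection of K.

For each candidate K, the latent matrix is clustered ``n_reps`` times on
random subsamples (default 80% of samples, drawn without replacement,
K-means++ initialization with a replicate-specific seed).  The consensus
value of a sample pair is the fraction of replicates in which the pair
was co-clustered among those in which it was co-sampled.  Clustering
stability per K is summarized by the Proportion of Ambiguously Clustered
pairs (PAC): the mass of the off-diagonal consensus distribution falling
in the ambiguous interval (0.1, 0.9] by default — lower PAC means more
stable clustering, and the K with the lowest PAC wins (ties go to the
smallest K).  Final labels come from average-linkage hierarchical
clustering of the consensus dissimilarity ``1 - consensus`` cut at K,
renumbered so that cluster 1 is the largest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .datatypes import check_finite


@dataclass
class ConsensusConfig:
    k_range: list[int] = field(default_factory=lambda: list(range(3, 11)))
    n_reps: int = 1000
    subsample_frac: float = 0.8
    pac_lower: float = 0.1
    pac_upper: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if any(k < 2 for k in self.k_range):
            raise ValueError("all candidate K must be >= 2")
        if not 0.0 < self.subsample_frac <= 1.0:
            raise ValueError("subsample_frac must lie in (0, 1]")
        if not 0.0 <= self.pac_lower < self.pac_upper <= 1.0:
            raise ValueError("need 0 <= pac_lower < pac_upper <= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class ConsensusResult:
    K: int
    matrix: np.ndarray           # samples x samples consensus values in [0, 1]
    copair_counts: np.ndarray
    cosample_counts: np.ndarray
    sample_ids: list
    pac: float | None = None
    labels: np.ndarray | None = None  # 1..K, 1 = largest cluster
    replicates: list | None = None    # optional (subsample_idx, labels) log

    def offdiag_values(self) -> np.ndarray:
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        return self.matrix[iu]

    def cdf(self, grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Empirical CDF of the off-diagonal consensus values."""
        v = self.offdiag_values()
        if grid is None:
            grid = np.linspace(0.0, 1.0, 101)
        return grid, np.array([(v <= g).mean() for g in grid])


def consensus_matrix(
    latent, K: int, config: ConsensusConfig | None = None,
    keep_replicates: bool = False,
) -> ConsensusResult:
    """Build the consensus matrix for one K (no PAC / labels attached).

    ``keep_replicates=True`` stores every (subsample index, labels) pair
    on the result so the matrix can be recounted independently.
    """
    config = config or ConsensusConfig()
    config.validate()
    if isinstance(latent, pd.DataFrame):
        sample_ids = list(latent.index)
        X = latent.to_numpy(dtype=float)
    else:
        X = np.asarray(latent, dtype=float)
        sample_ids = list(range(X.shape[0]))
    check_finite(X, "latent matrix")
    n = X.shape[0]
    n_sub = int(np.floor(config.subsample_frac * n))
    if K >= n_sub:
        raise ValueError(
            f"K={K} must be smaller than the subsample size {n_sub}"
        )

    rng = np.random.default_rng([config.seed, K])
    copair = np.zeros((n, n), dtype=np.int32)
    cosample = np.zeros((n, n), dtype=np.int32)
    replicates = [] if keep_replicates else None
    for _ in range(config.n_reps):
        idx = rng.choice(n, size=n_sub, replace=False)
        rep_seed = int(rng.integers(2**31))
        km = KMeans(
            n_clusters=K, init="k-means++", n_init=1, max_iter=300, tol=1e-4,
            random_state=rep_seed,
        )
        labels = km.fit_predict(X[idx])
        if keep_replicates:
            replicates.append((idx.copy(), labels.copy()))
        cosample[np.ix_(idx, idx)] += 1
        for c in range(K):
            members = idx[labels == c]
            copair[np.ix_(members, members)] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(cosample > 0, copair / np.maximum(cosample, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)

    iu = np.triu_indices(n, k=1)
    n_zero = int((cosample[iu] == 0).sum())
    if n_zero:
        msg = f"{n_zero} sample pairs were never co-sampled (consensus set to 0)"
        if n_zero > 0.01 * iu[0].size:
            msg += "; increase n_reps or subsample_frac for adequate coverage"
        warnings.warn(msg, stacklevel=2)

    return ConsensusResult(
        K=K, matrix=consensus, copair_counts=copair, cosample_counts=cosample,
        sample_ids=sample_ids, replicates=replicates,
    )


def pac(
    result: ConsensusResult | np.ndarray,
    pac_lower: float = 0.1,
    pac_upper: float = 0.9,
) -> float:
    """Proportion of ambiguously clustered pairs: CDF(u2) - CDF(u1).

    Counts upper-triangular off-diagonal consensus values in the
    open-left/closed-right interval (pac_lower, pac_upper].
    """
    if isinstance(result, ConsensusResult):
        v = result.offdiag_values()
    else:
        m = np.asarray(result, dtype=float)
        v = m[np.triu_indices(m.shape[0], k=1)]
    return float(((v > pac_lower) & (v <= pac_upper)).mean())


def select_k(pac_by_k: dict[int, float]) -> int:
    """argmin PAC over candidate K; ties resolved toward the smallest K."""
    if not pac_by_k:
        raise ValueError("pac_by_k is empty")
    best_k, best = None, np.inf
    for k in sorted(pac_by_k):
        if pac_by_k[k] < best:
            best_k, best = k, pac_by_k[k]
    return best_k


def assign_clusters(result: ConsensusResult, K: int | None = None) -> np.ndarray:
    """Average-linkage clustering of 1 - consensus, cut at K; 1 = largest."""
    K = result.K if K is None else K
    n = result.matrix.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds sample count {n}")
    d = 1.0 - result.matrix
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(Z, t=K, criterion="maxclust")
    # renumber by decreasing size; ties keep first-occurrence order
    ids, counts = np.unique(raw, return_counts=True)
    first_seen = {c: int(np.argmax(raw == c)) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], first_seen[c]))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[c] for c in raw])


def silhouette(latent, labels) -> tuple[dict[int, float], float]:
    """Euclidean silhouette: (per-cluster means, overall mean).

    Singleton clusters receive silhouette 0 by convention.
    """
    X = latent.to_numpy(dtype=float) if isinstance(latent, pd.DataFrame) else \
        np.asarray(latent, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    s = silhouette_samples(X, labels, metric="euclidean")
    per_cluster = {int(c): float(s[labels == c].mean()) for c in uniq}
    return per_cluster, float(s.mean())


class ConsensusKMeans(ClusterMixin, BaseEstimator):
    """sklearn-style wrapper: scan K by PAC (or fix ``k``) and label samples.

    Fitted attributes: ``labels_`` (1..K), ``best_k_``, ``pac_by_k_``,
    ``consensus_matrix_``, ``pac_``, ``results_`` (per-K ConsensusResult).
    """

    def __init__(
        self,
        k_range=tuple(range(3, 11)),
        k: int | None = None,
        n_reps: int = 1000,
        subsample_frac: float = 0.8,
        pac_lower: float = 0.1,
        pac_upper: float = 0.9,
        seed: int = 0,
    ):
        self.k_range = k_range
        self.k = k
        self.n_reps = n_reps
        self.subsample_frac = subsample_frac
        self.pac_lower = pac_lower
        self.pac_upper = pac_upper
        self.seed = seed

    def _config(self) -> ConsensusConfig:
        return ConsensusConfig(
            k_range=list(self.k_range),
            n_reps=self.n_reps,
            subsample_frac=self.subsample_frac,
            pac_lower=self.pac_lower,
            pac_upper=self.pac_upper,
            seed=self.seed,
        )

    def fit(self, X, y=None):
        cfg = self._config()
        candidates = [self.k] if self.k is not None else cfg.k_range
        self.results_ = {}
        self.pac_by_k_ = {}
        for K in candidates:
            res = consensus_matrix(X, K, cfg)
            res.pac = pac(res, cfg.pac_lower, cfg.pac_upper)
            self.results_[K] = res
            self.pac_by_k_[K] = res.pac
        self.best_k_ = self.k if self.k is not None else select_k(self.pac_by_k_)
        best = self.results_[self.best_k_]
        best.labels = assign_clusters(best, self.best_k_)
        self.consensus_matrix_ = best.matrix
        self.pac_ = best.pac
        self.labels_ = best.labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
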