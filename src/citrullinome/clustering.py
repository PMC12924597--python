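"""Sample ordination and clustering: classical MDS, k-means, consensus
clustering by resampled k-means, and hierarchical clustering.

Consensus clustering follows the standard resampling scheme: for each
candidate k, samples are repeatedly subsampled without replacement,
clustered with k-means, and the fraction of co-sampled runs in which two
samples co-cluster is recorded in a consensus matrix.  The number of
clusters is chosen by the delta-area criterion on the CDFs of consensus
values (k = 2 uses the raw area), which makes the usually-visual choice
reproducible; the matrices themselves are retained for inspection.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)


def euclidean_distance_matrix(features: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between rows (samples)."""
    features = np.asarray(features, dtype=float)
    if np.isnan(features).any():
        raise ValueError("missing values present; impute first")
    return squareform(pdist(features, metric="euclidean"))


def classical_mds(d: np.ndarray, dims: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres B = −½ J D² J, eigendecomposes, and returns coordinates
    from the top ``dims`` positive eigenvalues (eigenvector × sqrt(eigenvalue))
    along with all eigenvalues in descending order.  If fewer than ``dims``
    eigenvalues are positive the embedding is truncated with a warning.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if (d < -1e-12).any() or not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("distance matrix must be non-negative with zero diagonal")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-12 * abs(evals[0]) if evals.size else 0)
    n_pos = int(pos.sum())
    if n_pos < dims:
        log.warning("only %d positive eigenvalues; returning %d dimensions",
                    n_pos, n_pos)
    k = min(dims, n_pos)
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    return coords, evals


def kmeans(x: np.ndarray, k: int, seed: int = 0,
           n_init: int = 10) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd k-means with k-means++ initialisation, best of ``n_init`` restarts."""
    x = np.asarray(x, dtype=float)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of samples {x.shape[0]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-point convergence notices
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                    max_iter=300, algorithm="lloyd",
                    random_state=seed % (2 ** 32)).fit(x)
    return km.labels_.copy(), km.cluster_centers_.copy(), float(km.inertia_)


@dataclass
class ConsensusParams:
    max_k: int = 8
    reps: int = 50
    p_item: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_k < 2:
            raise ValueError("max_k must be >= 2")
        if not 0 < self.p_item <= 1:
            raise ValueError("p_item must lie in (0, 1]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class ConsensusResult:
    params: ConsensusParams
    consensus: dict[int, np.ndarray]   # k -> sample × sample consensus matrix
    auc: dict[int, float]              # k -> area under the consensus CDF
    delta_area: dict[int, float]       # k=2: raw AUC; k>=3: relative increase
    chosen_k: int
    assignments: np.ndarray            # final labels at chosen_k

    def within_between(self, labels: np.ndarray, k: int | None = None
                       ) -> tuple[float, float]:
        """Mean consensus within and between externally given label groups."""
        m = self.consensus[self.chosen_k if k is None else k]
        labels = np.asarray(labels)
        n = m.shape[0]
        w, b = [], []
        for i in range(n):
            for j in range(i + 1, n):
                (w if labels[i] == labels[j] else b).append(m[i, j])
        return float(np.mean(w)), float(np.mean(b))


def _cdf_auc(values: np.ndarray) -> float:
    """Area under the empirical CDF of consensus values over [0, 1]."""
    v = np.sort(values)
    n = v.size
    if n == 0:
        return 0.0
    # step-function integral: CDF is i/n on [v_i, v_{i+1})
    grid = np.concatenate([v, [1.0]])
    steps = np.diff(grid)
    cdf = np.arange(1, n + 1) / n
    return float(np.sum(steps * cdf))


def consensus_cluster(x: np.ndarray, params: ConsensusParams) -> ConsensusResult:
    """Resampled k-means consensus clustering over k = 2..max_k.

    Per k: ``reps`` subsamples of ⌈p_item·n⌉ samples without replacement are
    clustered; consensus(i, j) = co-clustered runs / co-sampled runs.  Pairs
    never co-sampled are excluded from the CDF and treated as 0 in the final
    matrix (vanishingly rare at the default p_item and reps).  Final labels
    at the chosen k come from average-linkage clustering of 1 − consensus.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < params.max_k:
        raise ValueError("need at least max_k samples")
    n_sub = math.ceil(params.p_item * n)
    root = np.random.SeedSequence([params.seed & 0x7FFFFFFF, 0xC05E])
    consensus: dict[int, np.ndarray] = {}
    auc: dict[int, float] = {}
    for k in range(2, params.max_k + 1):
        co = np.zeros((n, n))
        tot = np.zeros((n, n))
        for rep in range(params.reps):
            rng = np.random.default_rng(
                np.random.SeedSequence([params.seed & 0x7FFFFFFF, k, rep]))
            idx = rng.choice(n, size=n_sub, replace=False)
            rep_seed = int(rng.integers(0, 2 ** 31 - 1))
            labels, _, _ = kmeans(x[idx], k, seed=rep_seed)
            same = (labels[:, None] == labels[None, :]).astype(float)
            co[np.ix_(idx, idx)] += same
            tot[np.ix_(idx, idx)] += 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where(tot > 0, co / np.maximum(tot, 1), np.nan)
        np.fill_diagonal(m, 1.0)
        iu = np.triu_indices(n, k=1)
        vals = m[iu]
        finite = vals[np.isfinite(vals)]
        if finite.size < vals.size:
            log.warning("k=%d: %d sample pairs never co-sampled",
                        k, int(vals.size - finite.size))
        auc[k] = _cdf_auc(finite)
        consensus[k] = np.nan_to_num(m, nan=0.0)
    delta: dict[int, float] = {2: auc[2]}
    for k in range(3, params.max_k + 1):
        prev = auc[k - 1]
        delta[k] = (auc[k] - prev) / prev if prev > 0 else 0.0
    chosen_k = max(delta, key=lambda k: (delta[k], -k))
    dist = 1.0 - consensus[chosen_k]
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    assignments = hierarchy.fcluster(z, t=chosen_k, criterion="maxclust") - 1
    return ConsensusResult(params=params, consensus=consensus, auc=auc,
                           delta_area=delta, chosen_k=chosen_k,
                           assignments=assignments)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over Euclidean distances."""

    linkage_matrix: np.ndarray
    n_items: int
    method: str

    def cut(self, k: int) -> np.ndarray:
        """Labels (0-based) for a cut into k clusters."""
        if not 1 <= k <= self.n_items:
            raise ValueError(f"cannot cut {self.n_items} items into {k} clusters")
        return hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust") - 1

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def hierarchical_cluster(features: np.ndarray, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of rows with the given linkage (Euclidean)."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2:
        raise ValueError("need at least 2 items")
    if linkage not in ("single", "complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    z = hierarchy.linkage(features, method=linkage, metric="euclidean")
    return Dendrogram(linkage_matrix=z, n_items=features.shape[0], method=linkage)
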