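"""Embedding-quality and cluster-structure metrics.

These turn visual claims about embeddings — "distinct clusters", "families
form their own groups", "a gradient follows admixture proportion" — into
assertable numbers.  All neighbour computations exclude self and break
distance ties by ascending sample index, so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph
import scipy.spatial.distance
import scipy.stats
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "MetricReport",
    "knn_indices",
    "knn_label_accuracy",
    "neighborhood_preservation",
    "adjusted_rand_index",
    "mutual_knn_components",
    "gradient_alignment",
]


@dataclass
class MetricReport:
    knn_accuracy: float | None = None
    neighborhood_preservation: float | None = None
    ari: float | None = None
    components: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("knn_accuracy", "neighborhood_preservation"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            for key in ("knn_accuracy", "neighborhood_preservation", "ari"):
                v = getattr(self, key)
                if v is not None:
                    fh.write(f"{key}\t{v:.6f}\n")
            if self.components is not None:
                fh.write(f"n_components\t{len(np.unique(self.components))}\n")


def knn_indices(coords: np.ndarray, k: int, chunk: int = 512) -> np.ndarray:
    """``(n, k)`` indices of each point's k nearest neighbours (self excluded).

    Euclidean distances; ties broken by ascending sample index.  Chunked so
    the full distance matrix is never materialized for large n.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    out = np.empty((n, k), dtype=np.int64)
    idx = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = scipy.spatial.distance.cdist(coords[start:stop], coords)
        d[idx[start:stop] - start, idx[start:stop]] = np.inf  # exclude self
        # lexsort: primary key distance, secondary key index (ascending)
        order = np.lexsort((np.broadcast_to(idx, d.shape), d), axis=1)
        out[start:stop] = order[:, :k]
    return out


def knn_label_accuracy(coords: np.ndarray, labels: np.ndarray, k: int = 15) -> float:
    """Fraction of samples whose k-NN majority label matches their own.

    Majority ties are broken in favour of the first tied label in sample
    order among the neighbours.  A single-class labelling returns 1 with a
    warning (nothing to separate).
    """
    labels = np.asarray(labels)
    codes, uniq = _encode(labels)
    if len(uniq) < 2:
        warnings.warn("only one class present; k-NN accuracy trivially 1", stacklevel=2)
        return 1.0
    nn = knn_indices(coords, k)
    correct = 0
    for i in range(len(labels)):
        neigh = codes[nn[i]]
        counts = np.bincount(neigh, minlength=len(uniq))
        best = counts.max()
        # first tied label in neighbour (sample) order
        for c in neigh:
            if counts[c] == best:
                majority = c
                break
        correct += majority == codes[i]
    return correct / len(labels)


def _encode(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, codes = np.unique(np.asarray(labels), return_inverse=True)
    return codes, uniq


def neighborhood_preservation(
    high_coords: np.ndarray, low_coords: np.ndarray, k: int = 15
) -> float:
    """Mean over samples of |kNN_high intersect kNN_low| / k.

    Measures how well the low-dimensional embedding preserves each sample's
    high-dimensional neighbourhood; 1 means every neighbourhood is intact,
    and a random low-dimensional arrangement gives about k/(n-1).
    """
    high_coords = np.asarray(high_coords)
    low_coords = np.asarray(low_coords)
    if high_coords.shape[0] != low_coords.shape[0]:
        raise ValueError("both spaces must contain the same samples in the same order")
    nn_h = knn_indices(high_coords, k)
    nn_l = knn_indices(low_coords, k)
    overlap = [
        len(np.intersect1d(nn_h[i], nn_l[i], assume_unique=True))
        for i in range(high_coords.shape[0])
    ]
    return float(np.mean(overlap)) / k


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Standard pair-counting ARI; 1 for identical partitions, ~0 at random."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def mutual_knn_components(coords: np.ndarray, k: int) -> np.ndarray:
    """Connected-component label per sample of the mutual k-NN graph.

    Two points are joined iff each lies in the other's k nearest neighbours.
    Components of this graph operationalize visually "disjoint clusters".
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, n - 1)
    nn = knn_indices(coords, k)
    rows = np.repeat(np.arange(n), k)
    cols = nn.ravel()
    A = scipy.sparse.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n)).tocsr()
    mutual = A.multiply(A.T)
    _, labels = scipy.sparse.csgraph.connected_components(mutual, directed=False)
    return labels


def gradient_alignment(coords: np.ndarray, values: np.ndarray) -> float:
    """|Spearman rho| between ``values`` and position along the first
    principal axis of ``coords``.

    Quantifies whether a quantity (admixture proportion, geography) varies
    monotonically along the dominant direction of a point cloud; invariant to
    monotone transforms of ``values`` and to rigid motions of ``coords``.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(values) == 0:
        raise ValueError("values are constant")
    centered = coords - coords.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    axis_pos = centered @ Vt[0]
    rho = scipy.stats.spearmanr(axis_pos, values).statistic
    return abs(float(rho))
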