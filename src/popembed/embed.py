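"""UMAP embeddings of PC scores, PC-count sweeps, reference projection, and
the t-SNE comparison harness.

The embedding algorithms themselves are delegated (UMAP to umap-learn, the
t-SNE joint probabilities and KL objective/gradient to scikit-learn); this
module owns parameterization, seeding, sweeping, projection of new cohorts
onto a fitted embedding, and error-trace handling.

Defaults follow the protocol this package reproduces: 15 nearest neighbours
(the UMAP default) with a minimum distance of 0.5, on the top 10 PCs.
Sensible ranges are 5-50 neighbours and 0.001-0.5 minimum distance.  Runs
are reproducible given (data, params, seed) under single-threaded execution;
axes are arbitrary and long distances between clusters are not meaningful,
so no API here summarizes inter-cluster distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Any

import numpy as np
from sklearn.metrics import pairwise_distances

from . import metrics as _metrics

logger = logging.getLogger(__name__)

__all__ = [
    "EmbedParams",
    "Embedding",
    "TsneParams",
    "fit_embedding",
    "transform_new",
    "pc_sweep",
    "neighbor_sensitivity",
    "fit_tsne",
    "align_error_traces",
    "save_coords",
]


@dataclass(frozen=True)
class EmbedParams:
    dims: int = 2
    n_neighbors: int = 15
    min_dist: float = 0.5
    n_pcs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.min_dist <= 0:
            raise ValueError("min_dist must be > 0")
        if not 5 <= self.n_neighbors <= 50:
            logger.info(
                "n_neighbors=%d outside the sensible 5-50 range", self.n_neighbors
            )
        if not 0.001 <= self.min_dist <= 0.5:
            logger.info("min_dist=%g outside the sensible 0.001-0.5 range", self.min_dist)


@dataclass
class Embedding:
    coords: np.ndarray  # (n, dims)
    params: EmbedParams
    fitted_state: Any  # opaque; enables transform of new samples

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")


@dataclass(frozen=True)
class TsneParams:
    perplexity: float = 30.0
    n_iter: int = 500
    init_mode: str = "default"  # or "from_embedding"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perplexity <= 0:
            raise ValueError("perplexity must be > 0")
        if self.init_mode not in ("default", "from_embedding"):
            raise ValueError("init_mode must be 'default' or 'from_embedding'")


def fit_embedding(scores: np.ndarray, params: EmbedParams) -> Embedding:
    """Fit UMAP on PC scores; deterministic given seed (single-threaded)."""
    import umap

    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("NaN/inf in scores")
    if scores.shape[0] < params.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={params.n_neighbors + 1} samples, "
            f"got {scores.shape[0]}"
        )
    with warnings.catch_warnings():
        # umap-learn warns that random_state forces single-threaded execution;
        # that is exactly the determinism contract we document.
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", category=UserWarning)
        reducer = umap.UMAP(
            n_components=params.dims,
            n_neighbors=params.n_neighbors,
            min_dist=params.min_dist,
            random_state=params.seed,
        )
        coords = reducer.fit_transform(scores)
    return Embedding(coords=np.asarray(coords), params=params, fitted_state=reducer)


def transform_new(emb: Embedding, new_scores: np.ndarray) -> np.ndarray:
    """Map new samples (on the same PC axes) into a fitted embedding.

    The reference embedding is left untouched; returns the new coordinates.
    """
    new_scores = np.asarray(new_scores, dtype=float)
    if new_scores.size == 0:
        return np.empty((0, emb.params.dims))
    n_fitted_dims = emb.fitted_state._raw_data.shape[1]
    if new_scores.ndim != 2 or new_scores.shape[1] != n_fitted_dims:
        raise ValueError(
            f"new_scores must be (m, {n_fitted_dims}); got {new_scores.shape}"
        )
    before = emb.coords.copy()
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        out = emb.fitted_state.transform(new_scores)
    assert np.array_equal(emb.coords, before)
    return np.asarray(out)


def pc_sweep(
    scores_full: np.ndarray,
    pc_counts: list[int],
    params: EmbedParams,
    labels: np.ndarray | None = None,
) -> list[tuple[int, Embedding, _metrics.MetricReport]]:
    """One embedding per PC count (shared seed), with quality metrics attached.

    Emulates the protocol of sweeping the number of leading PCs fed to the
    embedding and watching clusters refine.  Duplicate counts are
    deduplicated with a warning; order of first appearance is kept.
    """
    scores_full = np.asarray(scores_full, dtype=float)
    counts: list[int] = []
    for c in pc_counts:
        if c in counts:
            warnings.warn(f"duplicate PC count {c} ignored", stacklevel=2)
        else:
            counts.append(c)
    if counts and max(counts) > scores_full.shape[1]:
        raise ValueError(
            f"max PC count {max(counts)} exceeds available PCs {scores_full.shape[1]}"
        )
    results = []
    for c in counts:
        emb = fit_embedding(scores_full[:, :c], replace(params, n_pcs=c))
        rep = _metrics.MetricReport(
            knn_accuracy=(
                None
                if labels is None
                else _metrics.knn_label_accuracy(emb.coords, labels, k=params.n_neighbors)
            ),
            neighborhood_preservation=_metrics.neighborhood_preservation(
                scores_full[:, :c], emb.coords, k=params.n_neighbors
            ),
        )
        results.append((c, emb, rep))
    return results


def neighbor_sensitivity(
    scores: np.ndarray,
    family_ids: np.ndarray,
    n_neighbors_list: tuple[int, ...] = (5, 15),
    params: EmbedParams | None = None,
) -> dict[int, dict[Any, bool]]:
    """Do declared families split off as their own embedded clusters?

    For each neighbour count, fits an embedding and reports, per family,
    whether the family forms a distinct embedded cluster: a mutual-k-NN
    component (k equal to the neighbour count) of at least two points made up
    solely of that family's members.  The "solely" rule tolerates one member
    being absorbed into the population — the typical picture for a pedigree
    with a married-in founder — while still requiring a family-only cluster.
    Few neighbours emphasize close relatedness, so families tend to separate
    at low counts and be absorbed into their population at higher ones.

    ``family_ids`` uses None/NaN/"" for samples not in any family.
    """
    params = params or EmbedParams()
    fam = np.asarray(family_ids, dtype=object)
    declared = {}
    for i, f in enumerate(fam):
        if f is None or f == "" or (isinstance(f, float) and np.isnan(f)):
            continue
        declared.setdefault(f, []).append(i)
    for f, members in declared.items():
        if len(members) < 2:
            raise ValueError(f"family {f!r} has fewer than 2 members")
    report: dict[int, dict[Any, bool]] = {}
    for k in n_neighbors_list:
        emb = fit_embedding(scores, replace(params, n_neighbors=k))
        comp = _metrics.mutual_knn_components(emb.coords, k)
        by_family = {}
        for f, members in declared.items():
            member_set = set(members)
            own = False
            for c in np.unique(comp[members]):
                component = set(np.flatnonzero(comp == c))
                if len(component) >= 2 and component <= member_set:
                    own = True
                    break
            by_family[f] = bool(own)
        report[k] = by_family
    return report


# ---------------------------------------------------------------------------
# t-SNE comparison harness
# ---------------------------------------------------------------------------

def fit_tsne(
    scores: np.ndarray,
    params: TsneParams,
    init_coords: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """t-SNE with a per-iteration KL-divergence trace.

    ``init_mode='default'`` starts from small random coordinates and uses the
    standard early-exaggeration phase (factor 12 for the first 250
    iterations); ``init_mode='from_embedding'`` starts from ``init_coords``
    (e.g. a converged UMAP embedding, rescaled) with early exaggeration
    disabled.  The joint probabilities and KL objective/gradient are
    delegated to scikit-learn's t-SNE internals; the plain gradient-descent
    loop here exists to record the objective at every iteration.  The
    recorded trace is always the KL against the *unexaggerated* joint
    probabilities, so traces from the two modes are directly comparable.
    """
    from sklearn.manifold._t_sne import _joint_probabilities, _kl_divergence

    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if params.perplexity >= n / 3:
        raise ValueError(f"perplexity {params.perplexity} too large for n={n}")
    rng = np.random.default_rng(params.seed)
    D = pairwise_distances(scores, squared=True)
    P = _joint_probabilities(D, params.perplexity, 0)

    if params.init_mode == "from_embedding":
        if init_coords is None:
            raise ValueError("init_mode='from_embedding' requires init_coords")
        init_coords = np.asarray(init_coords, dtype=float)
        if init_coords.shape != (n, 2):
            raise ValueError(f"init_coords must be (n, 2), got {init_coords.shape}")
        # rescale to the small spread t-SNE expects at the start
        Y = init_coords - init_coords.mean(axis=0)
        Y = Y / np.abs(Y).max() * 1e-2
        exaggeration_iters = 0
    else:
        Y = rng.normal(0.0, 1e-4, size=(n, 2))
        exaggeration_iters = min(250, params.n_iter)

    pos = Y.ravel().copy()
    update = np.zeros_like(pos)
    gains = np.ones_like(pos)
    learning_rate = max(n / 12.0 / 4.0, 50.0)
    trace = np.empty(params.n_iter)
    for it in range(params.n_iter):
        exaggerating = it < exaggeration_iters
        if exaggerating:
            _, grad = _kl_divergence(pos, P * 12.0, 1.0, n, 2, compute_error=False)
            error, _ = _kl_divergence(pos, P, 1.0, n, 2, compute_error=True)
        else:
            error, grad = _kl_divergence(pos, P, 1.0, n, 2, compute_error=True)
        trace[it] = error
        momentum = 0.5 if exaggerating else 0.8
        inc = update * grad < 0.0
        gains[inc] += 0.2
        gains[~inc] = np.maximum(gains[~inc] * 0.8, 0.01)
        update = momentum * update - learning_rate * gains * grad
        pos += update
    coords = pos.reshape(n, 2)
    return coords, trace


def align_error_traces(
    trace_a: np.ndarray, trace_b: np.ndarray, shift: int
) -> np.ndarray:
    """Pair two error traces with ``trace_b`` offset forward by ``shift``.

    ``trace_b[i]`` is paired with ``trace_a[i + shift]`` (e.g. shifting a
    from-embedding trace by the epochs already spent building the initial
    embedding).  Returns the ``(overlap, 2)`` paired region.
    """
    trace_a = np.asarray(trace_a, dtype=float)
    trace_b = np.asarray(trace_b, dtype=float)
    if shift < 0:
        raise ValueError("shift must be >= 0")
    if shift >= trace_a.size:
        raise ValueError(f"shift {shift} leaves no overlap with trace of length {trace_a.size}")
    overlap = min(trace_a.size - shift, trace_b.size)
    if overlap <= 0:
        raise ValueError("no overlap between traces")
    return np.column_stack([trace_a[shift : shift + overlap], trace_b[:overlap]])


def save_coords(coords: np.ndarray, samples: list[str], path: str) -> None:
    """Tab-separated coordinates: sample_id, dim1..dimd."""
    import pandas as pd

    df = pd.DataFrame(coords, columns=[f"dim{i + 1}" for i in range(coords.shape[1])])
    df.insert(0, "sample_id", samples)
    df.to_csv(path, sep="\t", index=False)
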