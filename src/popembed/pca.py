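"""Standardized genotype PCA, variance accounting, and cohort projection.

Genotypes are standardized per variant as ``x = (g - 2p) / sqrt(2p(1-p))``
(the usual genotype-PCA normalization; unscaled centering is available as an
option), with missing calls mean-imputed to 0 after centering.  When a new
cohort is projected onto an existing model, the *model's* allele frequencies
are reused for standardization — never recomputed from the projected cohort —
matching the reference-embedding projection protocol.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PCModel",
    "standardize",
    "fit_pca",
    "genotype_pca",
    "project_samples",
    "variance_explained_range",
    "save_scores",
]


@dataclass
class PCModel:
    """Fitted PCA: frequencies, loadings, scores, and variance accounting.

    ``var_fraction[i]`` is component i's share of the total variance of the
    standardized matrix (all components, not just the ``k`` retained ones),
    so fractions over disjoint ranges add and sum to 1 at full rank.
    """

    freqs: np.ndarray | None
    loadings: np.ndarray  # (L, k), orthonormal columns
    scores: np.ndarray  # (n, k)
    singular_values: np.ndarray  # (k,)
    var_fraction: np.ndarray  # (k,)
    k: int
    variants: pd.DataFrame | None = None
    scaled: bool = True

    def __post_init__(self) -> None:
        if np.any(np.diff(self.var_fraction) > 1e-12):
            raise ValueError("var_fraction must be non-increasing")
        if self.var_fraction.sum() > 1.0 + 1e-9:
            raise ValueError("var_fraction sums above 1")


def standardize(
    G: GenotypeMatrix | np.ndarray,
    freqs: np.ndarray | None = None,
    scale: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Center (and by default scale) a genotype matrix; returns ``(X, freqs)``.

    ``x_ij = (g_ij - 2 p_j) / sqrt(2 p_j (1 - p_j))``; missing calls become 0
    after centering (mean imputation).  If ``freqs`` is omitted it is computed
    from the non-missing calls, in which case standardized columns have mean
    ~0.  Frequencies of exactly 0 or 1 are rejected: run QC first.
    """
    calls = G.calls if isinstance(G, GenotypeMatrix) else np.asarray(G)
    ok = calls != MISSING
    if freqs is None:
        n_called = ok.sum(axis=0)
        if (n_called == 0).any():
            raise ValueError("variant with no called genotypes")
        freqs = np.where(ok, calls, 0).sum(axis=0) / (2.0 * n_called)
    else:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.size != calls.shape[1]:
            raise ValueError("freqs length does not match variant count")
    if ((freqs <= 0.0) | (freqs >= 1.0)).any():
        raise ValueError("monomorphic variant (p in {0,1}); apply QC before PCA")
    X = np.where(ok, calls, 2.0 * freqs[None, :]) - 2.0 * freqs[None, :]
    if scale:
        X /= np.sqrt(2.0 * freqs * (1.0 - freqs))[None, :]
    return X, freqs


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Deterministic sign convention: each loading column's largest-magnitude
    entry is positive (in place)."""
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0


def fit_pca(
    X: np.ndarray,
    k: int,
    freqs: np.ndarray | None = None,
    variants: pd.DataFrame | None = None,
    scaled: bool = True,
) -> PCModel:
    """PCA of an already-standardized matrix via economy SVD.

    ``scores = X @ loadings``; ``var_fraction_i = s_i^2 / sum(all s^2)``.
    ``k`` beyond the numerical rank is truncated with a warning.  Output is
    deterministic: each loading column's largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    n, L = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(n, L):
        raise ValueError(f"k={k} exceeds min(n, L)={min(n, L)}")
    U, s, Vt = scipy.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    rank = int((s > s[0] * max(n, L) * np.finfo(float).eps).sum()) if s.size else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds numerical rank {rank}; truncating", stacklevel=2)
        k = rank
    loadings = Vt[:k].T.copy()
    scores = (U[:, :k] * s[:k]).copy()
    _fix_signs(loadings, scores)
    var_fraction = s[:k] ** 2 / total
    return PCModel(
        freqs=None if freqs is None else np.asarray(freqs, dtype=float),
        loadings=loadings,
        scores=scores,
        singular_values=s[:k].copy(),
        var_fraction=var_fraction,
        k=k,
        variants=variants,
        scaled=scaled,
    )


def genotype_pca(G: GenotypeMatrix, k: int, scale: bool = True) -> PCModel:
    """QC'd genotypes -> standardized PCA model (records freqs and variants)."""
    X, freqs = standardize(G, scale=scale)
    return fit_pca(X, k, freqs=freqs, variants=G.variants.copy(), scaled=scale)


def project_samples(model: PCModel, G_new: GenotypeMatrix) -> np.ndarray:
    """Project a new cohort onto the model's PC axes.

    Variants are matched by ``chrom:pos:ref:alt``; mismatches are dropped with
    a warning, and fewer than 50% overlap is an error.  Standardization uses
    the model's allele frequencies.
    """
    if model.variants is None or model.freqs is None:
        raise ValueError("model lacks variant records/frequencies; fit with genotype_pca")
    model_keys = pd.Index(
        model.variants["chrom"].astype(str)
        + ":"
        + model.variants["pos"].astype(str)
        + ":"
        + model.variants["ref"].astype(str)
        + ":"
        + model.variants["alt"].astype(str)
    )
    new_keys = G_new.variant_keys()
    pos_in_new = pd.Series(np.arange(len(new_keys)), index=new_keys)
    in_both = model_keys.isin(pos_in_new.index)
    n_overlap = int(in_both.sum())
    if n_overlap == 0:
        raise ValueError("no variant overlap between model and new cohort")
    if n_overlap < 0.5 * len(model_keys):
        raise ValueError(
            f"variant overlap {n_overlap}/{len(model_keys)} below 50%; refusing to project"
        )
    if n_overlap < len(model_keys):
        warnings.warn(
            f"dropping {len(model_keys) - n_overlap} model variants absent from new cohort",
            stacklevel=2,
        )
    model_idx = np.flatnonzero(in_both)
    new_idx = pos_in_new[model_keys[in_both]].to_numpy()
    X, _ = standardize(
        G_new.calls[:, new_idx], freqs=model.freqs[model_idx], scale=model.scaled
    )
    return X @ model.loadings[model_idx, :]


def variance_explained_range(model: PCModel, first_pc: int, last_pc: int) -> float:
    """Percentage of total variance carried by PCs ``first_pc..last_pc``
    (1-based, inclusive)."""
    if not 1 <= first_pc <= last_pc <= model.k:
        raise ValueError(
            f"PC range ({first_pc}, {last_pc}) outside 1..{model.k}"
        )
    return 100.0 * float(model.var_fraction[first_pc - 1 : last_pc].sum())


def save_scores(scores: np.ndarray, samples: list[str], path: str) -> None:
    """Tab-separated scores: sample_id then PC1..PCk."""
    df = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
    df.insert(0, "sample_id", samples)
    df.to_csv(path, sep="\t", index=False)
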