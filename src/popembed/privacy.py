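"""Privacy-preserving randomization of plotted attributes.

Before figures are published, per-point attributes are binned and then each
point's displayed value is copied from a uniformly chosen one of its k
nearest neighbours in the figure's coordinate space (default k=9 for
attributes, k=50 for colours).  Local distributions are preserved — a point's
neighbours look like it — while no displayed value is traceable to the
individual at that position.  Spatial coordinates instead get Gaussian
jitter followed by binning to a grid (50 km noise / 50 km bins by default;
5 km / 1 km for distance-from-a-landmark values).

Every randomized value provably originates among the point's k nearest
neighbours' original values; each figure/attribute should be randomized
independently (fresh seed per call).  These are plotting safeguards, not
formal differential-privacy guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import knn_indices

__all__ = [
    "PrivacyParams",
    "bin_values",
    "permute_attribute",
    "jitter_and_bin",
    "permute_colours",
]


@dataclass(frozen=True)
class PrivacyParams:
    k_attr: int = 9
    k_colour: int = 50
    bins_per_attribute: dict = field(default_factory=dict)  # attr -> count or {"width": w}
    default_bins: int = 20
    coord_noise_sd: float = 50.0  # km
    coord_bin: float = 50.0  # km
    dist_noise_sd: float = 5.0  # km
    dist_bin: float = 1.0  # km
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_attr < 1 or self.k_colour < 1:
            raise ValueError("neighbour counts must be >= 1")
        for v in (self.coord_noise_sd, self.dist_noise_sd):
            if v <= 0:
                raise ValueError("noise sds must be > 0")
        if self.default_bins < 1:
            raise ValueError("bins must be >= 1")


def bin_values(
    values: np.ndarray,
    count: int | None = None,
    width: float | None = None,
) -> np.ndarray:
    """Round an attribute to bin midpoints.

    With ``width``, bins are half-open intervals anchored at multiples of the
    width ([100, 150) for width 50), each value mapped to its bin midpoint.
    With ``count``, equal-width bins span the observed range — except that
    data already taking no more than ``count`` distinct values are returned
    unchanged, which makes binning idempotent.  Exactly one of ``count`` /
    ``width`` must be given.
    """
    values = np.asarray(values, dtype=float)
    if (count is None) == (width is None):
        raise ValueError("give exactly one of count or width")
    if width is not None:
        if width <= 0:
            raise ValueError("width must be > 0")
        return (np.floor(values / width) + 0.5) * width
    if count < 1:
        raise ValueError("count must be >= 1")
    if np.unique(values).size <= count:
        return values.copy()
    lo, hi = values.min(), values.max()
    w = (hi - lo) / count
    idx = np.clip(np.floor((values - lo) / w).astype(int), 0, count - 1)
    return lo + (idx + 0.5) * w


def _copy_from_neighbours(
    coords: np.ndarray, originals: np.ndarray, k: int, seed: int | None
) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    rng = np.random.default_rng(seed)
    nn = knn_indices(coords, k)
    donors = nn[np.arange(n), rng.integers(0, k, size=n)]
    return originals[donors]


def permute_attribute(
    coords: np.ndarray,
    values: np.ndarray,
    k_attr: int = 9,
    seed: int | None = None,
) -> np.ndarray:
    """Replace each point's (already binned) value with a random neighbour's.

    Each point independently copies the ORIGINAL value of one of its
    ``k_attr`` nearest neighbours (self excluded; a donor keeps its own
    value, so a value can appear twice).  The input array is not modified.
    """
    values = np.asarray(values)
    return _copy_from_neighbours(coords, values.copy(), k_attr, seed)


def jitter_and_bin(
    values: np.ndarray,
    noise_sd: float,
    bin_width: float,
    seed: int | None = None,
) -> np.ndarray:
    """Add Normal(0, noise_sd) then round to the nearest multiple of
    ``bin_width`` (the treatment for spatial coordinates)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    noisy = values + rng.normal(0.0, noise_sd, size=values.shape)
    return np.round(noisy / bin_width) * bin_width


def permute_colours(
    coords: np.ndarray,
    rgb: np.ndarray,
    k_colour: int = 50,
    seed: int | None = None,
) -> np.ndarray:
    """Neighbour-copy randomization of RGB triples (a triple moves atomically).

    Same contract as :func:`permute_attribute`, applied to whole colours:
    channels are never mixed between donors.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 2 or rgb.shape[1] != 3:
        raise ValueError("rgb must be (n, 3)")
    return _copy_from_neighbours(coords, rgb.copy(), k_colour, seed)
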