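"""Colour encodings for embedding figures.

Two encodings are provided: per-sample admixture proportions mapped directly
to RGB (100% ancestry = channel value 255), and 3D embedding coordinates
mapped to RGB by independent per-axis min-max scaling so nearby points get
nearby colours.  Group (e.g. country-of-birth) colours are the per-group mean
taken in embedding space before the colour conversion.  Channel quantization
is round-half-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ColourTable",
    "admixture_to_rgb",
    "embedding3_to_rgb",
    "group_mean_colour",
    "truncate_coordinates",
]

#: Default ancestry-to-channel assignment: red=African, green=European,
#: blue=Asian/Native American (columns of the proportion matrix in that
#: order).  ``channel_map`` permutes it.
DEFAULT_CHANNEL_MAP = (0, 1, 2)


@dataclass
class ColourTable:
    """Integer RGB triples (0-255 per channel) keyed by sample or group id."""

    keys: list
    rgb: np.ndarray  # (n, 3) integers

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.int64)
        if self.rgb.shape != (len(self.keys), 3):
            raise ValueError("rgb must be (len(keys), 3)")
        if self.rgb.min() < 0 or self.rgb.max() > 255:
            raise ValueError("channels must lie in [0, 255]")

    def to_frame(self, hex_column: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.rgb, columns=["r", "g", "b"])
        df.insert(0, "key", self.keys)
        if hex_column:
            df["hex"] = [f"#{r:02x}{g:02x}{b:02x}" for r, g, b in self.rgb]
        return df

    def write(self, path: str, hex_column: bool = False) -> None:
        self.to_frame(hex_column).to_csv(path, sep="\t", index=False)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def admixture_to_rgb(
    props: np.ndarray,
    keys: list | None = None,
    channel_map: tuple[int, int, int] = DEFAULT_CHANNEL_MAP,
) -> ColourTable:
    """Three ancestry proportions per sample -> RGB, 100% mapping to 255.

    ``channel_map[c]`` names the proportion column feeding channel ``c``
    (default: column 0 African -> red, 1 European -> green, 2 Asian/Native
    American -> blue; pass a permutation for alternate assignments).
    """
    props = np.asarray(props, dtype=float)
    if props.ndim != 2 or props.shape[1] != 3:
        raise ValueError("props must be (n, 3)")
    if (props < 0).any():
        raise ValueError("proportions must be non-negative")
    if np.abs(props.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("each proportion triple must sum to 1 (within 1e-6)")
    if sorted(channel_map) != [0, 1, 2]:
        raise ValueError("channel_map must be a permutation of (0, 1, 2)")
    rgb = _round_half_up(255.0 * props[:, list(channel_map)])
    keys = list(keys) if keys is not None else list(range(props.shape[0]))
    return ColourTable(keys=keys, rgb=rgb)


def _minmax_scale_255(coords: np.ndarray) -> np.ndarray:
    lo = coords.min(axis=0)
    rng = np.ptp(coords, axis=0)
    scaled = np.empty_like(coords, dtype=float)
    for a in range(coords.shape[1]):
        if rng[a] == 0:
            scaled[:, a] = 128.0  # degenerate axis: mid-grey channel
        else:
            scaled[:, a] = 255.0 * (coords[:, a] - lo[a]) / rng[a]
    return scaled


def embedding3_to_rgb(coords: np.ndarray, keys: list | None = None) -> ColourTable:
    """3D embedding coordinates -> RGB via independent per-axis min-max scaling.

    The affine map makes colour distance at most
    ``255 * ||dx|| * sqrt(3) / min(axis range)``, so nearby points in the
    embedding receive nearby colours.  A zero-range axis maps to 128.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    rgb = _round_half_up(_minmax_scale_255(coords))
    keys = list(keys) if keys is not None else list(range(coords.shape[0]))
    return ColourTable(keys=keys, rgb=rgb)


def group_mean_colour(
    coords3: np.ndarray,
    group_of_sample: np.ndarray,
    include_mask: np.ndarray | None = None,
) -> ColourTable:
    """Per-group colour from the mean 3D embedding position of its members.

    Means are taken in embedding space (then converted with the same per-axis
    scaling as the individual colours, computed from the individual-level
    coordinates), matching the way countries are coloured by the mean x, y, z
    of individuals born there.  ``include_mask`` excludes samples from the
    means without affecting the colour scale — e.g. to keep a large diaspora
    group from skewing its birth country's colour.  Groups with no included
    samples are omitted with a warning.
    """
    coords3 = np.asarray(coords3, dtype=float)
    if coords3.ndim != 2 or coords3.shape[1] != 3:
        raise ValueError("coords3 must be (n, 3)")
    groups = np.asarray(group_of_sample)
    if groups.shape[0] != coords3.shape[0]:
        raise ValueError("one group per sample required")
    mask = (
        np.ones(coords3.shape[0], dtype=bool)
        if include_mask is None
        else np.asarray(include_mask, dtype=bool)
    )
    lo = coords3.min(axis=0)
    rng = np.ptp(coords3, axis=0)
    keys, rows = [], []
    for g in pd.unique(groups):
        sel = (groups == g) & mask
        if not sel.any():
            warnings.warn(f"group {g!r} has no included samples; omitted", stacklevel=2)
            continue
        mean = coords3[sel].mean(axis=0)
        channels = np.where(rng == 0, 128.0, 255.0 * (mean - lo) / np.where(rng == 0, 1, rng))
        keys.append(g)
        rows.append(_round_half_up(channels))
    return ColourTable(keys=keys, rgb=np.array(rows, dtype=np.int64).reshape(len(keys), 3))


def truncate_coordinates(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Clip plotting coordinates into [lo, hi] (e.g. northing to 100-700 km)."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    return np.clip(np.asarray(values, dtype=float), lo, hi)
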