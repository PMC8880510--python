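"""Peritumoral shell features: first-order statistics of the tissue ring
immediately surrounding the tumour mask."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..volumes import LabeledVolume
from .firstorder import first_order_statistics

#: the 16 peritumoral feature names (first-order statistics, peri_ prefix)
PERITUMORAL_BASE = [
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "maximum",
    "range",
    "p10",
    "p90",
    "interquartile_range",
    "energy",
    "root_mean_square",
    "entropy",
    "uniformity",
    "mean_absolute_deviation",
]
PERITUMORAL_NAMES = ["peri_" + n for n in PERITUMORAL_BASE]


def peritumoral_ring(mask: np.ndarray, spacing, thickness_mm: float) -> np.ndarray:
    """Shell of voxels within ``thickness_mm`` (Euclidean, spacing-aware)
    of the mask surface, excluding the mask itself."""
    if thickness_mm <= 0:
        raise ValueError("ring thickness must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    ring = (dist > 0) & (dist <= thickness_mm)
    if not ring.any():
        raise ValueError("peritumoral ring is empty (mask fills the grid?)")
    return ring


def peritumoral_features(
    vol: LabeledVolume, ring: np.ndarray, n_bins: int = 32
) -> dict[str, float]:
    """16 first-order features of the ring intensities, ``peri_``-prefixed."""
    if (ring & vol.mask).any():
        raise ValueError("ring overlaps the tumour mask")
    stats = first_order_statistics(vol.intensities[ring], n_bins=n_bins)
    return {"peri_" + k: stats[k] for k in PERITUMORAL_BASE}
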