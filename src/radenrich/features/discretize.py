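"""Grey-level discretization (fixed bin number over the in-mask range)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volumes import LabeledVolume


@dataclass
class DiscretizedVolume:
    """Integer grey levels 1..n_levels inside the mask, 0 outside."""

    levels: np.ndarray  # int grid, 0 outside mask
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray
    spacing: tuple[float, float, float]

    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(vol: LabeledVolume, n_bins: int = 32) -> DiscretizedVolume:
    """Fixed-bin-number discretization over the in-mask intensity range.

    Level of voxel x is ``floor((x - min) / (max - min) * n_bins) + 1``
    clipped to ``[1, n_bins]``; a constant region maps to level 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = vol.masked_values()
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.intensities.shape, dtype=np.int32)
    if hi == lo:
        levels[vol.mask] = 1
        edges = np.array([lo, hi])
        n_levels = 1
    else:
        scaled = (vol.intensities[vol.mask] - lo) / (hi - lo) * n_bins
        levels[vol.mask] = np.clip(np.floor(scaled).astype(np.int32) + 1, 1, n_bins)
        edges = np.linspace(lo, hi, n_bins + 1)
        n_levels = n_bins
    return DiscretizedVolume(
        levels=levels,
        mask=vol.mask,
        n_levels=n_levels,
        bin_edges=edges,
        spacing=vol.spacing,
    )
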