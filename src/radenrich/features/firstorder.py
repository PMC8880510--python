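"""First-order intensity statistics and shape features."""

from __future__ import annotations

import numpy as np
from skimage import measure

from ..volumes import LabeledVolume

FIRST_ORDER_NAMES = [
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "maximum",
    "range",
    "p10",
    "p25",
    "p75",
    "p90",
    "interquartile_range",
    "energy",
    "root_mean_square",
    "entropy",
    "uniformity",
    "mean_absolute_deviation",
]


def first_order_statistics(values: np.ndarray, n_bins: int = 32,
                           prefix: str = "") -> dict[str, float]:
    """First-order statistics of an intensity sample.

    Variance uses population (1/n) moments; skewness and kurtosis (excess)
    are defined as 0 for a constant sample; entropy and uniformity come
    from a fixed-bin-number histogram over the sample range (a constant
    sample has entropy 0 and uniformity 1).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty intensity sample")
    mu = float(v.mean())
    var = float(v.var())
    if var > 0:
        sd = np.sqrt(var)
        skew = float((((v - mu) / sd) ** 3).mean())
        kurt = float((((v - mu) / sd) ** 4).mean() - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    if v.max() > v.min():
        hist, _ = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    else:
        hist = np.array([v.size])
    p = hist[hist > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    out = {
        "mean": mu,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(p50),
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        "range": float(v.max() - v.min()),
        "p10": float(p10),
        "p25": float(p25),
        "p75": float(p75),
        "p90": float(p90),
        "interquartile_range": float(p75 - p25),
        "energy": float((v**2).sum()),
        "root_mean_square": float(np.sqrt((v**2).mean())),
        "entropy": entropy,
        "uniformity": uniformity,
        "mean_absolute_deviation": float(np.abs(v - mu).mean()),
    }
    if prefix:
        out = {prefix + k: x for k, x in out.items()}
    return out


def first_order(vol: LabeledVolume, n_bins: int = 32) -> dict[str, float]:
    return first_order_statistics(vol.masked_values(), n_bins=n_bins)


SHAPE_NAMES = [
    "volume_ml",
    "voxel_count",
    "surface_area_mm2",
    "sphericity",
    "surface_to_volume_ratio",
]


def shape(vol: LabeledVolume) -> dict[str, float]:
    """Shape features from the mask alone.

    ``volume_ml`` is voxel count x physical voxel volume / 1000; the
    surface is a marching-cubes mesh of the (zero-padded) mask, so a
    single-voxel mask yields the small octahedral surface of that voxel
    by convention rather than an error.
    """
    nvox = vol.n_voxels
    volume_mm3 = nvox * vol.voxel_volume_mm3
    padded = np.pad(vol.mask.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=vol.spacing
    )
    area = float(measure.mesh_surface_area(verts, faces))
    sphericity = float(np.pi ** (1 / 3) * (6 * volume_mm3) ** (2 / 3) / area)
    return {
        "volume_ml": volume_mm3 / 1000.0,
        "voxel_count": float(nvox),
        "surface_area_mm2": area,
        "sphericity": sphericity,
        "surface_to_volume_ratio": area / volume_mm3,
    }
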