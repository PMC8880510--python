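"""Feature registry and the one-call extractor for a labelled volume."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..volumes import LabeledVolume
from .discretize import discretize
from .firstorder import FIRST_ORDER_NAMES, SHAPE_NAMES, first_order, shape
from .peritumoral import PERITUMORAL_NAMES, peritumoral_features, peritumoral_ring
from .texture import (
    GLCM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
    glszm,
    glszm_features,
    ngtdm_features,
)

#: class tag -> ordered feature names
FEATURE_REGISTRY: dict[str, list[str]] = {
    "statistical": FIRST_ORDER_NAMES,
    "shape": SHAPE_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "peritumoral": PERITUMORAL_NAMES,
}

MANDATORY_FEATURES = [
    "volume_ml",
    "short_run_emphasis",
    "run_length_nonuniformity_normalized",
    "small_zone_emphasis",
]


def feature_class(name: str) -> str:
    for cls, names in FEATURE_REGISTRY.items():
        if name in names:
            return cls
    raise KeyError(name)


def all_feature_names(classes=None) -> list[str]:
    classes = classes or list(FEATURE_REGISTRY)
    out: list[str] = []
    for cls in FEATURE_REGISTRY:
        if cls in classes:
            out.extend(FEATURE_REGISTRY[cls])
    return out


@dataclass
class ExtractionConfig:
    n_bins: int = 32
    resample_mm: float | None = None  # isotropic resampling before texture
    ring_thickness_mm: float = 2.0
    classes: list[str] = field(
        default_factory=lambda: list(FEATURE_REGISTRY)
    )

    def __post_init__(self):
        unknown = set(self.classes) - set(FEATURE_REGISTRY)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class FeatureVector:
    """Named feature map plus the extraction settings that produced it."""

    values: dict[str, float]
    settings: dict

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values)


def extract_all(vol: LabeledVolume, config: ExtractionConfig | None = None) -> FeatureVector:
    """Compute every enabled feature class on one labelled volume.

    Texture classes require >= 2 in-mask voxels; shape and first-order
    features are defined down to a single voxel.  Ordering follows the
    registry, and the returned settings record bin count, spacing and
    resampling so extractions are reproducible.
    """
    config = config or ExtractionConfig()
    work = vol
    if config.resample_mm is not None:
        work = vol.resample_isotropic(config.resample_mm)

    texture_classes = {"glcm", "glrlm", "glszm", "ngtdm"}
    wants_texture = texture_classes & set(config.classes)
    if wants_texture and work.n_voxels < 2:
        raise ValueError(
            "texture features are undefined for a single-voxel mask; "
            "restrict classes to shape/statistical instead"
        )

    values: dict[str, float] = {}
    if "statistical" in config.classes:
        values.update(first_order(work, n_bins=config.n_bins))
    if "shape" in config.classes:
        values.update(shape(work))
    if wants_texture:
        d = discretize(work, n_bins=config.n_bins)
        if "glcm" in config.classes:
            values.update(glcm_features(glcm(d)))
        if "glrlm" in config.classes:
            values.update(glrlm_features(glrlm(d), work.n_voxels))
        if "glszm" in config.classes:
            values.update(glszm_features(glszm(d), work.n_voxels))
        if "ngtdm" in config.classes:
            values.update(ngtdm_features(d))
    if "peritumoral" in config.classes:
        ring = peritumoral_ring(work.mask, work.spacing, config.ring_thickness_mm)
        values.update(peritumoral_features(work, ring, n_bins=config.n_bins))

    ordered = {n: values[n] for n in all_feature_names(config.classes)}
    bad = [n for n, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad}")
    return FeatureVector(
        values=ordered,
        settings={
            "n_bins": config.n_bins,
            "resample_mm": config.resample_mm,
            "ring_thickness_mm": config.ring_thickness_mm,
            "classes": list(config.classes),
            "spacing": list(work.spacing),
        },
    )


def extract_batch(
    volumes: dict[str, LabeledVolume], config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Extract features for many volumes; one row per id."""
    rows = {pid: extract_all(v, config).values for pid, v in volumes.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df
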