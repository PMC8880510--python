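"""Pre-modelling feature filters.

Two screens run before any survival modelling:

* a *spatial stability* screen: every feature is recomputed after small
  ROI perturbations (one-voxel 6-connected erosion and dilation) across a
  set of lesions, and features whose concordance correlation coefficient
  (CCC) with the unperturbed values falls below a threshold (default 0.5,
  strict ``<``) are excluded;
* a *volume redundancy* filter: features whose Pearson correlation with
  lesion volume exceeds 0.8 in magnitude (strict ``>``) are dropped,
  while volume itself is always retained.

The accounting identity ``n_total = n_unstable + n_volume_redundant +
n_retained`` is reported for every run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import ExtractionConfig, extract_all
from .volumes import LabeledVolume

logger = logging.getLogger(__name__)


class MaskEmptyError(ValueError):
    """Raised when an ROI perturbation empties the mask."""


def concordance_ccc(x, y, moments: str = "population") -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2), using
    population (1/n) moments by default (``moments='sample'`` switches to
    n-1 denominators; the ratio is nearly identical for n >~ 20).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must have equal length >= 2")
    ddof = 0 if moments == "population" else 1
    vx, vy = x.var(ddof=ddof), y.var(ddof=ddof)
    if vx == 0 and vy == 0:
        raise ValueError("CCC undefined: both inputs are constant")
    cov = ((x - x.mean()) * (y - y.mean())).sum() / (len(x) - ddof)
    return float(2 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def perturb_roi(mask: np.ndarray, mode: str, voxels: int = 1) -> np.ndarray:
    """One small 6-connected morphological perturbation of an ROI mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MaskEmptyError("mask is empty")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    if mode == "erode":
        out = ndimage.binary_erosion(mask, structure=structure, iterations=voxels)
        if not out.any():
            raise MaskEmptyError("erosion removed every voxel")
    elif mode == "dilate":
        out = ndimage.binary_dilation(mask, structure=structure, iterations=voxels)
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    return out


def unstable_features(min_ccc: pd.Series, threshold: float = 0.5) -> list[str]:
    """Names whose minimum CCC is defined and *strictly* below threshold
    (a feature sitting exactly at the threshold is retained)."""
    return [f for f, v in min_ccc.items() if np.isfinite(v) and v < threshold]


@dataclass
class StabilityReport:
    """Per-feature minimum CCC over ROI perturbations, with exclusions."""

    ccc: pd.DataFrame  # index feature, columns per perturbation + 'min'
    threshold: float
    excluded: list[str]
    skipped_lesions: list[int] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return [f for f in self.ccc.index if f not in set(self.excluded)]

    def to_frame(self) -> pd.DataFrame:
        out = self.ccc.copy()
        out["excluded"] = out.index.isin(set(self.excluded))
        return out


def stability_screen(
    volumes: list[LabeledVolume],
    extraction: ExtractionConfig | None = None,
    ccc_threshold: float = 0.5,
    perturbations: tuple[str, ...] = ("erode", "dilate"),
) -> StabilityReport:
    """Assess spatial stability of every feature across lesions.

    For each perturbation mode the CCC between original-ROI and
    perturbed-ROI feature values (across lesions) is computed; a feature
    is excluded iff its minimum CCC over perturbations is < threshold
    (strict).  Lesions whose erosion empties the mask are skipped with a
    log entry; a feature whose CCC is undefined (constant in both
    sequences) is retained with a warning.
    """
    if len(volumes) < 10:
        warnings.warn(
            f"stability screen on only {len(volumes)} lesions; "
            "CCC estimates will be noisy",
            stacklevel=2,
        )
    extraction = extraction or ExtractionConfig()
    rows_orig: list[pd.Series] = []
    rows_pert: dict[str, list[pd.Series]] = {m: [] for m in perturbations}
    skipped: list[int] = []
    for i, vol in enumerate(volumes):
        try:
            pert_masks = {m: perturb_roi(vol.mask, m) for m in perturbations}
        except MaskEmptyError as err:
            logger.warning("lesion %d skipped in stability screen: %s", i, err)
            skipped.append(i)
            continue
        rows_orig.append(extract_all(vol, extraction).to_series())
        for m, pm in pert_masks.items():
            pvol = LabeledVolume(vol.intensities, pm, vol.spacing)
            rows_pert[m].append(extract_all(pvol, extraction).to_series())
    if len(rows_orig) < 2:
        raise ValueError("need at least 2 usable lesions for a stability screen")
    orig = pd.DataFrame(rows_orig)
    ccc = pd.DataFrame(index=orig.columns)
    for m in perturbations:
        pert = pd.DataFrame(rows_pert[m])
        vals = []
        for f in orig.columns:
            try:
                vals.append(concordance_ccc(orig[f], pert[f]))
            except ValueError:
                warnings.warn(
                    f"CCC undefined for feature {f!r} ({m}); retained",
                    stacklevel=2,
                )
                vals.append(np.nan)
        ccc[m] = vals
    ccc["min"] = ccc.min(axis=1)
    excluded = unstable_features(ccc["min"], ccc_threshold)
    return StabilityReport(
        ccc=ccc, threshold=ccc_threshold, excluded=excluded, skipped_lesions=skipped
    )


def volume_redundancy_filter(
    features: pd.DataFrame,
    volume_name: str = "volume_ml",
    r_threshold: float = 0.8,
) -> tuple[list[str], pd.Series]:
    """Drop features with |Pearson r| > r_threshold against volume.

    Returns (retained feature names, per-feature correlation with
    volume).  Volume itself is always retained; constant features have
    undefined r and are retained with a warning.
    """
    if volume_name not in features.columns:
        raise ValueError(f"volume feature {volume_name!r} not present")
    vol = features[volume_name].to_numpy(dtype=float)
    if vol.std() == 0:
        warnings.warn("volume feature is constant; redundancy filter is a "
                      "no-op", stacklevel=2)
        return list(features.columns), pd.Series(
            np.nan, index=features.columns, name="r_volume"
        )
    corrs = {}
    retained = []
    for f in features.columns:
        if f == volume_name:
            corrs[f] = 1.0
            retained.append(f)
            continue
        x = features[f].to_numpy(dtype=float)
        if x.std() == 0 or vol.std() == 0:
            warnings.warn(f"feature {f!r} constant; volume correlation "
                          "undefined, retained", stacklevel=2)
            corrs[f] = np.nan
            retained.append(f)
            continue
        r = float(np.corrcoef(x, vol)[0, 1])
        corrs[f] = r
        if not abs(r) > r_threshold:
            retained.append(f)
    return retained, pd.Series(corrs, name="r_volume")


@dataclass
class FilterAccounting:
    n_total: int
    n_unstable: int
    n_volume_redundant: int
    n_retained: int

    def __post_init__(self):
        assert (
            self.n_total
            == self.n_unstable + self.n_volume_redundant + self.n_retained
        ), "filter accounting identity violated"

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_unstable": self.n_unstable,
            "n_volume_redundant": self.n_volume_redundant,
            "n_retained": self.n_retained,
        }


def apply_filters(
    features: pd.DataFrame,
    stability: StabilityReport | None = None,
    volume_name: str = "volume_ml",
    r_threshold: float = 0.8,
) -> tuple[pd.DataFrame, FilterAccounting]:
    """Run the stability exclusion (if a report is given) then the volume
    redundancy filter; returns the filtered matrix and the accounting."""
    n_total = features.shape[1]
    cols = list(features.columns)
    n_unstable = 0
    if stability is not None:
        unstable = [c for c in cols if c in set(stability.excluded)]
        n_unstable = len(unstable)
        cols = [c for c in cols if c not in set(unstable)]
    if volume_name in cols:
        retained, _ = volume_redundancy_filter(
            features[cols], volume_name=volume_name, r_threshold=r_threshold
        )
    else:
        retained = cols
    acc = FilterAccounting(
        n_total=n_total,
        n_unstable=n_unstable,
        n_volume_redundant=len(cols) - len(retained),
        n_retained=len(retained),
    )
    logger.info("feature filter accounting: %s", acc.to_dict())
    return features[retained], acc
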