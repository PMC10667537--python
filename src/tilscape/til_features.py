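"""Per-slide TILs scoring.

Region assignment of nucleus centroids, stromal/intratumoural TILs counts,
the AI-based sTILs percentage (fraction of tumour-associated stroma area
occupied by immune nuclei), and the cell-type co-occurrence matrix with its
derived scalar features.

Feature definitions
-------------------
* ``stils_count`` — immune nuclei whose centroid lies in tumour-associated
  stroma (TAS).
* ``ttils_count`` — immune nuclei whose centroid lies in the effective
  tumour region (intratumoural TILs are operationalized by centroid
  membership; "direct contact" is not computable from centroids alone).
* ``total_tils`` — all non-excluded immune nuclei.
* ``stils_pct`` — 100 x (summed area of TAS immune nuclei) / (TAS pixel
  area), clamped to [0, 100]; undefined (``None``) when TAS is empty.
* ``cm[a, b]`` — number of unordered nucleus pairs of types (a, b) within
  ``radius_px`` of each other (Euclidean, centroid-to-centroid); cross-type
  pairs increment both symmetric cells, same-type pairs the diagonal once.
* ``heterogeneity`` — Shannon entropy (bits) of the CM normalized over the
  upper triangle including the diagonal.
* ``contrast`` — immune-involving off-diagonal mass fraction of that same
  normalized CM.

The heterogeneity and contrast definitions are this package's declared
substitutes for feature names that appear in the literature without a
formula; they are simple, dimensionless, and pinned by tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .region_ops import AnalysisRegions, apply_exclusions, capture_tas
from .slide_model import (
    CM_TYPES,
    NucleusRecord,
    NucleusType,
    RegionMaskSet,
    SlideFeatures,
    round_half_up,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RegionLabel",
    "LabelledNucleus",
    "CoocConfig",
    "FeatureConfig",
    "assign_regions",
    "count_tils",
    "stils_percentage",
    "cooccurrence_matrix",
    "cm_features",
    "compute_slide_features",
]


class RegionLabel(str, Enum):
    TUMOUR_REGION = "tumour_region"
    TAS = "tas"
    OTHER = "other"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class LabelledNucleus:
    nucleus: NucleusRecord
    region_label: RegionLabel


@dataclass(frozen=True)
class CoocConfig:
    """Co-occurrence parameters: pairing radius (px) and the ordered types
    in scope."""

    radius_px: float = 32.0
    types_in_scope: tuple[str, ...] = CM_TYPES

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("cooc radius_px must be > 0")


@dataclass(frozen=True)
class FeatureConfig:
    """All tunable knobs of the per-slide feature pipeline."""

    tas_dilation_radius: int = 8
    tas_fill_radius: int = 32
    tas_fill_mode: str = "close_then_fill"
    tissue_min_object_area: int = 64
    cooc_radius_px: float = 32.0
    default_nucleus_area: float = 28.0


def assign_regions(
    nuclei: Iterable[NucleusRecord], regions: AnalysisRegions
) -> list[LabelledNucleus]:
    """Label each nucleus by the analysis region containing its rounded
    centroid pixel; out-of-bounds or excluded-territory nuclei get
    ``excluded`` and are dropped from all downstream features."""
    h, w = regions.shape
    out = []
    for rec in nuclei:
        r, c = round_half_up(rec.y), round_half_up(rec.x)
        if not (0 <= r < h and 0 <= c < w):
            logger.warning("nucleus %s at (%s, %s) out of bounds: excluded", rec.id, rec.x, rec.y)
            label = RegionLabel.EXCLUDED
        elif regions.tumour_eff[r, c]:
            label = RegionLabel.TUMOUR_REGION
        elif regions.tas[r, c]:
            label = RegionLabel.TAS
        elif regions.other[r, c]:
            label = RegionLabel.OTHER
        else:
            label = RegionLabel.EXCLUDED
        out.append(LabelledNucleus(rec, label))
    return out


def count_tils(labelled: Iterable[LabelledNucleus]) -> tuple[int, int, int]:
    """(sTILs, tTILs, total TILs) counts over immune nuclei."""
    stils = ttils = total = 0
    for ln in labelled:
        if ln.nucleus.nucleus_type is not NucleusType.IMMUNE:
            continue
        if ln.region_label is RegionLabel.EXCLUDED:
            continue
        total += 1
        if ln.region_label is RegionLabel.TAS:
            stils += 1
        elif ln.region_label is RegionLabel.TUMOUR_REGION:
            ttils += 1
    return stils, ttils, total


def stils_percentage(
    labelled: Iterable[LabelledNucleus],
    regions: AnalysisRegions,
    default_nucleus_area: float = 28.0,
) -> float | None:
    """Percentage of TAS area occupied by immune nuclei.

    Nuclei without a measured area contribute ``default_nucleus_area``
    pixels.  Returns ``None`` (undefined, distinct from 0%) when TAS has
    zero area; values beyond 100% are clamped with a warning.
    """
    tas_area = int(regions.tas.sum())
    if tas_area == 0:
        logger.warning("TAS area is zero: sTILs percentage undefined")
        return None
    occupied = 0.0
    for ln in labelled:
        if ln.region_label is RegionLabel.TAS and ln.nucleus.nucleus_type is NucleusType.IMMUNE:
            area = ln.nucleus.area_px
            occupied += default_nucleus_area if area is None else area
    pct = 100.0 * occupied / tas_area
    if pct > 100.0:
        logger.warning("immune area exceeds TAS area; clamping percentage to 100")
        pct = 100.0
    return pct


def cooccurrence_matrix(
    labelled: Sequence[LabelledNucleus], config: CoocConfig | None = None
) -> np.ndarray:
    """Symmetric KxK co-occurrence count matrix over the types in scope.

    Uses a k-d tree; the output is contractually identical to the O(n^2)
    all-pairs count at the same radius.
    """
    config = config or CoocConfig()
    type_idx = {t: i for i, t in enumerate(config.types_in_scope)}
    k = len(config.types_in_scope)
    cm = np.zeros((k, k), dtype=np.int64)
    pts, ti = [], []
    for ln in labelled:
        t = ln.nucleus.nucleus_type.value
        if ln.region_label is not RegionLabel.EXCLUDED and t in type_idx:
            pts.append((ln.nucleus.x, ln.nucleus.y))
            ti.append(type_idx[t])
    if len(pts) < 2:
        return cm
    pts_arr = np.asarray(pts)
    ti_arr = np.asarray(ti)
    pairs = cKDTree(pts_arr).query_pairs(config.radius_px, output_type="ndarray")
    if len(pairs) == 0:
        return cm
    a = ti_arr[pairs[:, 0]]
    b = ti_arr[pairs[:, 1]]
    same = a == b
    np.add.at(cm, (a[same], b[same]), 1)
    np.add.at(cm, (a[~same], b[~same]), 1)
    np.add.at(cm, (b[~same], a[~same]), 1)
    return cm


def cm_features(cm: np.ndarray) -> tuple[int, int, float, float]:
    """(stroma-immune co-occ, tumour-immune co-occ, heterogeneity bits,
    immune contrast) from a symmetric co-occurrence matrix."""
    cm = np.asarray(cm)
    if not np.array_equal(cm, cm.T):
        raise ValueError("co-occurrence matrix must be symmetric")
    if (cm < 0).any():
        raise ValueError("co-occurrence matrix must be nonnegative")
    it = CM_TYPES.index("tumour")
    ist = CM_TYPES.index("stromal")
    ii = CM_TYPES.index("immune")
    si = int(cm[ist, ii])
    tiv = int(cm[it, ii])
    upper = cm[np.triu_indices(cm.shape[0])].astype(float)
    total = upper.sum()
    if total == 0:
        return si, tiv, 0.0, 0.0
    p = upper / total
    p = p[p > 0]
    heterogeneity = float(-(p * np.log2(p)).sum())
    contrast = float((cm[it, ii] + cm[ist, ii]) / total)
    return si, tiv, heterogeneity, contrast


def compute_slide_features(
    nuclei: Sequence[NucleusRecord],
    masks: RegionMaskSet,
    config: FeatureConfig | None = None,
) -> SlideFeatures:
    """Full per-slide pipeline: exclusions -> TAS capture -> region
    assignment -> counts -> percentage -> co-occurrence features.

    Deterministic for fixed inputs and config, and invariant to the order
    in which nuclei are supplied.
    """
    config = config or FeatureConfig()
    clean = apply_exclusions(masks)
    regions = capture_tas(
        clean["tumour"],
        clean["stroma"],
        dilation_radius=config.tas_dilation_radius,
        fill_radius=config.tas_fill_radius,
        fill_mode=config.tas_fill_mode,
        tissue=clean["tissue"],
    )
    labelled = assign_regions(nuclei, regions)
    stils, ttils, total = count_tils(labelled)
    pct = stils_percentage(labelled, regions, config.default_nucleus_area)
    cm = cooccurrence_matrix(labelled, CoocConfig(radius_px=config.cooc_radius_px))
    si, tiv, het, contrast = cm_features(cm)
    return SlideFeatures(
        stils_count=stils,
        ttils_count=ttils,
        total_tils=total,
        stils_pct=pct,
        cm=cm,
        stroma_immune_cooc=si,
        tumour_immune_cooc=tiv,
        heterogeneity=het,
        contrast=contrast,
    )
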