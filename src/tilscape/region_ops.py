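"""Tissue-mask generation, exclusion handling, and capture of
tumour-associated stroma (TAS) by morphological operations.

The TAS recipe: dilate the tumour regions with a disc of radius 8 px, fill
holes with a disc of radius 32 px, and call any stroma captured inside the
resulting tumour envelope TAS.  "Filling with a disc of radius r" is
interpreted, by default, as morphological closing with a disc of radius r
followed by binary hole filling (``close_then_fill``); the alternative
reading — fill only cavities that admit no disc larger than r — is available
as ``fill_only``.

Masks are padded by the structuring-element radius with background before
any morphology and cropped afterwards, so the image edge never creates
artificial TAS.  Discs are closed Euclidean balls: a pixel belongs to the
disc iff its centre is within distance r of the origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.morphology import disk, remove_small_objects

from .slide_model import RegionMaskSet

logger = logging.getLogger(__name__)

__all__ = ["AnalysisRegions", "compute_tissue_mask", "apply_exclusions", "capture_tas"]


@dataclass
class AnalysisRegions:
    """Disjoint analysis regions on the shared pixel grid.

    ``tumour_eff`` is the effective (post-exclusion) tumour region, ``tas``
    the tumour-associated stroma, ``other`` the remaining tissue.  Any pixel
    outside all three is excluded territory.
    """

    tumour_eff: np.ndarray
    tas: np.ndarray
    other: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.tumour_eff, self.tas, self.other)}
        if len(shapes) != 1:
            raise ValueError(f"region grids disagree on shape: {shapes}")
        if (self.tumour_eff & self.tas).any() or (self.tumour_eff & self.other).any() or (
            self.tas & self.other
        ).any():
            raise ValueError("analysis regions must be pairwise disjoint")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tumour_eff.shape


def compute_tissue_mask(
    image: np.ndarray,
    threshold: str | float = "otsu",
    min_object_area: int = 64,
) -> np.ndarray:
    """Threshold an RGB/grayscale image into a binary tissue mask.

    Pipeline: grayscale conversion, global threshold (Otsu by default) on
    the inverted intensity (tissue is darker than the slide background),
    small-object removal, hole filling.  A constant-intensity image yields
    an empty mask with a warning — the threshold is undefined there.

    Parameters
    ----------
    threshold:
        ``"otsu"`` or a fixed float on the inverted, [0, 1]-normalized
        intensity scale.
    min_object_area:
        Connected components smaller than this (pixels) are dropped.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = rgb2gray(img)
    else:
        img = img.astype(float)
        if np.issubdtype(np.asarray(image).dtype, np.integer):
            img = img / 255.0
    inv = img.max() - img
    if np.ptp(inv) == 0:
        logger.warning("constant-intensity image: tissue threshold undefined, returning empty mask")
        return np.zeros(img.shape, dtype=bool)
    thr = threshold_otsu(inv) if threshold == "otsu" else float(threshold)
    mask = inv > thr
    # keep components of area >= min_object_area
    mask = remove_small_objects(mask, max_size=int(min_object_area) - 1)
    return ndi.binary_fill_holes(mask)


def apply_exclusions(masks: RegionMaskSet) -> RegionMaskSet:
    """Remove DCIS and excluded-artefact pixels from tissue/tumour/stroma.

    Nuclei falling on removed pixels are later labelled ``excluded`` and
    dropped from every downstream feature.
    """
    drop = masks["dcis"] | masks["excluded"]
    out = {
        "tissue": masks["tissue"] & ~drop,
        "tumour": masks["tumour"] & ~drop,
        "stroma": masks["stroma"] & ~drop,
        "dcis": masks["dcis"].copy(),
        "excluded": masks["excluded"].copy(),
    }
    if masks["tissue"].any() and not out["tissue"].any():
        logger.warning("exclusions cover all tissue: every analysis region is empty")
    return RegionMaskSet(out, scale_note=masks.scale_note)


def _fill_small_holes(mask: np.ndarray, max_disc_radius: float) -> np.ndarray:
    """Fill only cavities whose largest inscribed disc has radius <= r."""
    filled = ndi.binary_fill_holes(mask)
    holes = filled & ~mask
    if not holes.any():
        return mask.copy()
    out = mask.copy()
    labels, n = ndi.label(holes)
    # Distance from each hole pixel to non-hole territory bounds the
    # largest disc the cavity admits.
    dist = ndi.distance_transform_edt(holes)
    for lab in range(1, n + 1):
        sel = labels == lab
        if dist[sel].max() <= max_disc_radius:
            out |= sel
    return out


def capture_tas(
    tumour: np.ndarray,
    stroma: np.ndarray,
    dilation_radius: int = 8,
    fill_radius: int = 32,
    fill_mode: str = "close_then_fill",
    tissue: np.ndarray | None = None,
) -> AnalysisRegions:
    """Capture tumour-associated stroma inside the dilated tumour envelope.

    ``envelope = hole_fill(close(dilate(tumour, disc(dilation_radius)),
    disc(fill_radius)))`` and ``tas = envelope & stroma``.  With both radii
    zero the envelope reduces to the raw tumour with its enclosed holes
    filled, so TAS is exactly tumour-enclosed stroma.
    """
    if dilation_radius < 0 or fill_radius < 0:
        raise ValueError("dilation_radius and fill_radius must be >= 0")
    if fill_mode not in ("close_then_fill", "fill_only"):
        raise ValueError(f"unknown fill_mode {fill_mode!r}")
    tumour = np.asarray(tumour, dtype=bool)
    stroma = np.asarray(stroma, dtype=bool)
    if tumour.shape != stroma.shape:
        raise ValueError(f"tumour {tumour.shape} and stroma {stroma.shape} shapes differ")
    if (tumour & stroma).any():
        raise ValueError("tumour and stroma must be disjoint (run mask repair first)")

    pad = int(dilation_radius) + int(fill_radius) + 1
    env = np.pad(tumour, pad, constant_values=False)
    if dilation_radius > 0:
        env = ndi.binary_dilation(env, structure=disk(int(dilation_radius)))
    if fill_mode == "close_then_fill":
        if fill_radius > 0:
            se = disk(int(fill_radius))
            env = ndi.binary_erosion(ndi.binary_dilation(env, structure=se), structure=se)
        env = ndi.binary_fill_holes(env)
    else:
        env = _fill_small_holes(env, float(fill_radius))
    env = env[pad:-pad, pad:-pad]

    tas = env & stroma
    if tissue is None:
        tissue = tumour | stroma
    other = tissue & ~tumour & ~tas
    return AnalysisRegions(tumour_eff=tumour.copy(), tas=tas, other=other)
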