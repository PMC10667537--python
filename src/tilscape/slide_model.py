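"""Domain types and I/O for nuclei tables, region masks and cohort tables.

Coordinate convention
---------------------
Pixel coordinates are 0-based with ``x`` the column and ``y`` the row,
``y`` increasing downward.  A nucleus at ``(x, y)`` lies inside a mask iff
``mask[round(y), round(x)]`` is set, with half-up rounding.  All spatial
computation happens at one shared resolution — typically the downsampled
grid on which nucleus centroids were mapped; :attr:`RegionMaskSet.scale_note`
carries that provenance as free text and no unit conversion is attempted.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from shapely.geometry import shape as shapely_shape

logger = logging.getLogger(__name__)

__all__ = [
    "NucleusType",
    "NucleusRecord",
    "RegionMaskSet",
    "SlideFeatures",
    "PatientRecord",
    "CM_TYPES",
    "REGION_NAMES",
    "COHORT_COLUMNS",
    "round_half_up",
    "read_nuclei",
    "write_nuclei",
    "read_masks",
    "write_masks",
    "read_features",
    "write_features",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

#: Region names every :class:`RegionMaskSet` carries (missing rasters are empty).
REGION_NAMES = ("tissue", "tumour", "stroma", "dcis", "excluded")

#: Ordered nucleus types entering the co-occurrence matrix.
CM_TYPES = ("tumour", "stromal", "immune")


def round_half_up(v: float) -> int:
    """Round to the nearest integer, ties away from the floor (0.5 -> 1)."""
    return int(math.floor(v + 0.5))


class NucleusType(str, Enum):
    TUMOUR = "tumour"
    STROMAL = "stromal"
    IMMUNE = "immune"
    NORMAL_EPITHELIAL = "normal_epithelial"
    OTHER = "other"

    @classmethod
    def coerce(cls, label: str) -> "NucleusType":
        """Map a free-text label to a nucleus type; unknown labels become OTHER."""
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            logger.warning("unknown nucleus type %r mapped to 'other'", label)
            return cls.OTHER


@dataclass(frozen=True)
class NucleusRecord:
    """One detected nucleus: the atom of all spatial features."""

    id: str
    x: float
    y: float
    nucleus_type: NucleusType
    area_px: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"nucleus {self.id}: non-finite coordinates ({self.x}, {self.y})")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"nucleus {self.id}: negative coordinates ({self.x}, {self.y})")
        if self.area_px is not None and self.area_px < 0:
            raise ValueError(f"nucleus {self.id}: negative area {self.area_px}")


class RegionMaskSet:
    """Co-registered binary region masks sharing one shape.

    Invariants enforced on construction (each repair is logged with pixel
    counts): all masks share one shape; ``tissue`` covers ``tumour`` and
    ``stroma``; ``tumour`` and ``stroma`` are disjoint, overlap being removed
    from ``stroma``.
    """

    def __init__(self, masks: Mapping[str, np.ndarray], scale_note: str = "") -> None:
        named = {}
        shapes = {}
        for name in masks:
            if name not in REGION_NAMES:
                raise ValueError(f"unknown region name {name!r}; expected one of {REGION_NAMES}")
        for name in REGION_NAMES:
            if name in masks:
                arr = np.asarray(masks[name])
                if arr.ndim != 2:
                    raise ValueError(f"mask {name!r} must be 2-D, got shape {arr.shape}")
                named[name] = arr.astype(bool)
                shapes[name] = arr.shape
        if not named:
            raise ValueError("at least one mask required")
        uniq = set(shapes.values())
        if len(uniq) > 1:
            raise ValueError(f"mask shape mismatch: {shapes}")
        shp = next(iter(uniq))
        for name in REGION_NAMES:
            named.setdefault(name, np.zeros(shp, dtype=bool))

        # Annotated regions are authoritative: grow tissue to cover them.
        cover = named["tumour"] | named["stroma"]
        missing = int((cover & ~named["tissue"]).sum())
        if missing:
            logger.warning("tissue mask grown to cover %d annotated region pixels", missing)
            named["tissue"] = named["tissue"] | cover
        overlap = int((named["tumour"] & named["stroma"]).sum())
        if overlap:
            logger.warning("tumour/stroma overlap: %d pixels removed from stroma", overlap)
            named["stroma"] = named["stroma"] & ~named["tumour"]

        self.masks: dict[str, np.ndarray] = named
        self.scale_note = scale_note

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks["tissue"].shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def equals(self, other: "RegionMaskSet") -> bool:
        return all(np.array_equal(self.masks[n], other.masks[n]) for n in REGION_NAMES)


@dataclass
class SlideFeatures:
    """Per-slide TILs outputs.

    ``stils_pct`` is ``None`` when the tumour-associated stroma has zero
    area (an undefined percentage, distinct from 0%).  ``cm`` is the
    symmetric co-occurrence count matrix over :data:`CM_TYPES`.
    """

    stils_count: int
    ttils_count: int
    total_tils: int
    stils_pct: float | None
    cm: np.ndarray
    stroma_immune_cooc: int
    tumour_immune_cooc: int
    heterogeneity: float
    contrast: float

    def __post_init__(self) -> None:
        self.cm = np.asarray(self.cm, dtype=np.int64)
        if self.cm.shape != (len(CM_TYPES), len(CM_TYPES)):
            raise ValueError(f"cm must be {len(CM_TYPES)}x{len(CM_TYPES)}, got {self.cm.shape}")
        if not np.array_equal(self.cm, self.cm.T):
            raise ValueError("co-occurrence matrix must be symmetric")
        if (self.cm < 0).any():
            raise ValueError("co-occurrence matrix must be nonnegative")
        if min(self.stils_count, self.ttils_count, self.total_tils) < 0:
            raise ValueError("TILs counts must be nonnegative")
        if self.stils_count + self.ttils_count > self.total_tils:
            raise ValueError("stils_count + ttils_count exceeds total_tils")
        if self.stils_pct is not None and not (0.0 <= self.stils_pct <= 100.0):
            raise ValueError(f"stils_pct out of [0, 100]: {self.stils_pct}")
        t, s, i = (CM_TYPES.index("tumour"), CM_TYPES.index("stromal"), CM_TYPES.index("immune"))
        if self.stroma_immune_cooc != int(self.cm[s, i]) or self.tumour_immune_cooc != int(self.cm[t, i]):
            raise ValueError("co-occurrence scalars inconsistent with cm")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SlideFeatures):
            return NotImplemented
        return (
            (self.stils_count, self.ttils_count, self.total_tils) ==
            (other.stils_count, other.ttils_count, other.total_tils)
            and self.stils_pct == other.stils_pct
            and np.array_equal(self.cm, other.cm)
            and (self.stroma_immune_cooc, self.tumour_immune_cooc) ==
                (other.stroma_immune_cooc, other.tumour_immune_cooc)
            and self.heterogeneity == other.heterogeneity
            and self.contrast == other.contrast
        )

    def to_row(self) -> dict:
        """Flat scalar view for joining into a cohort table."""
        return {
            "stils_count": self.stils_count,
            "ttils_count": self.ttils_count,
            "total_tils": self.total_tils,
            "stils_pct": self.stils_pct,
            "stroma_immune_cooc": self.stroma_immune_cooc,
            "tumour_immune_cooc": self.tumour_immune_cooc,
            "heterogeneity": self.heterogeneity,
            "contrast": self.contrast,
        }


@dataclass
class PatientRecord:
    """One cohort row: clinicopathological covariates and follow-up."""

    patient_id: str
    age_years: float
    size_cm: float
    grade: int
    ln_positive: bool
    lvi: bool
    npi_group: str
    pr_positive: bool
    ki67_high: bool
    time_months: float
    event: bool
    slide_features: SlideFeatures | None = None
    visual_stils_pct: float | None = None
    split_label: str = "unassigned"

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3):
            raise ValueError(f"patient {self.patient_id}: grade must be 1/2/3")
        if self.npi_group not in ("good", "moderate", "poor"):
            raise ValueError(f"patient {self.patient_id}: bad npi_group {self.npi_group!r}")
        if not np.isfinite(self.time_months) or self.time_months < 0:
            raise ValueError(f"patient {self.patient_id}: bad follow-up time {self.time_months}")
        if self.event and self.time_months <= 0:
            raise ValueError(f"patient {self.patient_id}: event with non-positive follow-up time")


#: Column dictionary for cohort CSV files (one row per patient).
COHORT_COLUMNS = {
    "patient_id": "unique patient identifier",
    "age_years": "age at diagnosis, years",
    "size_cm": "invasive tumour size, cm",
    "grade": "histological grade, 1/2/3",
    "ln_positive": "lymph-node metastasis, 0/1",
    "lvi": "lymphovascular invasion, 0/1",
    "npi_group": "Nottingham Prognostic Index group: good/moderate/poor",
    "pr_positive": "progesterone-receptor positivity, 0/1",
    "ki67_high": "Ki67 index >= 20%, 0/1",
    "time_months": "breast-cancer-specific follow-up, months",
    "event": "breast-cancer-specific death, 0/1",
    "visual_stils_pct": "optional pathologist sTILs percentage",
    "split_label": "discovery / test / unassigned",
}


# ---------------------------------------------------------------------------
# Nuclei I/O
# ---------------------------------------------------------------------------

def _records_from_frame(df: pd.DataFrame) -> list[NucleusRecord]:
    for col in ("x", "y", "type"):
        if col not in df.columns:
            raise ValueError(f"nuclei table missing required column {col!r}")
    records = []
    has_area = "area" in df.columns
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            x = float(getattr(row, "x"))
            y = float(getattr(row, "y"))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"nuclei table row {idx}: non-numeric coordinate") from exc
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError(f"nuclei table row {idx}: non-numeric coordinate")
        area = None
        if has_area:
            a = getattr(row, "area")
            if a is not None and not (isinstance(a, float) and math.isnan(a)):
                area = float(a)
        rid = str(getattr(row, "id")) if "id" in df.columns else f"n{idx}"
        records.append(NucleusRecord(rid, x, y, NucleusType.coerce(getattr(row, "type")), area))
    return records


def _records_from_geojson(doc: dict) -> list[NucleusRecord]:
    feats = doc.get("features")
    if feats is None:
        raise ValueError("GeoJSON document missing required column 'features'")
    records = []
    for idx, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if "type" not in props:
            raise ValueError(f"GeoJSON feature {idx} missing required column 'type'")
        geom = shapely_shape(feat["geometry"])
        if geom.geom_type == "Point":
            x, y, area = geom.x, geom.y, None
        elif geom.geom_type == "Polygon":
            c = geom.centroid
            x, y, area = c.x, c.y, geom.area
        else:
            raise ValueError(f"GeoJSON feature {idx}: unsupported geometry {geom.geom_type}")
        rid = str(feat.get("id", f"n{idx}"))
        records.append(NucleusRecord(rid, float(x), float(y), NucleusType.coerce(props["type"]), area))
    return records


def read_nuclei(path: str | Path, format_hint: str | None = None) -> list[NucleusRecord]:
    """Read a nuclei table (CSV/TSV with columns x, y, type[, area], or a
    GeoJSON FeatureCollection of points/polygons with a ``type`` property).

    Polygons yield their centroid and polygon area; row order is preserved.
    Unknown type labels map to ``other`` with a logged warning.
    """
    path = Path(path)
    fmt = format_hint
    if fmt is None:
        fmt = "geojson" if path.suffix.lower() in (".json", ".geojson") else "table"
    if fmt == "geojson":
        with open(path) as fh:
            return _records_from_geojson(json.load(fh))
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return _records_from_frame(pd.read_csv(path, sep=sep))


def write_nuclei(records: Iterable[NucleusRecord], path: str | Path) -> None:
    rows = [
        {"id": r.id, "x": r.x, "y": r.y, "type": r.nucleus_type.value, "area": r.area_px}
        for r in records
    ]
    pd.DataFrame(rows, columns=["id", "x", "y", "type", "area"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Mask I/O
# ---------------------------------------------------------------------------

def read_masks(paths_by_name: Mapping[str, str | Path], scale_note: str = "") -> RegionMaskSet:
    """Read single-channel rasters (PNG/TIFF), nonzero meaning in-region."""
    masks = {}
    shapes = {}
    for name, p in paths_by_name.items():
        arr = np.asarray(iio.imread(Path(p)))
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise ValueError(f"mask {name!r} at {p} is not single-channel (shape {arr.shape})")
        masks[name] = arr != 0
        shapes[name] = arr.shape
    if len(set(shapes.values())) > 1:
        raise ValueError(f"mask shape mismatch: {shapes}")
    return RegionMaskSet(masks, scale_note=scale_note)


def write_masks(masks: RegionMaskSet, out_dir: str | Path, fmt: str = "png") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in REGION_NAMES:
        p = out_dir / f"{name}.{fmt}"
        iio.imwrite(p, (masks[name].astype(np.uint8) * 255))
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# Feature I/O
# ---------------------------------------------------------------------------

def write_features(features: SlideFeatures, path: str | Path) -> None:
    """Serialize per-slide features as JSON: flat scalars plus the labelled CM."""
    doc = features.to_row()
    doc["cm"] = {
        "types": list(CM_TYPES),
        "counts": features.cm.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_features(path: str | Path) -> SlideFeatures:
    with open(path) as fh:
        doc = json.load(fh)
    cm_doc = doc["cm"]
    if tuple(cm_doc["types"]) != CM_TYPES:
        raise ValueError(f"unexpected CM type order {cm_doc['types']}")
    return SlideFeatures(
        stils_count=int(doc["stils_count"]),
        ttils_count=int(doc["ttils_count"]),
        total_tils=int(doc["total_tils"]),
        stils_pct=None if doc["stils_pct"] is None else float(doc["stils_pct"]),
        cm=np.asarray(cm_doc["counts"], dtype=np.int64),
        stroma_immune_cooc=int(doc["stroma_immune_cooc"]),
        tumour_immune_cooc=int(doc["tumour_immune_cooc"]),
        heterogeneity=float(doc["heterogeneity"]),
        contrast=float(doc["contrast"]),
    )


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

_BOOL_COLS = ("ln_positive", "lvi", "pr_positive", "ki67_high", "event")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly normalize) a cohort table in place."""
    required = [c for c in COHORT_COLUMNS if c not in ("visual_stils_pct", "split_label")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id values: {dups[:5]}")
    for col in _BOOL_COLS:
        df[col] = df[col].astype(int).astype(bool)
    if (df["time_months"] < 0).any() or ~np.isfinite(df["time_months"]).all():
        raise ValueError("time_months must be finite and >= 0")
    bad = df["event"] & (df["time_months"] <= 0)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} subjects have an event at time 0; ambiguous follow-up is rejected"
        )
    if not df["grade"].isin([1, 2, 3]).all():
        raise ValueError("grade must be 1/2/3")
    if not df["npi_group"].isin(["good", "moderate", "poor"]).all():
        raise ValueError("npi_group must be good/moderate/poor")
    if "split_label" not in df.columns:
        df["split_label"] = "unassigned"
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in _BOOL_COLS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
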