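"""Synthetic slides and cohorts with the statistical structure of an
early-stage luminal breast-cancer TILs study.

Slides are spatial point patterns on a pixel grid: tumour nests are unioned
random discs, stroma is the remaining tissue, tumour/stromal nuclei are
homogeneous Poisson within their regions, and immune nuclei split between
stroma and tumour with the stromal immune density decaying with distance to
the tumour boundary (``border_attraction``).  The generator records exact
planted counts per analysis region, so the feature pipeline can be checked
against ground truth nucleus by nucleus.

Cohorts share a per-patient log-normal latent immune intensity: stromal and
intratumoural TILs counts are conditionally Poisson given that latent (with
independent multiplicative noise), which induces the positive sTILs-tTILs
correlation observed in real cohorts; survival is exponential with a
proportional-hazards link to standardized log TILs burden (so Cox recovery
is a clean check), administratively censored at a horizon; ordinal
clinicopathological covariates are thresholded from the same latent, giving
the expected directions of association (higher grade, larger size, nodal
spread and high Ki67 with higher TILs; younger age with higher TILs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .region_ops import apply_exclusions, capture_tas
from .slide_model import NucleusRecord, NucleusType, RegionMaskSet, round_half_up
from .til_features import FeatureConfig, RegionLabel

__all__ = ["SlideSimConfig", "CohortSimConfig", "generate_slide", "generate_cohort"]


@dataclass(frozen=True)
class SlideSimConfig:
    """Virtual-slide parameters.

    Densities are nuclei per 1000 px^2; ``immune_intensity`` is the
    slide-level latent immune rate on the same scale.
    ``stromal_fraction_of_immune`` splits immune nuclei between stroma and
    tumour (stromal TILs dominate in practice); ``border_attraction``
    concentrates stromal immune nuclei near the tumour boundary (0 =
    uniform; larger = tighter).
    """

    width: int = 256
    height: int = 256
    n_tumour_nests: int = 4
    nest_radius_range: tuple[float, float] = (18.0, 42.0)
    tumour_density: float = 4.0
    stroma_density: float = 3.0
    immune_intensity: float = 1.5
    stromal_fraction_of_immune: float = 0.8
    border_attraction: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tumour_density, self.stroma_density, self.immune_intensity) < 0:
            raise ValueError("densities must be >= 0")
        if not (0 < self.nest_radius_range[0] <= self.nest_radius_range[1]):
            raise ValueError("nest radii must be positive and ordered")
        if not 0 <= self.stromal_fraction_of_immune <= 1:
            raise ValueError("stromal_fraction_of_immune must be in [0, 1]")
        if self.border_attraction < 0:
            raise ValueError("border_attraction must be >= 0")


@dataclass(frozen=True)
class CohortSimConfig:
    """Virtual-cohort parameters.

    The shared latent intensity ``lambda_i`` is log-normal
    (``lam_log_mean``, ``lam_log_sd``); sTILs/tTILs are Poisson with means
    ``lambda_i * noise * {stils_scale, ttils_scale}`` where the noise is
    independent log-normal (``noise_log_sd``) per compartment — the shared
    latent sets the between-compartment correlation, the noise bounds it
    away from 1.  ``beta_tils`` is the log hazard ratio per standard
    deviation of log(1 + total TILs); the baseline hazard is exponential
    (per month) with administrative censoring at ``censor_horizon_months``.
    ``covariate_link`` scales how strongly grade/size/LN/Ki67 track the
    latent intensity.
    """

    n_patients: int = 1000
    lam_log_mean: float = math.log(800.0)
    lam_log_sd: float = 0.7
    noise_log_sd: float = 0.4
    stils_scale: float = 1.0
    ttils_scale: float = 0.25
    beta_tils: float = math.log(1.7)
    baseline_hazard: float = 7e-4
    censor_horizon_months: float = 240.0
    covariate_link: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.baseline_hazard <= 0 or self.censor_horizon_months <= 0:
            raise ValueError("rates and horizon must be > 0")


# ---------------------------------------------------------------------------
# Slide generation
# ---------------------------------------------------------------------------

def _sample_region_pixels(rng: np.random.Generator, region: np.ndarray, n: int) -> np.ndarray:
    """n pixel (row, col) draws uniformly (with replacement) from a region."""
    rows, cols = np.nonzero(region)
    idx = rng.integers(0, rows.size, size=n)
    return np.column_stack([rows[idx], cols[idx]])


def generate_slide(
    config: SlideSimConfig, feature_config: FeatureConfig | None = None
) -> tuple[list[NucleusRecord], RegionMaskSet, dict]:
    """Simulate one slide: nuclei, region masks, and planted ground truth.

    Ground truth holds the exact per-region immune counts obtained by
    looking up each planted nucleus in the analysis regions the pipeline
    will compute (same TAS configuration), plus per-type totals.
    Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    tissue = np.ones((h, w), dtype=bool)

    yy, xx = np.mgrid[0:h, 0:w]
    tumour = np.zeros((h, w), dtype=bool)
    for _ in range(config.n_tumour_nests):
        r = rng.uniform(*config.nest_radius_range)
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        tumour |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    stroma = tissue & ~tumour

    masks = RegionMaskSet(
        {
            "tissue": tissue,
            "tumour": tumour,
            "stroma": stroma,
            "dcis": np.zeros((h, w), dtype=bool),
            "excluded": np.zeros((h, w), dtype=bool),
        },
        scale_note="synthetic slide (single shared resolution)",
    )

    fc = feature_config or FeatureConfig()
    clean = apply_exclusions(masks)
    regions = capture_tas(
        clean["tumour"],
        clean["stroma"],
        dilation_radius=fc.tas_dilation_radius,
        fill_radius=fc.tas_fill_radius,
        fill_mode=fc.tas_fill_mode,
        tissue=clean["tissue"],
    )

    nuclei: list[NucleusRecord] = []

    def place(region: np.ndarray, count: int, ntype: NucleusType) -> np.ndarray | None:
        if count == 0 or not region.any():
            return None
        pix = _sample_region_pixels(rng, region, count)
        for r, c in pix:
            nuclei.append(
                NucleusRecord(
                    f"{ntype.value[0]}{len(nuclei)}", float(c), float(r), ntype,
                    area_px=float(rng.integers(18, 40)),
                )
            )
        return pix

    t_area = int(tumour.sum())
    s_area = int(stroma.sum())
    place(tumour, rng.poisson(config.tumour_density * t_area / 1000.0) if t_area else 0,
          NucleusType.TUMOUR)
    place(stroma, rng.poisson(config.stroma_density * s_area / 1000.0) if s_area else 0,
          NucleusType.STROMAL)

    n_immune = rng.poisson(config.immune_intensity * tissue.sum() / 1000.0)
    n_stromal_immune = rng.binomial(n_immune, config.stromal_fraction_of_immune)
    n_tumour_immune = n_immune - n_stromal_immune
    if not tumour.any():
        n_stromal_immune, n_tumour_immune = n_immune, 0
    if not stroma.any():
        n_stromal_immune, n_tumour_immune = 0, n_immune

    place(tumour, n_tumour_immune, NucleusType.IMMUNE)
    if n_stromal_immune and stroma.any():
        if config.border_attraction > 0 and tumour.any():
            dist = ndi.distance_transform_edt(~tumour)
            weights = np.where(stroma, np.exp(-config.border_attraction * dist / 16.0), 0.0)
            flat = weights.ravel()
            probs = flat / flat.sum()
            chosen = rng.choice(flat.size, size=n_stromal_immune, replace=True, p=probs)
            for flat_idx in chosen:
                r, c = divmod(int(flat_idx), w)
                nuclei.append(
                    NucleusRecord(
                        f"i{len(nuclei)}", float(c), float(r), NucleusType.IMMUNE,
                        area_px=float(rng.integers(18, 40)),
                    )
                )
        else:
            place(stroma, n_stromal_immune, NucleusType.IMMUNE)

    # Planted ground truth: per-nucleus region lookup, same convention as
    # the pipeline (rounded centroid pixel).
    gt = {"stils": 0, "ttils": 0, "other_immune": 0, "total_tils": 0,
          "n_tumour_nuclei": 0, "n_stromal_nuclei": 0}
    for rec in nuclei:
        if rec.nucleus_type is NucleusType.TUMOUR:
            gt["n_tumour_nuclei"] += 1
        elif rec.nucleus_type is NucleusType.STROMAL:
            gt["n_stromal_nuclei"] += 1
        elif rec.nucleus_type is NucleusType.IMMUNE:
            r, c = round_half_up(rec.y), round_half_up(rec.x)
            if regions.tumour_eff[r, c]:
                gt["ttils"] += 1
                gt["total_tils"] += 1
            elif regions.tas[r, c]:
                gt["stils"] += 1
                gt["total_tils"] += 1
            elif regions.other[r, c]:
                gt["other_immune"] += 1
                gt["total_tils"] += 1

    # Shuffle so downstream order-invariance is exercised by construction.
    perm = rng.permutation(len(nuclei))
    nuclei = [nuclei[i] for i in perm]
    return nuclei, masks, gt


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate a cohort table with planted TILs features, covariates and
    right-censored breast-cancer-specific survival.  Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    log_lam = rng.normal(config.lam_log_mean, config.lam_log_sd, n)
    lam = np.exp(log_lam)
    z_lam = (log_lam - config.lam_log_mean) / config.lam_log_sd

    noise_s = np.exp(rng.normal(-config.noise_log_sd**2 / 2, config.noise_log_sd, n))
    noise_t = np.exp(rng.normal(-config.noise_log_sd**2 / 2, config.noise_log_sd, n))
    stils = rng.poisson(lam * noise_s * config.stils_scale)
    ttils = rng.poisson(lam * noise_t * config.ttils_scale)
    total = stils + ttils

    # Co-occurrence features scale with the counts (pair counts grow faster
    # than linearly with density; a fixed multiplier suffices here).
    si_cooc = rng.poisson(3.0 * stils)
    ti_cooc = rng.poisson(2.0 * ttils)

    # AI-based sTILs percentage: saturating transform of the stromal burden.
    stroma_capacity = np.exp(rng.normal(math.log(25000.0), 0.3, n))
    stils_pct = np.clip(100.0 * 28.0 * stils / stroma_capacity, 0.0, 100.0)

    # Visual score: the AI percentage plus rater noise.  Noise sd equals the
    # between-subject sd; after clipping to the percentage range this yields
    # a two-way absolute-agreement ICC of ~0.7 (the right-skewed percentage
    # distribution means the clipped noise is effectively milder than its
    # nominal sd).
    sd_between = float(np.std(stils_pct))
    visual = stils_pct + rng.normal(0.0, sd_between, n)
    visual = np.clip(visual, 0.0, 100.0)

    # Survival: exponential PH in standardized log TILs burden.
    log_burden = np.log1p(total)
    z = (log_burden - log_burden.mean()) / log_burden.std()
    hazard = config.baseline_hazard * np.exp(config.beta_tils * z)
    t_event = rng.exponential(1.0 / hazard)
    event = t_event <= config.censor_horizon_months
    time = np.minimum(t_event, config.censor_horizon_months)
    time = np.maximum(time, 1e-3)  # guard against a zero draw

    link = config.covariate_link
    grade_latent = link * z_lam + rng.normal(0, 1, n)
    q30, q70 = np.quantile(grade_latent, [0.3, 0.7])
    grade = np.where(grade_latent < q30, 1, np.where(grade_latent < q70, 2, 3))
    size_cm = np.round(np.exp(rng.normal(math.log(1.8), 0.35, n) + 0.25 * link * z_lam), 1)
    ln_positive = rng.random(n) < _sigmoid(-0.8 + 0.5 * link * z_lam)
    ki67_high = rng.random(n) < _sigmoid(-0.4 + 0.8 * link * z_lam)
    lvi = rng.random(n) < _sigmoid(-1.2 + 0.4 * link * z_lam)
    pr_positive = rng.random(n) < _sigmoid(1.0 - 0.3 * link * z_lam)
    age = np.round(np.clip(rng.normal(61, 11, n) - 3.0 * link * z_lam, 25, 95), 0)

    npi_score = 0.2 * size_cm + grade + np.where(ln_positive, 2, 1)
    npi_group = np.where(npi_score <= 3.4, "good", np.where(npi_score <= 5.4, "moderate", "poor"))

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age_years": age,
            "size_cm": size_cm,
            "grade": grade,
            "ln_positive": ln_positive,
            "lvi": lvi,
            "npi_group": npi_group,
            "pr_positive": pr_positive,
            "ki67_high": ki67_high,
            "time_months": time,
            "event": event,
            "stils_count": stils,
            "ttils_count": ttils,
            "total_tils": total,
            "stils_pct": stils_pct,
            "stroma_immune_cooc": si_cooc,
            "tumour_immune_cooc": ti_cooc,
            "visual_stils_pct": visual,
            "split_label": "unassigned",
        }
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))
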