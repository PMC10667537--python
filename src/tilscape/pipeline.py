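"""End-to-end orchestration of the TILs study protocol.

Stages: per-slide feature extraction (when slide inputs are given) ->
join to cohort -> stratified discovery/test split -> per feature:
outcome-based cut-point on the discovery set only, applied unchanged to the
test set; Kaplan-Meier + log-rank and univariate Cox (high vs low) in both
sets -> multivariate Cox for the intratumoural TILs count adjusted for
grade, lymph-node status, Ki67 and tumour size, with a per-1000-unit hazard
ratio -> rank-based association battery -> correlation panel -> ICC when a
visual score is present.  Everything is written to the output directory
with a machine-readable manifest.

The test set is never touched during cut-point derivation: the cut-point
stage receives only discovery rows, and the manifest records an audit of
the patient ids used.  Reruns with the same config and seed are
byte-identical (the manifest carries no wall-clock state; timings go to the
log stream).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_inference import association_battery, correlation, icc_agreement
from .slide_model import read_cohort, read_masks, read_nuclei, write_cohort, write_features
from .survival_analysis import (
    SurvivalData,
    apply_cutpoint,
    cox_fit,
    hr_per_k_units,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    stratified_split,
)
from .synthetic_cohort import CohortSimConfig, generate_cohort
from .til_features import FeatureConfig, compute_slide_features

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_FEATURES"]

DEFAULT_FEATURES = (
    "stils_count",
    "ttils_count",
    "total_tils",
    "stils_pct",
    "stroma_immune_cooc",
    "tumour_immune_cooc",
)

MULTIVARIATE_ADJUSTERS = ("grade", "ln_positive", "ki67_high", "size_cm")


@dataclass
class RunConfig:
    """One pipeline run: input source, module configs, seed, output dir."""

    out_dir: Path
    seed: int
    cohort_csv: Path | None = None
    synthetic_cohort: dict | None = None
    slides: list[dict] = field(default_factory=list)  # {patient_id, nuclei, masks: {name: path}}
    test_fraction: float = 0.3
    features: tuple[str, ...] = DEFAULT_FEATURES
    cutpoint_grid_policy: str = "percentile"
    min_group_fraction: float = 0.1
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)

    @classmethod
    def from_dict(cls, doc: dict, out_dir: str | Path, seed: int) -> "RunConfig":
        fc = FeatureConfig(**doc.get("feature_config", {}))
        cut = doc.get("cutpoint", {})
        return cls(
            out_dir=Path(out_dir),
            seed=int(seed),
            cohort_csv=Path(doc["cohort_csv"]) if doc.get("cohort_csv") else None,
            synthetic_cohort=doc.get("synthetic_cohort"),
            slides=doc.get("slides", []),
            test_fraction=float(doc.get("test_fraction", 0.3)),
            features=tuple(doc.get("features", DEFAULT_FEATURES)),
            cutpoint_grid_policy=cut.get("grid_policy", "percentile"),
            min_group_fraction=float(cut.get("min_group_fraction", 0.1)),
            feature_config=fc,
        )

    def config_hash(self) -> str:
        doc = asdict(self)
        doc["out_dir"] = None  # the output location is not part of the scientific config
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _extract_slide_features(cfg: RunConfig, features_dir: Path) -> pd.DataFrame:
    rows = []
    for spec in cfg.slides:
        pid = str(spec["patient_id"])
        t0 = _time.perf_counter()
        nuclei = read_nuclei(spec["nuclei"])
        masks = read_masks(spec["masks"])
        feats = compute_slide_features(nuclei, masks, cfg.feature_config)
        write_features(feats, features_dir / f"{pid}.json")
        logger.info(
            "slide %s: %d nuclei, features in %.2fs", pid, len(nuclei), _time.perf_counter() - t0
        )
        rows.append({"patient_id": pid, **feats.to_row()})
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the protocol and return the manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("tilscape").addHandler(collector)
    try:
        return _run(cfg, out, collector)
    finally:
        logging.getLogger("tilscape").removeHandler(collector)


def _run(cfg: RunConfig, out: Path, collector: _WarningCollector) -> dict:
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "tilscape_version": __version__,
        "outputs": [],
        "notes": [
            "p-values are two-sided; no multiple-testing correction (mirrors the study protocol)",
            f"sTILs percentage uses default nucleus area {cfg.feature_config.default_nucleus_area} px when polygons are absent",
            f"co-occurrence radius {cfg.feature_config.cooc_radius_px} px",
        ],
    }

    # --- stage: features -------------------------------------------------
    slide_feats = None
    if cfg.slides:
        features_dir = out / "features"
        features_dir.mkdir(exist_ok=True)
        slide_feats = _extract_slide_features(cfg, features_dir)
        manifest["outputs"].append("features/")

    # --- stage: cohort ----------------------------------------------------
    if cfg.cohort_csv is not None:
        cohort = read_cohort(cfg.cohort_csv)
    elif cfg.synthetic_cohort is not None:
        cohort = generate_cohort(CohortSimConfig(**cfg.synthetic_cohort, seed=cfg.seed))
    else:
        cohort = None

    if cohort is None:
        if slide_feats is None:
            raise ValueError("nothing to do: no cohort table, no synthetic config, no slides")
        manifest["mode"] = "features_only"
        _finish(manifest, out)
        return manifest

    if slide_feats is not None:
        cohort = cohort.merge(slide_feats, on="patient_id", how="left")

    missing = [f for f in cfg.features if f not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing analysis feature columns: {missing}")

    # --- stage: split -----------------------------------------------------
    cohort = stratified_split(cohort, cfg.test_fraction, cfg.seed)
    disc = cohort[cohort.split_label == "discovery"]
    test = cohort[cohort.split_label == "test"]
    manifest["split"] = {
        "discovery_n": int(len(disc)),
        "test_n": int(len(test)),
        "discovery_events": int(disc.event.sum()),
        "test_events": int(test.event.sum()),
    }
    # Audit: the rows the cut-point stage is allowed to see.
    manifest["cutpoint_audit"] = {
        "derived_on": "discovery",
        "patient_ids_hash": hashlib.sha256(
            ",".join(disc.patient_id.astype(str)).encode()
        ).hexdigest(),
        "n_rows": int(len(disc)),
    }
    write_cohort(cohort, out / "cohort_with_features.csv")
    manifest["outputs"].append("cohort_with_features.csv")

    n_events = int(cohort.event.sum())
    cut_rows, surv_rows = [], []
    km_dir = out / "km_curves"
    km_dir.mkdir(exist_ok=True)

    if n_events == 0:
        logger.warning("no events in cohort: survival stages skipped")
        for feat in cfg.features:
            surv_rows.append(
                {"feature": feat, "set": "all", "model": "none", "covariate": feat,
                 "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                 "n": len(cohort), "events": 0, "note": "no events"}
            )
    else:
        for feat in cfg.features:
            _analyze_feature(cfg, feat, disc, test, cut_rows, surv_rows, km_dir)
        _multivariate(cfg, disc, test, surv_rows)

    _write_csv(pd.DataFrame(cut_rows), out / "cutpoints.csv")
    _write_csv(pd.DataFrame(surv_rows), out / "survival_results.csv")
    manifest["outputs"] += ["cutpoints.csv", "survival_results.csv", "km_curves/"]

    # --- stage: associations ---------------------------------------------
    assoc_frames = []
    for name, subset in (("discovery", disc), ("test", test)):
        frame = association_battery(subset, [f for f in cfg.features if subset[f].notna().any()])
        frame.insert(0, "set", name)
        assoc_frames.append(frame)
    _write_csv(pd.concat(assoc_frames, ignore_index=True), out / "associations.csv")
    manifest["outputs"].append("associations.csv")

    # --- stage: correlation panel ----------------------------------------
    corr_rows = []
    panel = [("stils_count", "ttils_count"), ("stils_count", "stils_pct")]
    for name, subset in (("discovery", disc), ("test", test)):
        for xcol, ycol in panel:
            if xcol not in subset.columns or ycol not in subset.columns:
                continue
            ok = subset[xcol].notna() & subset[ycol].notna()
            if ok.sum() < 3:
                continue
            for method in ("pearson", "spearman"):
                r, p = correlation(subset.loc[ok, xcol], subset.loc[ok, ycol], method=method)
                corr_rows.append(
                    {"set": name, "x": xcol, "y": ycol, "method": method,
                     "r": r, "p_value": p, "n": int(ok.sum())}
                )
    _write_csv(pd.DataFrame(corr_rows), out / "correlations.csv")
    manifest["outputs"].append("correlations.csv")

    # --- stage: visual-vs-AI agreement ------------------------------------
    if "visual_stils_pct" in cohort.columns and cohort["visual_stils_pct"].notna().sum() >= 3:
        ok = cohort["visual_stils_pct"].notna() & cohort["stils_pct"].notna()
        res = icc_agreement(cohort.loc[ok, "visual_stils_pct"], cohort.loc[ok, "stils_pct"])
        _write_csv(
            pd.DataFrame(
                [{"icc": res.icc, "model": res.model,
                  "n_subjects": res.n_subjects, "n_raters": res.n_raters}]
            ),
            out / "agreement.csv",
        )
        manifest["outputs"].append("agreement.csv")

    manifest["warnings"] = collector.messages
    _finish(manifest, out)
    return manifest


def _surv(subset: pd.DataFrame) -> SurvivalData:
    return SurvivalData(subset.time_months.to_numpy(), subset.event.to_numpy())


def _analyze_feature(cfg, feat, disc, test, cut_rows, surv_rows, km_dir) -> None:
    d_ok = disc[disc[feat].notna()]
    if d_ok[feat].nunique() < 2 or not d_ok.event.any():
        logger.warning("feature %s: not analyzable on discovery set", feat)
        return
    cut = optimal_cutpoint(
        d_ok[feat].to_numpy(),
        _surv(d_ok),
        feature_name=feat,
        grid_policy=cfg.cutpoint_grid_policy,
        min_group_fraction=cfg.min_group_fraction,
    )
    cut_rows.append(
        {"feature": feat, "cutoff": cut.cutoff, "chi_square": cut.chi_square_at_cutoff,
         "p_uncorrected": cut.p_uncorrected, "n_low": cut.n_low, "n_high": cut.n_high,
         "grid_policy": cut.grid_policy, "derived_on": cut.derived_on, "caveat": cut.caveat}
    )
    for name, subset in (("discovery", disc), ("test", test)):
        ok = subset[subset[feat].notna()]
        if len(ok) == 0:
            continue
        high = apply_cutpoint(ok[feat].to_numpy(), cut.cutoff)
        surv = _surv(ok)
        for grp, label in ((~high, "low"), (high, "high")):
            if grp.any():
                km = km_estimate(SurvivalData(surv.time[grp], surv.event[grp]))
                km.to_csv(km_dir / f"{feat}__{name}__{label}.csv", index=False)
        if high.any() and (~high).any() and ok.event.any():
            chi2, p = logrank_test(surv, high)
            surv_rows.append(
                {"feature": feat, "set": name, "model": "univariate_km_logrank",
                 "covariate": f"{feat}>cutoff", "hr": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "p_value": p, "n": len(ok),
                 "events": int(ok.event.sum()), "note": f"chi_square={chi2:.6g}"}
            )
            try:
                res = cox_fit(high.astype(float)[:, None], surv)[0]
                surv_rows.append(
                    {"feature": feat, "set": name, "model": "cox_uni",
                     "covariate": f"{feat}_high", "hr": res.hr, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "p_value": res.p_value, "n": len(ok),
                     "events": res.n_events, "note": ""}
                )
            except (RuntimeError, ValueError) as exc:
                logger.warning("univariate Cox failed for %s on %s: %s", feat, name, exc)


def _multivariate(cfg, disc, test, surv_rows) -> None:
    cols = ["ttils_count", *MULTIVARIATE_ADJUSTERS]
    for name, subset in (("discovery", disc), ("test", test)):
        if not all(c in subset.columns for c in cols):
            return
        ok = subset.dropna(subset=cols)
        if not ok.event.any():
            continue
        X = ok[list(cols)].astype(float)
        try:
            results = cox_fit(X, _surv(ok))
        except (RuntimeError, ValueError) as exc:
            logger.warning("multivariate Cox failed on %s: %s", name, exc)
            continue
        for res in results:
            surv_rows.append(
                {"feature": "ttils_count_adjusted", "set": name, "model": "cox_multi",
                 "covariate": res.covariate, "hr": res.hr, "ci_low": res.ci_low,
                 "ci_high": res.ci_high, "p_value": res.p_value, "n": len(ok),
                 "events": res.n_events, "note": ""}
            )
        tt = next(r for r in results if r.covariate == "ttils_count")
        hr_k, lo_k, hi_k = hr_per_k_units(tt.beta, k=1000.0, se=tt.se)
        surv_rows.append(
            {"feature": "ttils_count_adjusted", "set": name, "model": "cox_multi",
             "covariate": "ttils_count_per_1000", "hr": hr_k, "ci_low": lo_k,
             "ci_high": hi_k, "p_value": tt.p_value, "n": len(ok),
             "events": tt.n_events, "note": "per-1000-unit rescaling of ttils_count"}
        )


def _finish(manifest: dict, out: Path) -> None:
    manifest["outputs"] = sorted(set(manifest["outputs"]))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
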