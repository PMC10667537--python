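# tilscape

Quantification of tumour-infiltrating lymphocytes (TILs) and their
prognostic analysis in early-stage luminal (ER+/HER2−) breast cancer, built
as a reusable, tested pipeline.  `tilscape` starts where the deep-learning
models of a digital-pathology workflow stop: its inputs are per-slide
**nuclei maps** (centroid x/y and nucleus class: tumour / stromal / immune /
normal epithelial / other) and co-registered **region masks** (tissue,
tumour, stroma, DCIS, excluded artefacts), plus a **cohort table** with
clinicopathological covariates and right-censored breast-cancer-specific
survival (BCSS).

It is written for computational-pathology and biostatistics researchers who
have nucleus/region segmentations (from any model) and want reproducible
TILs features and a complete outcome analysis.

## What it computes

**Per slide** (module `til_features`, geometry in `region_ops`):

- Tumour-associated stroma (TAS): the tumour mask is dilated with a disc of
  radius 8 px, holes are filled with a disc of radius 32 px (morphological
  closing followed by hole filling), and any stroma captured inside the
  resulting envelope is TAS.
- `sTILs count` — immune nuclei in TAS; `tTILs count` — immune nuclei in
  the tumour region; `total TILs` — all non-excluded immune nuclei.  DCIS
  and artefact regions are excluded before anything is counted.
- `AI-based sTILs %` — the fraction of TAS area occupied by immune nuclei
  (the automated analogue of the pathologist's visual stromal-TILs score).
- A cell-type **co-occurrence matrix** CM over (tumour, stromal, immune)
  nuclei: CM[a,b] counts unordered pairs of types (a,b) whose centroids lie
  within a radius (default 32 px); derived scalars are the stroma–immune
  and tumour–immune co-occurrence counts, an immune *heterogeneity*
  (Shannon entropy, in bits, of the normalized CM) and an immune *contrast*
  (immune-involving off-diagonal mass fraction).

**Per cohort** (modules `cohort_inference`, `survival_analysis`):

- Mann–Whitney / Kruskal–Wallis associations with per-group mean ranks;
  Pearson/Spearman correlation; ICC(2,1) agreement between visual and
  automated sTILs percentages.
- Stratified discovery/test splitting; outcome-based dichotomization (the
  maximally selected log-rank statistic over a percentile grid — an
  emulation of X-tile-style cut-point software) derived **only** on the
  discovery set and applied unchanged to the test set; Kaplan–Meier
  curves, log-rank tests, and Cox proportional-hazards models
  (univariate and multivariate, Efron or Breslow ties) with hazard ratios
  reported per unit and per 1000 units: HR_1000 = exp(1000·β).

**Synthetic data** (module `synthetic_cohort`) generates virtual slides
(tumour-nest point patterns with planted per-region immune counts) and
virtual cohorts (a shared log-normal latent immune intensity inducing the
sTILs–tTILs correlation, exponential proportional-hazards survival, and
covariates linked to the latent) so every stage is testable end to end
without any proprietary data.

## Worked example

```bash
tilscape simulate --seed 3 --out sim/ --n-slides 1
tilscape features --nuclei sim/slide_000/nuclei.csv \
    --masks sim/slide_000/masks --out features.json
tilscape analyze --cohort sim/cohort.csv --seed 3 --out results/
```

`features.json` for that slide contains (among the other fields):

```json
{
  "stils_count": 64,
  "ttils_count": 26,
  "total_tils": 115,
  "stils_pct": 19.810795770728994,
  "stroma_immune_cooc": 512,
  "tumour_immune_cooc": 527
}
```

i.e. 64 stromal TILs in the tumour-associated stroma, 26 intratumoural
TILs, 115 immune nuclei in total on the analysable tissue (the remaining
25 sit in stroma outside the TAS envelope), immune nuclei occupying ~20%
of the TAS area, and 512 stromal-cell–immune-cell centroid pairs within
the 32-px co-occurrence radius.  These counts equal the generator's
planted ground truth (`sim/slide_000/ground_truth.json`) exactly.

`results/` then holds `cohort_with_features.csv`, `cutpoints.csv` (each
cut-off with its discovery-set chi-square and an explicit
uncorrected-maximum caveat), `survival_results.csv` (log-rank p-values,
univariate high-vs-low hazard ratios, the adjusted multivariate model for
the tTILs count and its per-1000-unit HR), `associations.csv` (mean-rank
tables), `correlations.csv`, `agreement.csv` (ICC), Kaplan–Meier step
tables under `km_curves/`, and a `manifest.json` recording the config hash,
seed and the discovery-set audit.  Reruns with the same config and seed are
byte-identical.

As a library:

```python
from tilscape import read_nuclei, read_masks, compute_slide_features
feats = compute_slide_features(read_nuclei("nuclei.csv"),
                               read_masks({"tumour": "tumour.png",
                                           "stroma": "stroma.png",
                                           "tissue": "tissue.png"}))
print(feats.stils_count, feats.stils_pct)
```

## Documentation

`docs/methods.md` describes the model, the interpretive choices behind the
feature definitions, the synthetic generator's assumptions, and known
limitations.
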