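# Methods

This note documents the models and procedures `tilscape` implements, the
interpretive choices behind them, what the synthetic generators do and do
not emulate, and the numerical conventions that tests pin down.

## Coordinate and membership conventions

All spatial computation happens on a single shared pixel grid — typically
the downsampled grid on which nucleus centroids were mapped by an upstream
segmentation model.  Coordinates are 0-based with x = column and y = row
(y downward).  A nucleus belongs to a region iff the mask is set at its
rounded centroid pixel, with half-up rounding (`round_half_up(2.5) == 3`)
as a deterministic boundary tie-break.  No micron conversion is attempted;
`RegionMaskSet.scale_note` carries resolution provenance as free text.

On load, masks are repaired to satisfy the region algebra: tissue is grown
to cover annotated tumour and stroma (annotations are authoritative over a
thresholded tissue mask), and tumour∩stroma overlap is removed from stroma.
Both repairs are logged with pixel counts and are idempotent.

## Tumour-associated stroma (TAS)

The TAS capture recipe is: dilate the tumour mask with a disc of radius 8
px, fill holes with a disc of radius 32 px, and take any stroma inside the
resulting envelope as TAS.  "Filling holes with a disc of radius r" is
interpreted as morphological **closing** with a disc of radius r followed
by binary hole filling (`fill_mode="close_then_fill"`): closing bridges
stromal channels narrower than ~2r and hole filling captures fully
enclosed stroma, which together realize the intent of capturing the stroma
a tumour surrounds.  The alternative reading — fill only cavities that
admit no disc larger than radius r — is selectable as
`fill_mode="fill_only"`.

Numerical conventions, pinned by an independent oracle (per-pixel Euclidean
distance transforms plus connected-component flood fill):

- Discs are closed Euclidean balls: a pixel belongs to `disc(r)` iff its
  centre is within distance r of the origin.
- Masks are padded with background by the total structuring radius before
  morphology and cropped afterwards, so the image edge never creates
  artificial TAS and results are translation invariant.
- With both radii zero, TAS reduces to stroma enclosed in holes of the raw
  tumour mask; TAS is monotone in the dilation radius.

Whether the published radii (8, 32) refer to the downsampled or the full
resolution grid is not derivable from their source; defaults assume the
grid on which centroids live, and both are configurable
(`tas.dilation_radius`, `tas.fill_radius`).

## TILs features

- **sTILs count**: immune nuclei whose centroid lies in TAS.
- **tTILs count**: immune nuclei in the effective tumour region (tumour
  minus DCIS minus artefacts).  "In direct contact with tumour cells" is
  not computable from centroids alone, so intratumoural status is
  operationalized as region membership.
- **total TILs**: all non-excluded immune nuclei (sTILs + tTILs + immune
  nuclei in other tissue); conservation is tested.
- **AI-based sTILs %**: 100 × (summed immune nucleus area in TAS) / (TAS
  pixel area), clamped to [0, 100].  Nuclei without polygons contribute a
  configurable default area (28 px; an average-lymphocyte-scale constant
  on the analysis grid, logged in every report since percentage-based
  conclusions must not silently depend on it).  An empty TAS yields an
  *undefined* percentage (`None`), distinct from 0%.
- **Co-occurrence matrix**: symmetric counts of unordered nucleus pairs
  within 32 px (configurable) over (tumour, stromal, immune).  Cross-type
  pairs increment both symmetric cells; same-type pairs increment the
  diagonal once.  The implementation uses a k-d tree and is contractually
  identical to the O(n²) all-pairs count; pair counting is monotone in the
  radius.
- **Heterogeneity** is the Shannon entropy (bits) of the CM normalized
  over its upper triangle including the diagonal; **contrast** is the
  immune-involving off-diagonal mass fraction of the same normalization.
  These two feature names circulate in the literature without published
  formulas; the definitions here are declared substitutes — simple,
  dimensionless, testable — not reconstructions.  Likewise the
  co-occurrence radius is a package default, exposed prominently, because
  only "within a certain distance" is public.

## Statistical procedures

**Rank tests.**  Mann–Whitney uses mid-ranks, the tie-corrected variance,
and a two-sided normal approximation with continuity correction; for
pooled N ≤ 10 an exact enumeration over rank assignments is auto-selected
(the normal approximation's ≤0.05 accuracy claim holds tie-free at these
sizes but not under heavy ties, which is why the exact path exists).
Mean ranks per group are always reported and satisfy rank-sum
conservation Σ n·r̄ = N(N+1)/2.  Kruskal–Wallis uses the tie-corrected H
against chi-square with k−1 df; two groups delegate to Mann–Whitney.
P-values are two-sided throughout and deliberately uncorrected for
multiple testing, mirroring the study protocol this package reproduces;
reports say so.

**Agreement.**  ICC(2,1) — two-way random effects, absolute agreement,
single measures — computed from the mean-squares decomposition.  This is
the standard model for method comparison between two fixed raters (here:
pathologist's visual score vs the automated percentage); the model tag is
always recorded.

**Survival.**  The Kaplan–Meier estimator (product-limit; subjects
censored at an event time remain at risk at that time) is exposed as a
step-function table.  The log-rank test uses the observed-minus-expected
statistic with hypergeometric variance summed over distinct event times.
The Cox model maximizes the partial likelihood by Newton iteration
(convergence |Δ log-lik| < 1e-9, ≤ 100 iterations, step halving), with
Efron tie handling by default and Breslow available; Wald CIs come from
the observed information.  A scale-aware divergence guard and a
degenerate-information check raise diagnostic errors under monotone
likelihood / perfect separation.  For tie-free data the Breslow score
test at β = 0 equals the log-rank chi-square — a theorem used as a
cross-module consistency check (with d > 1 ties the hypergeometric
variance carries an (n−d)/(n−1) factor the information lacks, so the
identity is checked on continuous times).  Per-1000-unit hazard ratios
are exp(1000·β) with CI endpoints transformed identically.

**Cut-point selection** emulates outcome-based dichotomization software as
a maximally selected log-rank statistic: candidates are the 5th–95th
percentiles (step 1) or all unique values, both sides must hold at least a
fraction (default 0.1) of subjects, the maximizing cut wins, and exact
ties break toward the cut nearest the median.  The selected cut's p-value
is an uncorrected maximum; instead of a Miller–Siegmund-type correction,
the protocol's guard is validation on held-out data: cut-points are
derived on the discovery set only (the pipeline passes only discovery rows
to this stage and records an audit of the patient ids used) and applied
unchanged to the test set.  High means strictly greater than the cut-off.

**Splitting** is stratified on the event indicator with per-stratum
proportional allocation (rounded), deterministic per seed, so event
proportions in the two sets agree to within one subject.

## Synthetic generators

The slide generator produces tumour nests as unioned random discs on a
256×256 grid (configurable), stroma as the remaining tissue, homogeneous
Poisson tumour/stromal nuclei within their regions (defaults 4 and 3
nuclei per 1000 px²), and immune nuclei split 80/20 between stroma and
tumour, with stromal immune density decaying exponentially with distance
to the tumour boundary (`border_attraction`, default 2, length scale 16
px) — reflecting that stromal TILs dominate intratumoural TILs and
concentrate near tumour borders.  Ground truth records each planted
nucleus's analysis region, so pipeline counts can be checked for exact
equality.

The cohort generator uses a shared per-patient log-normal latent immune
intensity (median 800, log-sd 0.7) with independent log-normal
multiplicative noise (log-sd 0.4) per compartment; sTILs and tTILs are
conditionally Poisson with rate multipliers 1.0 and 0.25.  The shared
latent — not spatial interaction — is the mechanism for the sTILs–tTILs
correlation; the chosen dispersions put the raw-count Pearson r near
0.65–0.70, inside the 0.6–0.8 band reported for real cohorts, and the
correlation rises monotonically with latent dispersion.  Survival is
exponential (constant baseline hazard 7e-4/month) with log hazard ratio
ln(1.7) per standard deviation of log(1 + total TILs) and administrative
censoring at 240 months, giving ~15% events — proportional hazards holds
by construction, making Cox recovery a clean calibration check.  Note the
per-SD continuous effect of 1.7 implies somewhat larger *high-vs-low*
hazard ratios (≈2–3) after outcome-optimized dichotomization, since a
median-type split separates groups by ≈1.6 SD.  Ordinal covariates
(grade, size, nodal status, Ki67, age, LVI, PR) are thresholded or
logistic draws from the same latent, so association *directions* match
clinical expectation; their magnitudes are not calibrated to any specific
cohort.  The visual sTILs score adds rater noise with sd equal to the
between-subject sd; after clipping to [0, 100] this yields a two-way
absolute-agreement ICC of ~0.7.

What the generators do **not** emulate: H&E texture (no images are
rendered), nucleus shape/size biology (areas are uniform draws),
segmentation errors of upstream models, informative censoring, competing
risks, and cohort-specific covariate distributions.  Passing tests
therefore demonstrate correctness of the measurement and inference
machinery under known ground truth, not clinical validity on real slides.

## Problem sizes and defaults used in checks

The acceptance checks run 100 random slides (192² px) for planted-count
recovery, 100 random point sets up to 2000 nuclei for co-occurrence, 50
random 128² masks for TAS, 1000 null replicates (n = 50/50) for test
calibration, 200 replicates of n = 1000 for Cox coverage, 100 seeds of
n = 1000 for cut-point recovery, and one 2231-patient virtual cohort
(discovery/test ≈ 1572/659) for the end-to-end protocol — sizes chosen to
exercise each property convincingly on a single CPU.

## Known limitations

- Intratumoural status is centroid-in-region, not cell-contact.
- Heterogeneity/contrast/co-occurrence-radius definitions are this
  package's substitutes for undocumented feature definitions (above).
- No immune subtyping (CD8/CD4/FOXP3…): inputs are H&E-derived classes.
- No competing-risks model for non-breast-cancer death; no correction of
  discovery-set maximally-selected p-values beyond the held-out protocol.
- Proprietary WSI formats and pyramid/tile handling are out of scope;
  masks and nuclei tables must already live on one shared grid.
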