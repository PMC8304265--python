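# Methods note

## Model and procedure

### Quantification scale

qPCR reports a quantification cycle Cq per (assay, sample); template
abundance is proportional to E^(−Cq) with amplification efficiency E
(default 2.0, perfect doubling). Cq > 35 is treated as undetected
(`NaN`); 35.0 itself counts as detected. The instrument ceiling is 40
cycles. All internal arithmetic is done on log scales (log2 for
cycle-domain quantities, log10 for expression ratios) and exponentiated
once at the end, which avoids overflow for large fold changes and keeps
geometric means exact.

### Global-mean normalization

For assay *i* with detected reference mean Cq̄ᵢ, the relative quantity in
sample *j* is RQᵢⱼ = E^(Cq̄ᵢ − Cqᵢⱼ). The per-sample normalization factor
NFⱼ is the geometric mean of RQᵢⱼ over the assays detected in *j*
(default policy), and NRQᵢⱼ = RQᵢⱼ / NFⱼ. Consequences, enforced by
tests:

* the geometric mean of NRQ within each sample is exactly 1;
* a constant per-sample Cq shift (pipetting/extraction/input amount)
  cancels exactly;
* the per-assay anchor (mean vs minimum Cq) is arbitrary — it rescales an
  assay's NRQs by a constant. Between-sample ratios within an assay are
  anchor-invariant; the NRQ values themselves are not. With missing data
  this invariance is exact only under the `complete_cases` NF policy
  (NF computed on assays detected in every sample); the default
  per-sample-detected policy follows the field convention instead.

An assay is dropped when undetected in ≥ ceil(0.5 × group size) samples of
either the pre- or post-transplant group (4 of 8 at the study size). For
spiking series, at most one missing level is allowed. Remaining missing
NRQs may be imputed at the assay's minimum log10(NRQ) − 1 (one decade
below the lowest observed value), flagged in a boolean mask, and used only
for group-fold computation.

### Differential stage

Paired two-tailed Student t-tests on log10(NRQ) per assay; no multiplicity
correction, by design — the original workflow controls false discovery
through orthogonal evidence (anchors, spike-in recovery) rather than
p-value adjustment. Fold change policies: `ratio_of_means` (default;
mean(post)/mean(pre)) and `mean_of_ratios`. Up set: fold ≥ 4 and
p < 0.05; down set: fold < 1 and p < 0.05. Zero-variance differences
report t = 0, p = 1, flagged.

### Spike-in recovery

Per assay over levels 0/5/50/250 K cells/mL: least-squares slope and R² of
Cq on log10(level) over the *positive, observed* levels only (level 0
carries no template and enters the criteria, not the regression). Pass
requires slope < −1.5, R² > 0.9, ≥ 4 of 6 monotonicity criteria (three
decreasing-Cq and three increasing-NRQ steps across the four levels, an
undetected level 0 counting in favour), every spiked-step ΔCq ≥ 1 and
progressively declining Cq. More than one missing level is "insufficient
data". The 4-of-6 convention allows an assay with saturating NRQ response
to pass on its Cq behavior alone, but never the reverse.

### geNorm

M value of gene *j*: mean over other candidates *k* of the SD across
samples of log2(aⱼ/aₖ), computed on complete cases. Iterative ranking
removes the worst gene (ties broken by id) until two remain. Pairwise
variation V(n, n+1) is the SD across samples of the difference between
log-scale normalization factors from the n and n+1 best genes; the
selected set is the smallest n with V < 0.15, with a `no_stable_set` flag
when the cutoff is never met. A prefilter keeps the 15 lowest-SD assays
among those detected in ≥ 15 of 16 samples.

### Panel selection

An assay is included when it is in the up set, shows a significant
(p < 0.05) *positive* Spearman correlation with an anchor of beta-cell
lysis (plasma GAD65 or calibrated molar miR-375) or passes recovery, and
is not significantly correlated with a duct-cell exclusion marker. The
sign requirement matters: the anchors rise with lysis, so a negative
correlation is chance, not provenance — without it, planted duct
confounders slipped into the panel through spurious negative correlations
in ~14% of synthetic seeds at n = 8. Ranking: recovery passers first, then
best anchor correlation, then fold. Manual overrides (the codified expert
judgment) require an explicit reason; an include-override still requires
up-set membership and no exclusion flag.

### Validation RQ

Without stable reference genes, validation cohorts use reference-free
relative quantities: paired RQ = 2^(Ct_pre − Ct_post) per transplant, and
cross-sample RQ = 2^(mean Ct − Ct) for the clinical cohort (geometric mean
1 by construction). Half-detected pairs impute the missing side at the
detection threshold (35), giving a conservative lower-bound RQ flagged as
censored; fully undetected pairs are excluded. Group significance: paired
t-test of ΔCt against zero; the group RQ is the arithmetic mean of
per-pair RQs by default (surge distributions are heavy-tailed and the
arithmetic mean preserves them; geometric available).

### Clinical stage

* Spearman correlations (average ranks; exact permutation option for
  n ≤ 9) of post-transplant marker levels against graft composition, with
  univariable OLS p-values for the designated regressors.
* Outliers: one-sided upper Tukey fence Q3 + 1.5·IQR (only surges signal
  excessive destruction), or externally studentized residuals > 2 from
  the marker-vs-graft regression.
* ROC: AUC as the tie-corrected Mann–Whitney probability; variance by
  DeLong structural components (midranks), CI = AUC ± 1.96·SE truncated
  to [0, 1]. DeLong was chosen over bootstrap for determinism and speed;
  the test suite cross-checks the SE against a bootstrap within 15%.
* Backward stepwise OLS: start from all predictors, repeatedly drop the
  largest p > 0.05, after removing perfectly collinear columns by a
  greedy rank check (later columns dropped first). Note the null
  behavior: each noise predictor survives with probability ≈ α, so with
  k noise predictors the chance that *none* survives is ≈ 0.95^k — the
  procedure reliably retains a true predictor but does not guarantee a
  clean model.

## Parameter defaults

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| detection threshold | 35 | Cq | field convention for reliable quantification |
| instrument ceiling | 40 | Cq | cycler run length |
| PCR efficiency E | 2.0 | — | perfect doubling; configurable in (1, 2] |
| group missingness | ceil(0.5·group) | samples | 4-of-8 at the study size |
| imputation offset | −1 | log10(NRQ) | one decade below assay minimum |
| fold threshold (up set) | 4 | fold | selection threshold for surges |
| alpha | 0.05 | — | all significance screens |
| recovery slope / R² | −1.5 / 0.9 | Cq per decade | linear-response requirements |
| recovery ΔCq | ≥ 1 | cycles | per spiked step |
| geNorm V cutoff | 0.15 | — | standard geNorm recommendation |
| outcome threshold | 0.5 | ng/mL C-peptide | poor graft function at 2 months |
| GAD65 LoD/LoQ | 0.121 / 0.288 | pmol/L | assay characterization |
| miR-375 LoD/LoQ | 0.049 / 0.102 | pmol/L | assay characterization |

Synthetic generator (study conditions, `SimConfig`): 8 transplant pairs,
733 assays of which 220 detectable, 20 planted markers with abundance
weights log-uniform in (32, 2048) — realized surges span ~10–6000-fold —
technical Cq noise 0.25, per-assay biological variability 1.0,
per-sample intercept 0.5 (all cycles, Gaussian), latent destruction
signal lognormal with log10-SD 0.35. Clinical cohort: n = 46, 2-month
C-peptide increment = 0.9 + 0.25·(mass − 2.9) − 0.62·log10(destruction)
+ N(0, 0.35) ng/mL, 15% excessive-destruction outliers boosted by 0.8
decades. The destruction coefficient 0.62 was calibrated by a sweep to
put the single-marker AUC near 0.78 and frozen before any acceptance
assertion was written. All randomness flows through one
`numpy.random.default_rng(seed)` (PCG64); identical config + seed give
identical cohorts across platforms.

## What the generator captures — and what it does not

Captured: paired design with per-sample nuisance shifts that normalization
must remove; detection censoring at 35 cycles; heavy-tailed surge spectrum;
anchor measurements tracking the same latent signal; a duct-cell confounder
pathway for the exclusion rule; dose-dependent spiking response with flat
background; an outcome model where destruction hurts and implanted mass
helps.

Known limits:

* **Compositional bias.** Global-mean normalization makes expression
  relative to the sample average; 20 strongly surging markers shift the
  post-transplant normalization factor, so background assays drift
  slightly "down". With only technical noise this made nearly every
  background assay significantly down; per-assay biological variability
  (1.0 cycles between draws) was added as the realistic counterweight —
  plasma microRNA levels fluctuate between blood draws far more than
  replicate wells do. A residual excess of modest "down" calls remains
  (~55–60 of ~227 at the defaults); it is a property of the normalization
  scheme, not a bug, and is why the down set carries no fold threshold.
  The type-I error of the t-test itself is calibrated (≈ 0.05) on null
  cohorts with no planted markers.
* Gaussian Cq noise with level-independent variance; real qPCR noise grows
  near the detection limit.
* No hemolysis, sample-quality or batch covariates; no inter-assay
  efficiency differences (E is global).
* Anchor noise is lognormal and independent across anchors; real GAD65 and
  miR-375 share pre-analytic error.
* The clinical outcome model is a single linear latent-variable model;
  real outcomes have more structure (immunosuppression, second infusions).

## Numerical choices

* log-domain arithmetic throughout normalization and RQ computation; the
  only exponentiations are at output boundaries.
* `numpy.polyfit` degree-1 for recovery regression (3 points; no weighting).
* scipy `ttest_rel` with `nan_policy="omit"`; zero-variance short-circuited
  to p = 1 before calling scipy.
* scipy `linkage`/`pdist` (Manhattan, complete linkage by default) for
  heatmap ordering; ward optional.
* statsmodels OLS and `OLSInfluence` for regression p-values and
  externally studentized residuals.
* TSV output uses `repr`-level float formatting so write→read round-trips
  are byte-stable.

## Problem sizes

Defaults mirror the study design (8 pairs, 733 assays, 4 spiking levels,
46 clinical patients) and are this package's own choice of operating
point; every stage works at other sizes, with hard minimums enforced where
a statistic is undefined (≥ 2 pairs for a t-test, ≥ 3 geNorm candidates,
≥ 4 Spearman observations, ≥ 5 transplants for clinical correlations,
≥ 10 observations and ≥ 2 predictors for stepwise regression).

## Limitations

The pipeline encodes the field's established analysis logic, including
choices one might revisit today: no multiple-testing correction in the differential
screen, selection partly resting on n = 8 Spearman correlations (power is
low and chance correlations at that n are why the positive-sign rule and
the recovery criterion carry most of the selection weight), and stepwise
regression as the multivariable selector. The defaults encode that logic
faithfully rather than improving on it; alternatives (FDR control,
penalized regression) are deliberately out of scope.
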