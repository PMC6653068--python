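# Methods

This document records the statistical methods, the generator that stands in
for non-public registry data, parameter defaults with their rationale, and
the numerical and design decisions a reader would otherwise have to reverse
engineer from the code.

## Data model and formats

A cohort is a list of patients; each patient has strictly increasing visit
days, a per-visit SLEDAI-2k score, and a 17-column matrix of panel values in
the fixed order `CRP, C3, C4, Hb, WCC, platelets, neutrophils, lymphocytes,
ESR, dsDNA_fold_ULN, UPCR, urine_WCC, urine_RBC, MIF, CCL2, CCL19, CXCL10`.
Binary patient characteristics live in a separate table. Patients with fewer
than 3 visits are excluded before analysis.

Interchange is CSV (`patient_id,day,sledai,<17 columns>`); a JSON sidecar
records whether values are pooled z-scores. Floats are written with 17
significant digits and parsed with round-trip float precision, so a
write/read cycle is bit-exact. Missing cells are rejected by default
(incomplete records are excluded from the design) or, on request, drop the
whole patient.

## Preprocessing

Each of the 17 parameters is z-normalized against the pooled mean and
standard deviation over *all visits of all patients* (ddof = 1). Pooling is
deliberate: per-patient normalization would erase exactly the magnitude
differences the first clustering step is meant to find. A constant parameter
normalizes to zeros with a warning. SLEDAI-2k is never transformed.
Per-patient summary vectors (mean by default, median optionally) feed the
magnitude analysis. Anti-dsDNA is expressed as fold-change over the assay's
upper limit of normal before pooling, so different assays are comparable.

## Distances

**Magnitude:** Euclidean distance between per-patient summary vectors.

**Trajectory shape:** multivariate DTW with squared-Euclidean local cost and
steps (1,0), (0,1), (1,1); the reported distance is the raw cumulative sum
(no path-length normalization). With the open end (the default), the
minimum is taken over the last row and column of the cumulative-cost grid,
so series of different lengths compare by aligning the shorter one with a
prefix of the longer. Open-end DTW is symmetric under exchanging the
arguments (the grid transposes), so the distance matrix is well defined.
Ties in the backtracking prefer diagonal, then (1,0), then (0,1); ties
affect only the reported alignment path, never the cost. The implementation
is validated against exhaustive path enumeration in the tests.

## Clustering and validity

Agglomerative clustering (complete linkage by default; single and average
available) on a precomputed distance matrix, via SciPy's linkage. The flat
partition keeps every merge at or below `fraction × max merge height`
(default fraction 0.9). The "at or below" convention means `fraction = 1.0`
yields a single cluster; for continuous-height dendrograms any strictly
interior cut is unaffected by the equality convention.

Validity indices:

- **Connectivity** with `L` neighbors (default 10): for each patient, the
  `j`-th nearest neighbor (j = 1..L) in a *different* cluster contributes
  `1/j`; lower is better. Neighbor ranking ties are broken by patient order
  (stable sort). Note: a popular worked example for 4 collinear points
  (0, 1, 2, 3 split down the middle, 2 neighbors) is sometimes quoted as
  1.0, but the definition above gives 2.5 — the two inner points each
  contribute 1 or 1/2 for their out-of-cluster first/second neighbor and
  the two outer points contribute 1/2 each; the implementation follows the
  definition.
- **Dunn index**: minimum between-cluster point distance divided by the
  maximum within-cluster diameter; undefined when all clusters are
  singletons.
- **Embeddings**: classical MDS (double-centered eigendecomposition; the
  residual is the discarded eigenvalue mass) and isotonic MDS (SMACOF with
  isotonic regression on the disparities, Kruskal stress-1, best of several
  seeded restarts, monotonically non-increasing stress trace).
- A silhouette-based `suggest_k` is available for exploratory use.

## Regression

Designs stack one row per eligible visit:

- *time-agnostic*: 17 current-visit predictors + intercept = 18 free
  parameters;
- *time-dependent*: 17 current + 17 previous-visit predictors + intercept =
  35 free parameters. A patient's first visit contributes no row; lags are
  never imputed and never cross patients.

Fitting is ordinary least squares (`numpy.linalg.lstsq`); rank-deficient
designs are rejected with the offending column named via the QR diagonal.

Validation never mixes a patient's visits across the train/test boundary:

- **LOPO CV**: each patient's full visit set is a held-out fold; folds whose
  training fit fails are skipped with a warning.
- **Patient-level bootstrap** (default 1,000 iterations, 80/20): patients
  are split without replacement, the model fits on training rows and scores
  mean squared error on test rows; degenerate splits are resampled.
- **Model comparison**: the two modes are run with the same seed so splits
  pair up; the comparison reports mean difference, the 2.5/97.5 percentile
  interval, and a two-sided bootstrap p-value floored at 1/n.

Error scores are mean squared and mean absolute residuals on the raw SLEDAI
scale, unclamped.

## Association

Each characteristic forms a 2×2 table (exposed subgroup vs reference). The
point estimate is the cross-product odds ratio with the Wald 95% CI on the
log scale. Tables with a zero cell yield infinite/zero sentinels (or the
Haldane 0.5 correction on request). Characteristics carried by fewer than
5% of the cohort, and zero-cell tables, are additionally analyzed with
conditional exact inference: the Fisher-type two-sided p-value and the
conditional maximum-likelihood odds ratio (solving the conditional score
equation under the noncentral hypergeometric distribution). Per-patient
biomarker/activity concordance profiles (per-interval direction agreement
and Pearson correlation) support patient-level inspection.

The package stores the published per-subgroup counts of a 110-patient
registry cohort (69 concordant vs 32 discordant patients) as worked-example
input; the eleven characteristics with finite published odds ratios that
separated the subgroups are the acceptance targets t1–t11.

## Synthetic cohort generator

Real registry data are not redistributable, so the pipeline is exercised on
a generator with planted ground truth mirroring the assumed structure:

- **Subgroup 1A (concordant, default n = 69).** A latent disease-activity
  trajectory: sinusoid (amplitude 1.2, period 8 visits at tempo 1) traversed
  at a patient-specific tempo drawn from (0.5, 2.0), entered at a shared
  baseline phase (jitter sd 0.4 rad), plus a small random walk (sd 0.15 per
  step). Parameters load on the *centered* latent signal (coefficient 0.8)
  plus noise (sd 0.5). Centering is deliberate: concordance is a property of
  the dynamics, and loading on the uncentered latent would leak each
  patient's latent mean into their magnitude profile, handing the magnitude
  clustering a signal that is not supposed to exist. SLEDAI-2k additionally
  receives a lagged contribution from the previous visit's cytokine values
  (coefficient 0.4), so the time-dependent model is genuinely better
  specified.
- **Subgroup 1B (discordant, default n = 32).** Parameters are pure noise
  matched to subgroup 1A's marginal standard deviation (no magnitude
  signal); activity follows its own latent trajectory at a random phase.
- **Group 2 (default n = 9).** Cytokine means shifted by +3 z-units and all
  spreads inflated ×1.5 — the small group magnitude clustering must isolate.

SLEDAI-2k is an affine map of the latent signal centered at 4 (scale 1.2,
noise sd 0.5), clamped at 0 and rounded. Values are emitted in plausible raw
assay units (fixed per-parameter location/scale), so pooled z-normalization
has real work to do. Visits: 5–11 per patient, gaps 30–90 days. Binary
outcome flags are drawn once per patient; subgroup-1B probabilities are
solved from configured odds ratios (defaults: flare 3.733, damage accrual
2.631, SLEDAI > 4 5.492, musculoskeletal involvement 7.68, biologics
15.692) against subgroup-1A baselines. Everything is reproducible from one
seed, and `truth_alignment_score` reports the adjusted Rand index of any
predicted partition against the planted one.

Identifiability note: the planted lag coefficients act on the generator's
z-scale draws, while the regression sees pooled-z-normalized raw values, so
the recoverable lag coefficient is the planted one times `sledai_scale`
times the ratio of the realized pooled standard deviation to the nominal raw
scale. The tests verify recovery within three standard errors under this
mapping.

What the generator does *not* emulate: missingness and informative dropout,
treatment feedback on biomarkers, assay batch effects, non-stationary
measurement noise, or correlations between the binary outcomes.

## Pipeline

Seven stages (preprocess; magnitude clustering; per-group time-agnostic
LOPO; time-dependent comparison on the majority group; DTW subgrouping;
per-subgroup regression; subgroup association), each writing CSV/JSON
artifacts and a line in `report.json`. Artifacts contain no timestamps, so
a rerun with the same inputs and seed is byte-identical. A failing stage
marks the report and stops, preserving earlier artifacts — except that a
small DTW subgroup that cannot support LOPO validation for some regression
mode records `null` for that entry rather than failing the stage, since
that is an expected outcome of an unbalanced split.

## Numerical choices

- Seeds: every stochastic component takes an explicit seed
  (`numpy.random.default_rng`); derived seeds are drawn below 2³¹.
- CSV floats: 17 significant digits out, round-trip parsing in.
- Wald CIs use z = 1.959963984540054.
- The conditional MLE solves the score equation by bisection on log ψ.
- Distance matrices validate symmetry, non-negativity, and a zero diagonal
  on construction.

## Limitations and open decisions

- The dendrogram-cut equality convention ("at or below") matters only for
  cuts landing exactly on a merge height; it was chosen so a full-height
  cut yields one cluster.
- The connectivity index follows its formula, not the occasionally quoted
  1.0 for the 4-point worked example (see above).
- The time-dependent model uses a single lag; longer memory is out of
  scope.
- Exact inference conditions on both margins; unconditional alternatives
  (e.g., Barnard) are not implemented.
- The generator's group sizes and outcome odds ratios are study conditions,
  not tuning knobs; they are fixed defaults of `SimConfig`.
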