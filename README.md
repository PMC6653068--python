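# sletraj — time-aware analysis of longitudinal SLE biomarker trajectories

Systemic lupus erythematosus (SLE) is heterogeneous: patients with similar
average biomarker levels can have very different disease *dynamics*. Routine
stratification compares magnitudes (mean biomarker profiles), which hides
patients whose biomarkers move in concordance with disease activity from
those whose biomarkers fluctuate independently of it. `sletraj` implements a
time-aware pipeline for longitudinal cohorts that:

1. pools and z-normalizes a 17-parameter panel (CRP, C3, C4, Hb, WCC,
   platelets, neutrophils, lymphocytes, ESR, dsDNA fold-ULN, UPCR, urine WCC,
   urine RBC, and the serum cytokines MIF, CCL2, CCL19, CXCL10) across all
   visits of all patients;
2. clusters patients by **magnitude** (Euclidean distance between per-patient
   summary vectors) to isolate a small high-cytokine, high-variance group;
3. clusters the remaining majority by **trajectory shape** using open-end
   multivariate dynamic time warping (DTW), which aligns patients observed at
   different tempos and for different durations;
4. asks whether disease activity (SLEDAI-2k) is better explained by a
   time-dependent regression than a time-agnostic one, validated without
   within-patient leakage;
5. associates the resulting subgroups with baseline characteristics and
   adverse outcomes via 2×2 odds ratios with exact small-sample inference.

Because longitudinal registry data of this kind are not publicly deposited,
the package ships a synthetic cohort generator with planted, known ground
truth (a concordant subgroup, a magnitude-matched discordant subgroup, and a
small high-cytokine group), plus the published per-subgroup characteristic
counts of a 110-patient registry cohort as worked-example inputs for the
association analysis.

## Model

For patient $p$ with visits $t = 1, \dots, T_p$, let $x_{p,t} \in
\mathbb{R}^{17}$ be the pooled z-scores of the panel and $y_{p,t}$ the
SLEDAI-2k score.

**Open-end DTW.** For two series $x_{1..n}$, $y_{1..m}$ with local cost
$c(i,j) = \lVert x_i - y_j \rVert^2$, the cumulative cost follows

$$D(i,j) = c(i,j) + \min\{D(i-1,j),\; D(i,j-1),\; D(i-1,j-1)\},$$

and the open-end distance is $\min$ of $D$ over the last row and last
column, so a shorter series may align with a prefix of a longer one.
Distances feed complete-linkage agglomerative clustering; the dendrogram is
cut at a fraction (default 0.9) of its maximum merge height. Partitions are
checked with the connectivity index, Dunn index, and 2-D embeddings
(classical and isotonic MDS).

**Regression.** Two nested linear models of disease activity:

- time-agnostic: $y_{p,t} = \alpha + \beta^\top x_{p,t} +
  \varepsilon_{p,t}$ (18 free parameters);
- time-dependent: $y_{p,t} = \alpha + \beta^\top x_{p,t} + \gamma^\top
  x_{p,t-1} + \varepsilon_{p,t}$ (35 free parameters; each patient's first
  visit contributes no row — lags never cross patients).

Validation is leave-one-patient-out (all visits of one patient are held out
together) and a patient-level 80/20 train/test bootstrap; the two models are
compared by the paired bootstrap distribution of their mean-squared-error
difference.

**Association.** For each binary characteristic, the subgroup-vs-subgroup
2×2 table yields the cross-product odds ratio with a Wald 95% CI; tables
with zero cells or rare characteristics (< 5% of the cohort) fall back to
conditional exact inference (Fisher-type p-value and conditional maximum
likelihood OR).

## Worked example

Run the whole analysis on a simulated 110-patient cohort:

```bash
sletraj run --simulate --seed 0 --out-dir results/pipeline
```

On this seed the run reports seven `ok` stages. Magnitude clustering
separates the planted high-cytokine group exactly (cluster sizes 101 / 9).
On the majority group the time-dependent model beats the time-agnostic one:
the paired bootstrap MSE difference is 0.705 (95% CI 0.294–1.108,
p = 0.002), and within the DTW-concordant subgroup the LOPO mean squared
error drops from 1.844 (time-agnostic) to 1.061 (time-dependent).

The same stages compose individually:

```bash
sletraj simulate --out-dir work --seed 0
sletraj preprocess --in work/visits.csv --out work/normalized.csv
sletraj cluster --in work/normalized.csv --out-dir work
sletraj dtw-cluster --in work/normalized.csv --out-dir work
sletraj regress --in work/normalized.csv --mode lagged --lopo --out-dir work
sletraj associate --labels work/dtw_labels.csv \
    --characteristics work/characteristics.csv --out work/association.csv
```

Recomputing the registry association table from the stored counts
(`python analysis/03_published_associations.py`) reproduces, e.g., an SFI
flare odds ratio of 3.733, mucocutaneous involvement 11.264 (p_exact
< 0.001), and biologics use 15.692 for the discordant subgroup.

## Repository layout

- `src/sletraj/` — the library (core model/IO, preprocessing, distances,
  clustering, regression, association, simulator, pipeline, CLI);
- `analysis/` — numbered thin drivers that write into `results/`;
- `tests/` — pytest suite, including independent brute-force oracles
  (`tests/oracles.py`) and the acceptance suite (`tests/test_acceptance.py`);
- `scripts/acceptance.py` — recomputes the headline targets;
- `docs/methods.md` — detailed methods, defaults, and design decisions.

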