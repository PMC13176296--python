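# Methods

`twascell` implements a cell-level analysis of genetic risk-gene activity
in single-cell RNA-seq. A risk-gene set — genes whose genetically
predicted expression associates with a trait in a summary-statistics TWAS
— is scored in every cell with five independent gene-set statistics; the
normalized scores are summed into a composite activity score; cells are
stratified into low / median / high activity states by quartiles; the
high-vs-low contrast drives a consensus feature-selection step and a
patient-aware predictive evaluation. Everything runs on synthetic cohorts
with planted ground truth.

## TWAS association stage

For a gene with eQTL weight vector `w` over its cis-SNPs, GWAS z-scores
`z` and SNP correlation (LD) matrix `V`, the association statistic is

    z_gene = wᵀz / √(wᵀVw),

two-sided normal p-value, Benjamini–Hochberg adjustment across all
testable genes, risk set = genes with q < 0.05 (strict inequality). Genes
whose predictive variance `wᵀVw` falls at or below 1e-12 are flagged
untestable and excluded before BH. The statistic is exact under the null:
conditional on `w`, `z_gene` is standard normal whenever `z ~ N(0, V)`,
which the null-calibration suite exercises.

The synthetic TWAS fixture gives each gene an independent cis block of
AR(1)-correlated SNPs (ρ = 0.5 by default; closed-form PSD). Causal genes
receive a mean shift along `Vw/√(wᵀVw)` so that their gene-level statistic
is `N(shift, 1)` by construction, which makes power analytically
predictable and the planted truth unambiguous.

## The five activity scores

All rankings order genes within a cell by descending log-normalized
expression with ties broken by gene identifier, so scores are fully
deterministic.

* **module_mean** — mean expression of set genes minus the mean of control
  genes. Genes are binned by average expression into `n_bins = 24`
  equal-size bins; up to `n_ctrl = 100` non-set genes per set gene are
  sampled (seeded, without replacement) from the set gene's bin and
  pooled. When the set exhausts a bin (e.g. the set is the whole
  transcriptome) the control falls back to the set itself, giving an exact
  zero rather than an error.
* **aucell** — area under the set-recovery step curve within the top
  `⌈0.05·G⌉` ranks, normalized by the maximal achievable area.
* **ucell** — clipped-rank Mann–Whitney statistic:
  `U' = Σ min(rankᵢ, r_max) − n_s(n_s+1)/2`, score
  `1 − U'/(n_s·(r_max − n_s))` with `r_max = 1500`, clamped to [0, 1].
  The clamp covers the small negative overshoot that occurs when several
  set genes are clipped simultaneously; the two anchor cases (single set
  gene at rank 1 → 1, at/beyond `r_max` → 0) are exact.
* **singscore** — mean of `(ascending rank − 0.5)/G` over set genes,
  centered by subtracting 0.5; symmetric about zero.
* **ssgsea** — single-sample weighted Kolmogorov–Smirnov running sum:
  walking the descending ranking, the sum rises by `w^α` (rank weight
  `w = G − position + 1`, normalized over the set; `α = 0.25`) at set
  genes and falls by `1/(G − n_s)` elsewhere; the score integrates the
  running sum over all positions.

Parameter defaults where the underlying algorithm families leave a free
choice (bins 24 / controls 100; top fraction 5%; max rank 1500; α = 0.25)
follow those families' conventions and are exposed as arguments.

Each raw column is z-scored and then min-max rescaled to [0, 1]. The two
steps compose to plain min-max on any non-constant column (z-scoring is
affine) — both are kept for fidelity to the composite-score recipe, and
the algebraic redundancy is itself asserted in the test suite. Constant
columns map to 0.5 so they are neutral in the sum and cannot propagate
NaNs. The composite Scoring is the row sum of the five normalized columns,
in [0, 5].

## Stratification and enrichment

Quartiles of the composite score (linear-interpolation percentiles) split
cells into low (≤ q25), median, and high (≥ q75) states; boundaries are
inclusive on both tails. Stratification is scoped to whatever cell
population it is invoked on — per-cell-type by default in the pipeline —
and the degenerate all-equal case labels every cell median with a warning.
Group enrichment uses Ro/e: observed over chi-square-expected counts in
the stratum × group table; entries with an empty margin are missing. The
column conservation law Σ_s expected(s,g)·Ro/e(s,g) = n_g is a test
invariant.

## High-vs-low task and the seven selectors

Median-state cells are dropped; high = 1, low = 0; features are the risk
genes present in the matrix (absences are reported, not fatal). Quartile
construction makes the classes ≈ 1:1, so no reweighting is applied.

Selector cutoffs: lasso keeps non-zero coefficients at an inner-CV-chosen
penalty (|coef| > 0; a sign-restricted variant is a caller option);
random forest keeps the top 10 by impurity importance (an absolute
importance threshold is available as an option, since any fixed threshold
is dataset-specific); XGBoost and LightGBM keep the top 20 by gain; the
decision tree keeps the top 20 with non-zero impurity importance; Boruta
keeps confirmed features, top 20 by mean importance; the best-subset
selector keeps its chosen support. The consensus signature is the exact
intersection of all seven lists, ordered by mean rank — monotone in every
list by construction.

**Boruta** is implemented from its defining procedure: each iteration
permutes every feature into a shadow copy, fits a forest on real + shadow
columns, and scores a hit when a real feature's importance exceeds the
best shadow's; features are confirmed/rejected by a two-sided exact
binomial test against p = 1/2 at α = 0.01 with Bonferroni correction over
still-tentative features, stopping early when nothing is tentative. A
practical caveat the tests document: on a fixed finite sample, a noise
feature whose chance correlation with the outcome is picked up
consistently by the forest is genuinely "relevant in-sample" and may stay
tentative; the guarantee the suite asserts is that null features are
almost never *confirmed* (≤ 5%) and mostly rejected.

**Best-subset (ABESS-type) selection** scores an OLS working model on the
0/1 outcome by BIC. With ≤ 15 features every subset up to the size cap is
enumerated (an exact search, also the oracle for its own tests); above
that, forward selection per support size is refined by single-swap
splicing, and the BIC-minimizing size wins. The OLS working model keeps
each candidate evaluation a closed-form least-squares solve.

## Patient-aware evaluation

All splits assign whole patients to one side. The 80/20 split greedily
adds patients, visited in a seeded random order, while doing so moves the
train cell count toward the target fraction; with few patients the exact
fraction is unattainable and the achieved fraction is reported. The
benchmark is nested CV: outer patient-grouped folds (10, or the patient
count if smaller) estimate AUC; inner 5-fold CV (patient-grouped when
enough patients remain, stratified otherwise) tunes each learner's small
grid. The default panel — penalized logistic, Gaussian naive Bayes, k-NN,
random forest, gradient boosting — is ordered simplest-first, which is
also the tiebreak for the mean-AUC winner; grids are deliberately tiny
(≤ 3 values per hyperparameter) and the panel is configurable.

AUC is the probability that a random positive outscores a random negative
(ties counted ½), computed from midranks; ROC/PR point lists come from
standard threshold sweeps. LOPO-CV holds out each patient once, fits a
scaled logistic model on the signature genes using all other patients, and
reports per-patient AUCs with median and IQR; held-out patients whose
cells are all one class are excluded and listed with the reason. A canary
test verifies no leakage: perturbing test cells arbitrarily leaves the
fitted training model bit-identical.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: 10 case + 10
control patients by default; per-cell log-normal library sizes
(σ = 0.35); gene-wise negative-binomial counts (variance μ + 0.4·μ²)
around log-normal baseline means; a planted "active" subpopulation —
exactly `round(active_fraction × cells_per_patient)` cells per patient
(0.35 case / 0.15 control by default) — whose risk-gene means are
multiplied by `2^0.5` and signature-gene means by `2^2`; per-cell QC
covariates (detected-gene count from the matrix, mitochondrial fraction as
a clipped-normal covariate rather than actual mito-gene counts, since the
QC filter consumes only the fraction). Risk-gene baseline means are drawn
from a moderate-expression law (log-normal mean 0, σ 0.5) against a
lower-expression background (mean −1, σ 1): genes carrying eQTL weights in
a tissue are by construction expressed there, and a risk gene with a
near-zero baseline would be undetectable to every scoring and selection
method regardless of its planted fold-change.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, cell-type hierarchies, or patient-level covariate shifts. Passing
tests therefore demonstrate correctness of the procedures and their
behavior under the assumed noise model, not robustness to those real-data
artifacts.

## Problem sizes and determinism

The test suite and the acceptance script run desk-scale problems chosen by
this package: cohorts of 4–8 patients × 80–200 cells and a few hundred
genes for planted-recovery suites (20 simulation seeds, medians reported),
and a 10+10-patient × 150-cell × 1500-gene cohort for the end-to-end
acceptance run. Every source of randomness is seeded; identical seeds give
bit-identical outputs, which the pipeline determinism test asserts at the
byte level on every artifact.

## QC boundary semantics

Cells survive QC when `min_genes ≤ detected ≤ max_genes` and
`pct_mito ≤ max_mito` (defaults 200 / 6000 / 15%): the filter removes
strictly-outside cells only, so the threshold values themselves are kept.
The mitochondrial threshold is interpreted as a fraction of total counts.
HVG selection ranks genes by variance of log-normalized expression with a
deterministic gene-id tiebreak — a loess-free simplification that is
monotone in dispersion under the NB model. PCA standardizes (clip ± 10)
the selected genes and fixes component signs so the largest-magnitude
loading is positive.
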