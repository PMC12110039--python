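# Methods and design notes

## Scope and model overview

The package re-implements, as pure functions over plain-text inputs, the
analysis chain of a digital-spatial-profiling (DSP) + multiplex-IF tumor
microenvironment study: per-AOI count QC, cell-type deconvolution,
two-group differential expression, single-cell spatial metrics, cut-off
survival analysis, and the correlation of imaging-derived cell densities
with expression-derived pathway scores. A synthetic-data generator
produces cohorts with the statistical structure these analyses assume, so
every downstream stage is testable end to end without external data.

## QC: LOQ and Q3 normalization

Negative-control probes carry no biological target; their counts in an
AOI estimate its background. The limit of quantitation is

    LOQ_a = geomean(neg_a) · geoSD(neg_a)^n_sd ,   n_sd = 2 by default,

with the geometric SD computed as `exp` of the sample (n−1) standard
deviation of natural-log counts. Zero probe counts are replaced by a
pseudo-count of 1 before logs, the thresholding convention that avoids
−∞; both conventions are stated here because they determine whether an
external reanalysis reproduces a given retained-gene count. Detection is
strict (`count > LOQ`; a tie does not count), and a gene is retained when
detected in at least `ceil(0.10 · n_AOIs)` AOIs (the ≥-with-ceiling
reading of "10% of AOIs", exposed as a flag).

Q3 normalization computes each AOI's 75th percentile over genes with
positive counts (linear interpolation) and rescales the AOI so that this
percentile equals the geometric mean of all AOI Q3s. With that common
target, doubling every count of one AOI shifts the target itself by
2^(1/n); all normalized columns absorb the same global factor and
relative expression is unchanged — the invariance the tests assert.

## Deconvolution

Cell-type abundances β per AOI minimize the sum of squared log residuals

    Σ_g [ log(y_g + δ) − log((Xβ)_g + b_g + δ) ]² ,  β ≥ 0,

where X is the signature restricted to shared genes, b an optional
per-gene background and δ = 0.5 a stabilizing offset (configurable). Log
residuals suit the multiplicative, right-skewed noise of counting data.
The solver is bound-constrained L-BFGS-B with the analytic gradient,
started from equal abundances scaled to the total signal; a
non-negative-least-squares fallback handles the rare non-converged AOI
and is flagged per AOI. Percentages are row-normalized β × 100. On
two-type/five-gene problems the returned objective is within 1e-4 of a
0–5 (step 0.01) grid search, and 60/30/10 three-type mixtures under NB
noise are recovered with per-type mean absolute error well under 10
percentage points.

The built-in signature (110 genes × 12 immune/stromal types) is a
synthetic stand-in assembled from canonical lineage markers (CD8A for
CD8 T cells, FOXP3 for Tregs, CD68/CD163 for macrophages, …) at a high
common level over a low deterministic baseline. It exists so tests and
demos need no download; a real profile matrix is loadable from CSV and
drops in unchanged. Group percentage summaries are means of per-AOI
percentages within group × compartment (the pooled-count alternative is
a one-line change and was deliberately not made the default).

## Differential expression

Counts are modeled per gene as NB(μ = s_i·m_group, var = μ + αμ²) with
Q3-derived size factors s_i (geometric-mean centered). Dispersions use a
Pearson-residual moment estimate per gene, shrunk toward the across-gene
median with a prior weight of 10 residual degrees of freedom — an
empirical-Bayes moderation in the spirit of standard RNA count
pipelines, pinned here so results are reproducible without an external
package. Group means are exact GLM MLEs obtained by a vectorized Newton
solve of the score equation; the Wald contrast of log means is referred
to a t distribution with n−2 degrees of freedom, a deliberately
conservative small-sample choice (with ~23 AOIs per compartment the
permutation-null false-positive rate sits at ~5%). log₂ fold changes use
a 0.5 pseudo-count on normalized group means so contrasts stay finite;
genes with no counts at all are flagged with log₂FC 0 and p 1.

DEG selection applies |log₂FC| ≥ 1 with raw p < 0.001 (strict on p), with
BH-adjusted values reported alongside — both criteria appear in the
literature this pipeline emulates, so both are surfaced. Gene-set
over-representation is a plain hypergeometric upper tail over any GMT
collection; no ontology-graph propagation is attempted.

## mIF spatial statistics

Gating is threshold-based with a fixed priority for multi-positive
cells: CK → cancer, else CD68 → macrophage, else FOXP3 → Treg, else CD8
(split by PD1), else CD56 → NK, else other. The priority is arbitrary but
deterministic and documented; with well-separated intensity modes it
recovers ≥ 99% of true labels. "Total CD8" always means PD1⁻ + PD1⁺.

Compartments are disc-shaped tumor-nest regions (boundary counts as
inside); areas use the union of discs clipped to the window (shapely), so
overlapping nests are not double-counted. Densities are counts per mm² of
compartment area. Distances are centroid-to-centroid Euclidean in µm with
no edge correction — a known limitation shared with raw reported means;
nearest-neighbor queries use a k-d tree and agree with the O(n²) brute
force to 1e-9 on 2,000-cell instances. When reference and target classes
overlap, self-matches are excluded by cell identity, not class equality.

Distance ratios are computed in both directions. The pipeline reports
the cancer-referenced direction (for each cancer cell, the nearest
immune cell). The planted-effect recovery checks use the immune→cancer
direction (for each Treg/CD8 cell, the nearest cancer cell) because the
clustered process acts on Treg positions and that direction measures it
without dilution over the cancer population.

## Survival

Markers are dichotomized at a median, mean or explicit cut-off; boundary
values go to "low" (a deterministic rule where none is prescribed).
Kaplan–Meier, the 1-df log-rank test and Cox proportional hazards come
from lifelines with Efron tie handling. Monotone partial likelihoods
(complete separation — likely at n = 12 when a marker tracks the group)
are detected and refit with a ridge penalty of 0.1, flagged in the
result. Simulation checks: type-I error 5% ± 2 under an independent
binary covariate, and a true hazard ratio of 3 at n = 200 recovered in
[2.5, 3.6] on average.

## Pathway scores and integration

The per-AOI gene-set score is the ssGSEA running-sum statistic: genes
ranked by expression, the in-set ECDF weighted by rank^0.25 minus the
uniform out-of-set ECDF, summed over the ranking, then rescaled by the
score range across AOIs. The GSVA-style KS kernel was deliberately not
reproduced: the integration consumes only relative scores, and the
ssGSEA variant is simpler to pin exactly (`--method ssgsea` marks the
choice). Scores depend on expression only through ranks, hence are
invariant to any strictly monotone transform.

Integration correlates patient-level quantities: mIF densities from the
tumor-nest compartment against pathway scores averaged over each
patient's PanCK AOIs, Spearman with tie correction, stratified by
recurrence group, with significance stars at 0.05/0.01/0.001. Patient
level (rather than AOI level) is the default because densities exist
once per patient; the aggregation is configurable. A cross-platform
gate — Spearman between a marker gene's expression and the matching
phenotype's density — runs first; a constant marker yields a flagged,
undefined correlation rather than an error.

## Synthetic data generator

The generator defines the study conditions:

- **Cohort**: 12 patients, 8 recurring. Recurring patients have events
  with PFS uniform on (3, 60) months; non-recurring are censored with
  PFS uniform on (60, 120) months (the "beyond five years" criterion).
  Uniform windows were chosen because group membership, not a time
  distribution, is the documented datum.
- **Design**: 11 patients × 2 ROIs + 1 × 1 ROI = 23 ROIs of 660 × 785
  µm², three AOIs each (PanCK/CD45/SMA) = 69 AOIs.
- **Counts**: expected AOI profiles are compartment- and group-specific
  mixtures of signature columns (PanCK adds a 60% carcinoma profile);
  mixing weights get a per-AOI Dirichlet jitter (concentration 150,
  i.e. mild compositional noise) and per-patient lognormal abundance
  multipliers (σ = 0.5) for selected types — applied identically to the
  cell-map densities, which is what couples the two platforms. Counts
  are NB with dispersion α = 0.1 (variance μ + 0.1μ²), matching the DEG
  model; total depth 60,000 per AOI; 10 negative probes at mean 5.
- **Planted expression effects** (log₂FC, non-recur over recur): TFPI2
  +2.0 and PIGR +2.0 in PanCK, NKG7 +1.32 and CYBB +1.12 in CD45, CDH5
  +1.28 and TRAC +1.23 in SMA, EYA2 −1.5 in PanCK and CD45 — the
  compartment-specific marker structure the downstream stages are asked
  to recover, applied symmetrically around the shared mean.
- **Cell maps**: 4 random disc nests of radius 130 µm per 660 × 785
  window; carcinoma cells at 800/mm² inside nests; immune phenotypes as
  Poisson processes at the reported group density means (cells/mm²,
  nest/stroma): e.g. total CD8 289.0/320.7 (non-recur) vs 46.6/110.0
  (recur), macrophages 270.3/443.2 vs 137.2/332.5. Treg densities
  follow from the planted ratio folds (6.40 nest, 2.37 stroma) on a
  non-recur baseline Treg/CD8 ratio of 0.15, a plausible suppressed
  baseline chosen once. In the recurrence group Tregs are a Thomas-type
  clustered process: each Treg is a Gaussian offspring (σ = 8 µm) of a
  parent cancer cell (60%) or macrophage (40%) compatible with its
  compartment — for stroma Tregs the eligible cancer parents are those
  within 1.5σ of a nest boundary, so stroma Tregs also acquire cancer
  proximity, as the planted biology intends. The nest radius of 130 µm
  keeps recur-group nest CD8 counts near 10 cells, so the per-sample
  ratio-of-counts estimator is not dominated by small-count bias.

What the generator does **not** emulate: spatial autocorrelation of
expression within an ROI beyond compartment identity, segmentation
errors, batch/slide effects, cell-size-dependent marker intensity,
holes/irregular nest shapes, and any marker–survival coupling beyond the
group labels. Passing tests therefore demonstrate correctness of the
estimators under the planted model, not robustness to those real-data
phenomena.

## Numerical choices and degenerate inputs

Optimizer tolerances: L-BFGS-B ftol 1e-12/gtol 1e-10, Newton relative
tolerance 1e-10 (≤ 50 iterations, halving steps that would cross zero).
Exact Wilcoxon rank-sum p-values for small tie-free samples, normal
approximation with tie correction otherwise. Ties in ssGSEA ranking are
averaged for weights with a stable sort for ordering. Errors are typed
(`spatialtme.exceptions`): too few negative probes, zero-Q3 AOIs (named
in the message), empty phenotype classes (named), degenerate median
splits, all-zero denominators, insufficient platform overlap.

## Problem sizes used by the checks

Oracle equivalences run on ≤ 2,000 cells, 20-gene deconvolution
instances, 10-gene score vectors and 6-subject survival tables.
Recovery experiments use 50–100 replicate cohorts or mixtures, 200
permutations for the DEG null, 500/200 Cox simulations at n = 200, and
1,000 Spearman null draws at n = 10 — sizes at which Monte-Carlo error
is small relative to the asserted bands while the whole suite stays
interactive.

## Known limitations

- The NB test is Wald-based; likelihood-ratio tests would be slightly
  more accurate at extreme fold changes.
- No multiple-testing structure across compartments (BH is within
  compartment, matching the emulated analysis).
- Deconvolution identifiability degrades for collinear signature
  columns; the built-in signature is well-conditioned by construction.
- Survival analyses at n = 12 are illustrative; separation is expected
  and flagged rather than prevented.
- Edge effects in distance metrics are uncorrected.
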