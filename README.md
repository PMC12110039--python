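# spatialtme

Integrated spatial-transcriptome and multiplex-immunofluorescence (mIF)
analysis of the tumor microenvironment, built around the study design of
digital spatial profiling (DSP) of ovarian high-grade serous carcinoma
(HGSC): rectangular regions of interest (ROIs) on tumor tissue, each
segmented into PanCK (tumor), CD45 (immune) and SMA (stroma) areas of
interest (AOIs), profiled for whole-transcriptome counts, paired with
single-cell mIF maps of the same tissue, and a small two-group cohort
(recurring vs non-recurring patients) with progression-free survival (PFS).

The package is aimed at computational biologists who want a tested,
reusable, fully synthetic-data-driven re-implementation of that analysis
chain — every stage can be exercised and validated without any external
download.

## What it computes

- **QC / normalization** (`geomx_qc`). Per-AOI limit of quantitation from
  negative-control probes, `LOQ_a = geomean(neg_a) · geoSD(neg_a)^2`;
  genes kept when count > LOQ in ≥ 10% of AOIs; upper-quartile (Q3)
  normalization scaling each AOI so its 75th-percentile count equals the
  geometric mean of all AOI Q3s.
- **Cell-type deconvolution** (`deconvolution`). Constrained log-normal
  regression: per AOI solve
  `argmin_{β≥0} Σ_g [log(y_g+δ) − log((Xβ)_g + b_g + δ)]²`
  against a genes × cell-types signature matrix `X` (built-in 110-gene,
  12-type synthetic signature included; any CSV signature loadable), plus
  Wilcoxon rank-sum group comparisons of per-AOI percentages.
- **Differential expression** (`differential_expression`). Per-gene
  negative-binomial GLM (variance μ + αμ²) with Q3 size-factor offsets,
  moment dispersions shrunk toward the across-gene trend (prior df 10),
  exact Newton group means, Wald t-test, Benjamini–Hochberg correction;
  DEG selection at |log₂FC| ≥ 1 and p < 0.001; Venn partitions and
  hypergeometric gene-set over-representation.
- **mIF spatial statistics** (`mif_spatial`). Threshold gating of marker
  intensities into phenotypes (CK/CD8/PD1/CD68/FOXP3/CD56), tumor-nest vs
  stroma compartment assignment, densities in cells/mm², Treg/CD8 density
  ratios, nearest-neighbor shortest distances (µm) and distance ratios,
  each with recurrence-group contrasts.
- **Survival** (`survival`). Median/mean/explicit cut-off dichotomization,
  Kaplan–Meier curves with log-rank tests, Cox proportional hazards
  (Efron ties; penalized refit on separation) via lifelines.
- **Pathway scoring and integration** (`pathway_scores`). ssGSEA-style
  rank-weighted running-sum scores per AOI and gene set (weight 0.25),
  Spearman correlation of patient-level immune-cell densities with
  patient-level pathway scores stratified by recurrence group, gated by a
  cross-platform consistency check (e.g. CD68 expression vs macrophage
  density).
- **Synthetic data** (`synthetic`). A first-class generator reproducing
  the study conditions: 12 patients (8 recurring), 23 ROIs of 660 × 785
  µm², 69 AOIs, NB counts around compartment-specific signature mixtures
  with planted group fold changes, negative probes, and marked point
  patterns with disc-shaped tumor nests, Poisson immune intensities from
  the reported group density means, and a Thomas-type clustered Treg
  process in the recurrence group.

## Worked example

```python
from spatialtme import RunConfig, run_pipeline

res = run_pipeline(RunConfig(out_dir="demo", seed=42))
s = res.summary
```

prints artifacts under `demo/` and yields, among others:

```text
ROIs: 23  AOIs: 69
genes retained: 110 / 110
macrophage %: non-recur 18.50 vs recur 13.48 (p=0.300)
Treg/CD8 density ratio fold (nest): 9.73 (p=0.0040)
CD68 vs macrophage density: rho=0.55 (p=0.067)
NKG7 (immune AOIs, median cut-off 1119.2): log-rank p=0.0310
```

Reading these numbers: the synthetic design reproduces the bookkeeping of
the emulated study (23 ROIs × 3 compartments = 69 AOIs); all 110 panel
genes clear the negative-probe LOQ at this sequencing depth; deconvolved
macrophage percentages trend higher in non-recurring tissue; the
regulatory-T-cell to CD8 T-cell density ratio inside tumor nests is
several-fold higher in the recurrence group (the generator plants a
6.40-fold effect; per-cohort estimates scatter around it); macrophage
density agrees with CD68 expression across platforms; and patients with
high NKG7 in immune segments separate on PFS.

The same pipeline is scriptable from the shell:

```bash
spatialtme run --seed 42 --out demo        # full pipeline, JSON summary
spatialtme simulate --seed 1 --out sim     # just the synthetic cohort
spatialtme qc --counts sim/counts.tsv --out qc_out
spatialtme deg --counts qc_out/qc_counts.tsv --annot sim/annotations.csv \
    --compartment PanCK --out deg_out
```

## Layout

```
src/spatialtme/     library modules (see module docstrings)
tests/              pytest suite incl. oracle-equivalence and
                    parameter-recovery acceptance checks
scripts/acceptance.py
docs/methods.md     model and design notes
```
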