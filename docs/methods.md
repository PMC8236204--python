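# Methods

## Models

### The cell-type interaction model

For probe `c` with methylation response `x_c` (M-values,
`M = log2(β/(1−β))`, clipped at `ε = 1e-6`), cell-type fractions
`f_1..f_K` (rows on the simplex), phenotype `y` and covariates `z`:

```
x_c = Σ_k f_k μ_kc + Σ_k f_k y β_kc + z ρ + e,   e ~ N(0, σ²)
```

fitted by OLS per probe with no intercept: because `Σ_k f_k = 1`, an
intercept is exactly collinear with the fraction columns. `μ_kc` is the
cell-type-specific mean level, `β_kc` the within-cell-type phenotype
effect. There is no phenotype main-effect column: a bulk-wide effect is
the special case `β_1c = … = β_Kc`, already representable by the
interaction columns. Each `β_kc` is tested two-sided against
`t(n − 2K − q)`; no small-sample correction is applied. The design matrix
is identical for every probe, so all probes are fitted in one batched
linear solve (the same QR factorization serves ~10⁴ probes in well under
a second).

Significance is decided on the M scale. Refitting the identical design on
β-values gives effect sizes interpretable as changes in methylation
proportion; since a proportion cannot change by more than 1, β-scale
estimates are clipped to [−1, 1] and flagged (`clipped=True`) rather than
silently truncated — a flagged +1/−1 is read as a complete
unmethylated↔methylated shift in that cell type.

Rank deficiency (e.g. `y ≡ 0` makes every interaction column zero; a
fraction column identically zero) is resolved left-to-right: a column in
the span of the columns before it is flagged inestimable and its
coefficient reported missing, never fabricated. This mirrors aliasing
order in standard linear-model software and guarantees that, when
`f_k` and `f_k·x_c` are exactly collinear in the reverse model, the
interaction terms (listed second) are the ones flagged.

### Comparators

* **Standard EWAS**: `x_c ~ 1 + y + z + f_{−ref}` per probe, testing the
  `y` coefficient. One fraction column is dropped (default the last);
  the test is invariant to which, because the fractions span the
  intercept. This is the model that *cannot* see opposing-direction
  effects: if `+δ` in one cell type is balanced by `−δ·(mean-fraction
  ratio)` in another, the expected bulk effect is zero.
* **Reverse interaction model**: `y ~ Σ f_k ν*_k + Σ f_k x_c γ*_kc + z ρ*`,
  no intercept, for continuous outcomes measured *after* the methylation
  sample (a binary prenatal exposure on the response side is flagged with
  a warning). Its design varies with the probe, so probes are fitted in a
  loop.

### Multiple testing

Benjamini–Hochberg FDR is applied within each cell type across probes by
default (`fdr_family="per_cell_type"`); a pooled probe×cell-type family is
available. The rationale for the default: genome-wide Bonferroni practice
divides by the number of probes, not probes×cell types, implying per-cell-type
families. Locus-level summaries (unique significant probes, per-probe count
of significant cell types) are identical under either choice. The Bonferroni
helper is simply `α / n_tests`; at `α = 0.05` and 790,563 retained probes it
reproduces the conventional epigenome-wide threshold 6.3×10⁻⁸.

### Residual-permutation null

Permuting raw phenotypes is invalid for interaction tests (it destroys the
covariate and main-effect structure along with the interactions). Instead:

1. Fit per probe the no-interaction model `x_c ~ f_1..f_K + y + z`
   (no intercept) and keep residuals `R = x_c − x̂_c`. Retaining the `y`
   main effect (`null-model: with-main`, the default) means the permutation
   destroys only interaction structure; a `without-main` variant is a
   config switch.
2. Draw ONE random re-ordering of samples and apply it to every probe's
   residual vector. The shared re-ordering preserves the cross-probe
   residual correlation matrix exactly, which is what makes the
   genome-wide minimum of the null comparable to the observed minimum.
3. Refit the full interaction model using the permuted residuals as the
   response (the `add_back_fitted` flag instead uses `x̂ + R_perm`) and
   record all probe×cell-type interaction p-values.
4. Repeat `n_perm` times (default 100; configurable — small replicate
   counts are sometimes preferred for plotting) with child seeds spawned
   from one master seed.

`qq_summary` returns −log10 observed order statistics against uniform
expectation with the pointwise min/max envelope across replicates, plus the
genomic inflation factor λ (median observed 1-df χ² quantile over 0.4549).

## The simulator

Bulk methylation is generated as `bulk_ic = Σ_k f_ki · v_kci + e_ic` on a
chosen mixing scale:

* `mixing_scale="M"` (default): the interaction model holds *exactly* by
  construction, so coefficient recovery can be tested to machine precision.
* `mixing_scale="beta"`: physically faithful convex mixing of proportions,
  the right setting for deconvolution tests; spiked β-scale effects that
  would push a pure value outside [0, 1] raise an error naming the probe.

Components:

* **Pure profiles.** K×P β-value matrix. The first
  `K × markers_per_type` probes are designed markers: for each cell type,
  half hypermethylated in that type (β ≈ 0.9 vs ≈ 0.1 elsewhere) and half
  the reverse, guaranteeing a one-vs-rest difference ≥ 0.5 — the structure
  a marker-selection procedure needs. Defaults (7 types × 100 markers)
  reproduce a 700-probe panel. Non-marker probes share one baseline value
  across cell types (between-type biological variation at non-marker loci
  is deliberately not modelled; within-type per-sample deviation is
  available via `within_type_sd`, default 0, since its magnitude in real
  tissue is not well established).
* **Compositions.** Dirichlet with `α_k = mean_k × concentration`. Default
  means are a real term-birth cohort's estimated composition (B 9.5%,
  CD4T 15.8%, CD8T 12.6%, Gran 39.9%, Mono 9.0%, NK 2.0%, nRBC 11.2%).
  The default concentration 44.49 is the closed-form least-squares fit of
  the common factor `1/√(c+1)` to the cohort's seven per-type SDs
  (`fit_dirichlet_concentration`); a single concentration cannot match all
  seven SDs exactly (the Dirichlet ties SD to mean), so per-type SDs are
  approximated — granulocytes slightly under-dispersed (7.3pp vs 9.2pp),
  B cells slightly over. `concentration=inf` collapses every sample to the
  mean, a useful degenerate case.
* **Phenotype and covariates.** Binary exposure Bernoulli(0.084) or
  standard-normal continuous outcome; covariates maternal age
  N(28.5, 4.2²), smoking Bernoulli(0.076), parity Bernoulli(0.48),
  gestational age N(39.5, 1.0²), child sex Bernoulli(0.545). The phenotype
  is independent of composition by default; `phenotype_proportion_corr=
  ("Mono", 0.16)` induces a monocyte–outcome correlation of the size seen
  in real cord blood. Optional `covariate_effects` add genuine `ρ` terms.
* **Noise.** `noise_sd` (default 0.5 on the M scale, a mid-range
  residual SD for array M-values) i.i.d. Gaussian on the mixing scale.
* **Determinism.** One integer seed; each stage (profiles, compositions,
  phenotype, mixing) draws from an independent CRC-derived child stream,
  so e.g. adding probes does not perturb the composition draw.

What the simulator does **not** emulate: probe-level technical artifacts
(dye bias, batch, detection failures), genotype effects at SNP-probes,
spatial/chromosomal correlation of methylation, heteroscedastic β-scale
noise near 0/1. Tests passing on these mixtures therefore demonstrate the
statistical machinery (estimation, calibration, power, null construction),
not robustness to array artifacts — those are handled upstream
(normalization, batch correction) and by the probe filters.

## Deconvolution

Marker selection ranks probes per cell type by one-vs-rest mean β
difference and takes the top `n_per_type/2` hyper- and hypomethylated
probes without replacement across types (types processed in label order;
with designed markers the selection is exactly the designed sets, and
estimates are invariant to marker ordering). Estimation solves, per
sample, `min_{w≥0} ‖β_markers − Panelᵀw‖²` (active-set NNLS), then
renormalizes `f = w / Σw` — non-negativity during the solve, simplex by
explicit renormalization, matching the two-stage practice with cord-blood
panels; an upper bound `w ≤ 1` is omitted as renormalization makes it
immaterial. With noiseless β-scale mixtures recovery is exact to ~1e-15;
with β-noise SD 0.02 the per-type RMSE stays under 5pp at n=275.

## Probe filters

Rules applied in a fixed order with first-rule attribution (so per-rule
counts sum to the total removed): non-CpG probes; sex-chromosome probes;
probes with detection p > 0.05 in ≥ 5% of samples (boundary inclusive);
probes with a SNP of MAF ≥ 5% at the target CpG or single-base extension;
known cross-reactive probes. Filtering is idempotent and independent of
probe order. Detection p-values are optional input (they come from raw
intensities, which this package does not process); batch correction is
deliberately upstream — a `batch` column in the manifest only triggers a
warning.

## Annotation

Coordinates are 1-based inclusive internally; BED12's 0-based half-open
intervals are converted at the boundary (and UTRs inferred from the thick
region by strand). A probe is `upstream_regulatory` if within 1,500 bp
upstream of the TSS (strand-aware, TSS-exclusive) or in the 5′UTR,
`downstream_regulatory` in the 3′UTR, `gene_body` elsewhere within
[start, end], else `intergenic`; with multiple overlapping genes all IDs
are reported and the most regulatory label wins (upstream > downstream >
body). Classification is strand-symmetric: mirroring coordinates and
flipping strands preserves labels. Which annotation release defines genes
is the caller's choice; no ontology enrichment is performed — per-cell-type
gene lists are emitted for use with any enrichment tool.

## Problem sizes used in the test suite

Validation simulations are sized to make each check statistically sharp:
type-I error at 10,000 null probes (3-SE binomial band around 0.05);
permutation-null uniformity at 5,000 probes × 20 replicates (700,000
pooled p-values, KS p > 0.01 and λ ∈ [0.95, 1.05]); coefficient recovery
at n=275 over 200 replicate cohorts of 50 spiked probes (mean absolute
bias < 0.05, CI coverage 92–98%); deconvolution calibration at 10,000
samples (granulocyte mean within 1pp). The opposing-effects power
contrast uses 60 independent cohorts — independent cohorts, not repeated
probes within one cohort, because all probes of one cohort share the same
realized composition–phenotype imbalance and would give a correlated
(and misleading) power estimate for the standard EWAS.

## Known limitations

* Homoscedastic OLS only; no robust/sandwich variance, no empirical-Bayes
  moderation, no mixed models.
* Deconvolution is reference-based only; no reference-free variant, and
  the real published cord-blood reference panel is not bundled (any panel
  can be supplied as CSV).
* The reverse model's per-probe loop is O(P) linear solves; fine to ~10⁵
  probes, not optimized beyond that.
* Fraction estimates enter the interaction model as known quantities;
  uncertainty from deconvolution is not propagated.
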