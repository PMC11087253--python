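# Methods

`mechamethyl` implements an epigenome-wide association (EWAS) workflow for a
two-arm, two-model mechanical-loading experiment on neo-cartilage organoids:
probe-level QC and normalization, per-model moderated-t differential
methylation, random-effects meta-analysis across the two organoid models,
differentially methylated region (DMR) scanning, chromatin-state enrichment,
positional integration with differential expression ("transcriptionally
active CpGs", tCpGs), and a clinical severity / RT-qPCR arm. This note
records the statistical model behind each stage, the defaults and why they
were chosen, and what the synthetic data generator does and does not emulate.

## Statistical model

**Per-probe linear model.** For each probe the methylation value (beta by
default, M = log2(beta/(1−beta)) optionally) is regressed on a loading
indicator, `y ~ loading` (plus optional covariates, e.g. organoid model for
the joint expression analysis). For the plain two-group design the loading
coefficient is the loaded-minus-control mean difference with unscaled
variance `v_g = 1/n_loaded + 1/n_control` and residual degrees of freedom
`d_g = n − 2`.

**Empirical-Bayes moderation.** Residual variances are assumed to follow a
scaled inverse-chi-square prior `σ_g² ~ s₀² d₀ / χ²_{d₀}`. The
hyperparameters are estimated by moment matching on
`e_g = log s_g² − ψ(d_g/2) + log(d_g/2)`:
`ψ′(d₀/2) = var(e) − mean(ψ′(d_g/2))` (solved by monotone bisection of the
trigamma function) and `log s₀² = mean(e) + ψ(d₀/2) − log(d₀/2)`. The
posterior variance `s²_post = (d₀ s₀² + d_g s_g²)/(d₀ + d_g)` gives the
moderated t with `d₀ + d_g` degrees of freedom. When the observed spread of
log-variances is at or below pure sampling noise, `d₀ = ∞` and every
variance is pinned at `s₀²`. The closed-form implementation reproduces
limma's `lmFit`/`eBayes` to ~1e-13 (cross-checked in the test suite via
Rscript). Forcing `d₀ = 0` reproduces the ordinary pooled two-sample t
exactly, which the tests assert.

**Meta-analysis.** The two per-model effect estimates are combined per probe
with the DerSimonian–Laird random-effects estimator: fixed-effect weights
`w_i = 1/se_i²` give Cochran's Q, the between-model variance is
`τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`, and the combined estimate uses
weights `1/(se_i² + τ²)`; `z = b_meta/se_meta` is referred to the standard
normal. BH FDR runs across all combined probes, and DM CpGs are flagged at
q < 0.01 (the pipeline also reports the Bonferroni bound α/n, e.g.
6.243109e-08 for a full 800,883-probe array, but all downstream stages use
the FDR flag).

**DMR rule.** A region must start and end at a DM CpG, contain ≥ 3 DM CpGs
and ≤ 3 interspersed non-DM CpGs, with every pair of consecutive member CpGs
< 1 kb apart. The gap rule is applied between consecutive *members* (DM or
not), the stricter of the two possible readings; `gap_between` is
config-exposed. Assembly is greedy left-to-right and maximal, which is
deterministic and verifiable against exhaustive window enumeration (the
tests do exactly that on randomized layouts). Region significance — not
specified by any standard — is a Stouffer combination of member DM CpG
z-scores with equal weights (Fisher's method available), BH-corrected across
regions; it is a documented stand-in, not a claim about any published
analysis.

**Chromatin-state enrichment.** For each of the 15 ChromHMM states a 2×2
table of DM status × state membership over the tested probe universe is
scored with a two-sided Fisher exact test; BH runs across the 15 states.
The background is the tested universe (probes surviving QC and
meta-analysis), not a full array manifest — enrichment should be relative to
what was actually tested.

**tCpG integration.** DM CpGs map to genes through promoter/UTR/exon
categories (TSS200, TSS1500, 5'UTR, 1stExon, ExonBnd, 3'UTR); gene-body
links are excluded. Differential expression is a moderated t on
log2(CPM + 0.5) with library-size normalization, jointly across both models
with a model covariate (`~ loading + model`). The expression FDR family is
restricted to the unique genes that carry ≥ 1 mapped DM CpG — "FDR
correction for the number of genes overlapping with mapped CpGs" — and
pairs are retained when the gene's restricted q < 0.05. A
negative-binomial DE model was deliberately not used: the moderated-t on
log-CPM keeps the repository's single inference engine well-defined and
reuses machinery that is oracle-tested; NB-based DE is out of scope.

**Clinical and qPCR.** Methylation at a selected CpG is regressed on the
Kellgren–Lawrence grade with BMI and age as covariates (OLS; the direction
and the response scale, beta or logit, are config-exposed — see below).
qPCR uses ΔCt against the mean of the housekeeping genes, fold change
2^−ΔΔCt, and a Gaussian linear model of −ΔCt on the loading indicator
(the only GLM consistent with a continuous, signed response).

## Analysis scale

Testing and effect estimation default to the beta scale, so effect sizes
read as methylation-fraction differences (the way array effect sizes are
usually quoted); `scale='m'` switches to the variance-stabilized M scale.
Per-model moderated p-values are calibrated on both scales in the
generator's regime (KS statistic ≈ 0.01 at 5,000 probes under the global
null; asserted in the test suite).

## Known calibration property of the k=2 random-effects step

With only two studies the DL estimator's `τ² = max(0, ·)` floor truncates at
zero for half the probes under homogeneity, and inflates `se_meta` for the
other half. The combined p-values are therefore mildly *conservative*: under
the global null their empirical CDF sits below uniform with a KS statistic
of ≈ 0.055–0.06 at 5,000 probes — an intrinsic property of the estimator,
reproducible with exactly known standard errors and exactly normal effects,
not an implementation artifact. The deviation is in the safe direction
(fewer false discoveries than nominal); realized false-discovery counts at
q < 0.01 are ≈ 0.01–0.05 per 5,000-probe null run. Users wanting exactly
uniform nulls should inspect the per-model p-values, which are calibrated.

## Synthetic data generator

The generator emulates the study design used throughout the tests: two
organoid models (spherical: 13 loaded / 13 control; cylindrical: 13 / 14 —
the 26/27 totals split evenly, per-arm sizes being otherwise unreported),
5,000 probes and 500 genes by default on four synthetic 10-Mb chromosomes.

* **Baselines and noise.** Probe baselines are bimodal on the M scale
  (mixture of N(−4,1), N(4,1), N(0,1.5)), mimicking the characteristic
  two-hump beta distribution of Infinium arrays. Residual noise is Gaussian
  on the M scale with SD `noise_sd_m = 0.5`, a typical M-value residual SD
  for array data; effects planted on the M scale keep betas in (0,1) by
  construction.
* **Loading effects.** A fraction `frac_dm = 0.05` of probes carries a
  signed M-scale effect `delta_m = 1.0`, plus a per-probe, per-model shift
  N(0, `tau_model = 0.25`) that creates genuine between-model heterogeneity
  for the random-effects step. Half of the DM budget is placed on whole
  positional probe clusters (4–8 probes, 80–400 bp gaps) with a shared
  effect sign, producing true DMRs; their intervals are recorded as the
  recovery target.
* **Nuisance structure.** 5% of probes are genotype-like: three beta bands
  near {0.05, 0.5, 0.95} with Hardy–Weinberg weights (allele frequency
  U(0.2, 0.8)) and band SD 0.02. 0.2% of probe×sample cells fail detection
  (p-value U(0.02, 1) instead of U(0, 0.005)); failures are not planted on
  DM probes so that effect recovery remains well defined.
* **Expression.** Counts are negative binomial (dispersion 0.1, gene means
  log-normal around 100, library sizes ±30%). A fraction
  `frac_linked_genes = 0.3` of the genes reachable from DM CpGs through
  qualifying categories receives a true log2 fold change of ±1.
* **Clinical.** KL grades are uniform on {1..4}, BMI ~ N(27, 4),
  age ~ N(65, 8); per-CpG beta is the inverse logit of a linear predictor
  with the planted KL slope on the *natural-logit* scale. Because an OLS of
  beta on KL estimates an attenuated, scale-mismatched quantity, recovery
  checks regress the logit of beta (`scale='logit'`), while the beta-scale
  default matches how clinical methylation coefficients are conventionally
  reported.

What the generator does **not** emulate: raw IDAT intensities and Infinium
I/II chemistry, control probes (the control-probe PCA normalization step is
exercised with explicitly constructed control matrices in tests and is
applied in the pipeline only when a control matrix is supplied), probe
cross-reactivity (the blacklist path is exercised with synthetic lists),
batch/chip layout effects, genomic correlation of methylation beyond the
planted clusters, and count–methylation correlation at the per-sample level
(linkage is planted at the group-effect level). Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
stated generative model — not that real-array technical artifacts are fully
handled.

## Numerical choices

* Beta values are clipped to [1e-6, 1−1e-6] before the logit; the M/beta
  round-trip is exact to < 1e-9 away from the clip boundary.
* Quantile normalization resolves ties by averaging the tied reference
  values, which makes the transform idempotent (asserted to 1e-12).
* The trigamma inversion in the prior fit uses monotone bisection on a
  log-spaced bracket [1e-8, 1e8]; spread at or below sampling noise maps to
  `d₀ = ∞` rather than a huge finite value.
* SNP-like flagging adds two robustness rules to the three-band heuristic:
  bands holding a single sample are treated as outliers and ignored, and
  adjacent occupied bands must have means > 0.2 apart. Without the
  separation rule a unimodal probe straddling a band boundary — or a truly
  DM probe whose two condition groups fall either side of one — is falsely
  flagged (measured false-positive rate ≈ 11% vs < 1% with the rule).
* DMR assembly breaks ties by earliest start; regions never overlap.
* Degenerate inputs raise typed errors (`InvalidDesignError`, `DomainError`,
  `EmptyInputError`, `AnnotationMismatchError`, `ConfigError`) before any
  partial computation.

## Problem sizes

Default simulations run at 5,000 probes × 53 samples × 2 models and 500
genes; null-calibration and recovery studies repeat this over 5–20 seeds.
These sizes keep every planted structure (clusters, genotype bands,
detection failures) well represented while the full test suite and the
acceptance script each complete in well under a minute of compute per study.

## Limitations

* The k=2 random-effects conservatism described above.
* Functional normalization is a generic control-probe PCA regression, not
  minfi's summary-statistic pipeline; it preserves the statistical intent
  (remove technical variation visible to control probes), not the exact
  output.
* Gene symbols are case-normalized but not alias-resolved; no external
  databases are consulted.
* DMR significance has no accepted reference procedure; the Stouffer
  combination ignores inter-CpG correlation and should be read as a ranking
  score rather than a calibrated p-value.
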