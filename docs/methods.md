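# Methods

This note documents the statistical models implemented in `stemomics`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## Study design and data model

Two cell populations — parental (condition `P`) and stem-like (condition
`S`) — are profiled on two omics layers sharing one sample sheet:

* a metabolite concentration table (pmol per 10⁶ cells), stored **raw**,
  i.e. before division by each sample's protein mass in mg
  (`normalize_to_protein` performs that correction and everything
  downstream consumes corrected values);
* a log₂-scale expression matrix over a signaling-pathway gene panel
  (Wnt, Ca²⁺ signaling, nicotinate/nicotinamide metabolism member lists,
  carried as GMT files).

Samples may additionally carry a glucose `plus`/`minus` label; all group
statistics in this package compare `S` versus `P`.

## Metabolite statistics

Group comparison defaults to the equal-variance Student *t*-test on
untransformed, protein-corrected concentrations; Welch's test and a log₂
transform are flags. Significance tiers are assigned at 0.05/0.01/0.001 on
the raw p-values — a targeted panel is reported untouched by multiple-testing
correction, with Benjamini–Hochberg q-values available behind a flag. Two
metabolites' ratio (NAAD⁺/NAADP⁺) is formed per sample and compared with
the same machinery. Z-score profiles standardize every sample against the
parental group's per-metabolite mean and SD (n − 1 denominator throughout);
metabolites with zero reference SD are excluded with a log message. A
zero-variance, equal-mean comparison returns p = 1 by convention.

## PLS-DA

* **Coding and scaling.** Class membership is a single 0/1 dummy (the
  lexicographically larger class, `S`, is 1), centered; features are
  mean-centered and scaled to unit variance (n − 1 SD). Constant features
  are excluded with a warning.
* **Fitting.** NIPALS with sequential deflation. With a single response
  column each component is extracted in closed form (the inner iteration
  converges in one pass); the documented tolerance for the general case is
  a relative score change below 1e-10 within 500 iterations. Extraction
  truncates with a warning when X is numerically exhausted (rank reached).
  The first nonzero element of each weight vector is forced positive, so
  refits are bit-identical.
* **Fit statistics.** R²X = Σₐ ‖tₐpₐᵀ‖²/‖X‖², R²Y analogously on the
  centered dummy. Q² = 1 − PRESS/TSS from stratified k-fold
  cross-validation (default 7 folds, deterministic round-robin assignment;
  k = n reduces to leave-one-out). Scaling and the response offset are
  re-estimated inside each training fold, so no information leaks from
  held-out samples.
* **VIP.** VIPⱼ = √(p · Σₐ SSYₐ w²ⱼₐ / Σₐ SSYₐ) with SSYₐ = q²ₐ tₐᵀtₐ;
  since weights are unit-norm, Σⱼ VIPⱼ² = p exactly. Discriminant
  selection requires VIP > 1 and univariate p < 0.05.
* **Permutation validation.** Default 100 rounds of uniform label
  shuffling; R²Y and Q² are recomputed per round and the empirical p uses
  the +1/+1 estimator (never 0). Shuffles are *not* filtered: at n = 5 + 5
  a round occasionally reproduces the true labeling (or its complement)
  and ties the observed Q², so the attainable floor is slightly above
  1/(n_perm + 1). Rounds whose refit fails are excluded and counted.
* **Hotelling ellipse.** Axis-aligned in score space with semi-axis
  sd(tₐ)·√(2(n−1)/(n−2)·F₂,ₙ₋₂(1−α)), α = 0.05 by default; Monte-Carlo
  coverage is verified at 95% ± 2% in the test suite.

## Expression preprocessing and differential expression

Quantile normalization forces every sample column onto the mean sorted
distribution; tied values within a column share the mean of the reference
values their ranks span. The transform is idempotent and requires a
complete matrix. log₂-centering subtracts each gene's mean after log₂ (a
non-positive value is a hard error naming the cell). Probe-to-gene
collapsing, when needed, keeps the probe with the highest mean intensity
per gene (ties by probe id).

The random-variance (moderated) *t*-test assumes per-gene variances follow
an inverse-gamma prior, under which the pooled residual variance s² is
marginally distributed as b·F(m, 2a) with m = n − 2. (a, b) are fitted by
maximum likelihood over (log a, log b); the shrunken variance is
s̃² = (m·s² + 2ab)/(m + 2a) and the statistic is referred to t with m + 2a
degrees of freedom. a → 0 recovers the ordinary Student *t*. The search
confines a to [1e-3, 1e4]; the upper bound is the homogeneous-variance
limit, where shrinkage is effectively total and additional degrees of
freedom change nothing. If the fit fails, the method falls back to the
ordinary test with a warning. Because the fit is a numerical optimization,
results are reproducible but sensitive to float summation order at the
~1e-6 level (e.g. under column permutations of the input).

## Gene-set enrichment

Classic (unweighted) Kolmogorov–Smirnov running sum over the gene list
ranked by decreasing *t*-statistic (ties broken by gene id): hits step up
1/Nh, misses step down 1/(N − Nh); the enrichment score is the signed
maximum deviation, bounded in [−1, 1]. The null is gene-set membership
permutation (same-size random draws), chosen over phenotype permutation
because the design's per-group n is too small for the latter; p-values are
two-sided on |ES| with the +1/+1 estimator, and Benjamini–Hochberg
q-values are reported across sets. Sets overlapping the ranking in fewer
than 5 genes are skipped. A rank-weighted variant exists behind a flag.

## Differential co-expression network

Per condition, pairwise Pearson correlations over that condition's samples
only (≥ 3 required; a loud warning below 8, where sample correlations are
extremely noisy). Negative correlations are removed — an edge exists only
where r > 0, strictly. Differential selection keeps pairs with r_S > 0 and
r_S − r_P > τ (default τ = 0.6, signed difference, strict inequality);
`P_gain` is the mirror image and `both` the union. The positive filter is
applied to the *gained* condition's matrix: a "co-expressed in S" edge is
meaningless if r_S ≤ 0, while r_P may legitimately be negative. Zero
variance genes yield missing correlations, which never create edges.
Hubs are ranked by degree over selected edges, ties lexicographic.

Selection is monotone in τ, and `S_gain`/`P_gain` are exact mirror images;
both properties, and agreement with literal pair enumeration on small
instances, are enforced by tests.

## Gene–metabolite integration

Per condition, the metabolites × genes Pearson matrix over samples paired
by identical id across the two layers (unpaired samples are an error; no
imputation). Gene columns are clustered by average-linkage agglomeration
on the distance 1 − r between their correlation profiles — 1 − r rather
than 1 − |r| so sign-discordant genes separate — and the tree is cut into
exactly k clusters (default 10), renumbered contiguously by first
appearance so relabeling genes relabels clusters. Metabolite rows are not
clustered (fixed pathway order). Genes whose profile is entirely missing
(zero variance in a condition, e.g. rank-constant after quantile
normalization of a small panel) are dropped with a warning before
clustering. Display export clips values to ±0.7; statistics always use
uncapped values.

The differential-association report gives, per cluster × metabolite, the
mean correlation in P and S and Δ = mean_S − mean_P, plus two flags:
`sign_flip` (the mean association changes sign) and `flagged`
(|Δ| ≥ 0.5). The Δ-based flag is the operative one: a planted S-only
coupling leaves the P-side mean hovering around zero, where a sign test
alone would be a coin flip. The 0.5 default is half the correlation range
on the display scale; it is a reporting threshold, not a test.

## Synthetic-data generator

The generator defines the study conditions:

* **Metabolome.** 28 NMR-panel plus 10 targeted NAD-pathway metabolites
  (NAAD⁺ appears in both, 37 distinct). Per-metabolite baselines are
  log-normal around 50 pmol/10⁶ cells. Concentrations are log-normal with
  multiplicative condition effects: log x = log baseline + [S]·log(fold) +
  ε, ε ~ N(0, log(1+cv)²). The default planted folds are NAAD⁺ ×2.0,
  NAADP⁺ ×0.5 (so the NAAD⁺/NAADP⁺ ratio rises ~4-fold), ADP ×1.8,
  glutamate ×0.6, proline ×0.7. Protein mass is a Uniform(0.8, 1.2) mg
  nuisance multiplied into the raw table, so the normalization path is
  always exercised. The default within-group CV is 0.15, a typical
  targeted-assay biological CV; recovery simulations that specify cv = 0.1
  set it explicitly.
* **Transcriptome.** 194 genes (named pathway members first, filler after),
  baselines N(8, 2) on the log₂ scale. In condition S the 10 planted
  module genes are √ρ·f + √(1−ρ)·εᵢ around their baselines with a shared
  per-sample latent f, so the expected within-module pairwise Pearson
  correlation is exactly ρ (default 0.85); in P all genes are independent.
  Differentially expressed genes add their log₂ effect in S (by default
  the module genes +1, plus ALPL up, CD38 down — coordinated pathway
  up-regulation).
* **Coupling.** The NAAD⁺ log-abundance noise in S samples is mixed with
  the same module latent at c = 0.9, planting an S-specific
  gene–metabolite association of roughly c·√ρ ≈ 0.8 at the gene level.
* **Design sizes.** Default n = 5 per condition × glucose cell, matching
  the targeted panel's group sizes; network-recovery simulations use
  n = 30 per condition, the smallest size at which a τ = 0.6 differential
  edge is reliably distinguishable from sampling noise.
* **Reproducibility.** One master seed; `SeedSequence(seed).spawn` block
  k is fixed as 0 = sample sheet/protein, 1 = metabolome,
  2 = transcriptome, 3 = module latent (PCG64 streams). Identical
  config + seed reproduces every artifact byte-for-byte.

What the generator does **not** emulate: raw NMR/MS spectra and their
processing artifacts, probe-level microarray noise beyond Gaussian,
batch/array effects, missing values, heavy-tailed or count-like noise, and
any biology beyond the planted first-order structure. Passing recovery
tests therefore demonstrate that the estimators are correct and calibrated
under the stated generative model — not that real spectra or arrays would
yield the same power.

## Known limitations

* At the targeted panel's scale (n = 5 per group) Q² and the permutation
  p are highly seed-variable; this is a property of the design size, and
  the package reports it rather than smoothing it.
* Under the global null at n = 30 per condition, the probability that a
  gene pair clears the τ = 0.6 differential-edge rule is slightly above
  1% (the acceptance script measures ≈1.02–1.03% over the 194-gene
  panel). Differential-edge selection is a threshold rule, not a
  calibrated test; on panels of hundreds of genes the selected set at this
  n contains a material number of chance edges, which is why recovery is
  evaluated on the ~30-gene pathway panel the network is defined over.
* The random-variance prior fit assumes the inverse-gamma model; gross
  misspecification degrades it to (at worst) the ordinary test via the
  fallback.
* Quantile normalization requires complete matrices and can make
  rank-constant genes exactly constant on small panels; such genes are
  excluded from correlation-based stages with a warning.
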