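# stemomics

Integrated metabolome–transcriptome analysis of parental (P) versus
stem-like (S) cancer cell populations, packaged as a tested, reusable
pipeline.

## The problem

Stem-like cancer cells selected by metabolic stress rewire both their
metabolite pools and their signaling transcriptome. Characterizing that
rewiring from paired omics measurements involves a chain of classical but
easy-to-get-wrong statistics:

1. **Targeted metabolomics** — concentrations (pmol per 10⁶ cells) are
   corrected by each sample's protein mass (mg), compared between groups by
   Student's *t*-tests with `*`/`**`/`***` significance tiers, summarized as
   fold changes, derived ratios (e.g. NAAD⁺/NAADP⁺) and Z-score profiles
   against the parental reference.
2. **PLS-DA** — a two-class partial least squares discriminant analysis on
   unit-variance-scaled data, fitted by NIPALS. The model is described by
   *R²X* and *R²Y* (variance explained in the data and in class membership),
   *Q²* = 1 − PRESS/TSS from stratified cross-validation, and a repeated
   permutation test of the class labels. Discriminating metabolites are
   those with VIP > 1 *and* univariate *p* < 0.05, where
   VIPⱼ = √( p · Σₐ SSYₐ w²ⱼₐ / Σₐ SSYₐ ) and Σⱼ VIPⱼ² = p by construction.
   The 2-component score plot carries the 95% Hotelling *T*² ellipse.
3. **Transcriptomics** — quantile normalization, log₂ transform with
   per-gene centering, ordinary or *random-variance* (moderated) *t*-tests
   whose per-gene variances are shrunk toward an inverse-gamma prior fitted
   across genes, and classic Kolmogorov–Smirnov gene-set enrichment with a
   membership-permutation null.
4. **Differential co-expression networks** — pairwise Pearson correlations
   among pathway genes per condition, negative correlations removed, and
   differential edges selected where r_S > 0 and r_S − r_P > τ (default
   τ = 0.6): gene pairs co-expressed in the stem-like cells but not the
   parental ones. Hubs are the highest-degree genes of the selected set.
5. **Gene–metabolite integration** — per-condition Pearson matrices between
   pathway genes and NAD-pathway metabolites, average-linkage hierarchical
   clustering of gene columns (distance 1 − r) into k = 10 sub-clusters,
   display capping at ±0.7, and a per-cluster report of associations that
   flip between conditions.

Because no public dataset accompanies this design, the package ships a
first-class **synthetic-data generator** that plants the reported structure
(a ~2-fold NAAD⁺ elevation in S, a gene module co-expressed only in S, an
S-specific gene–metabolite coupling) together with a machine-readable
ground-truth record, so every stage is testable end to end.

## Worked example

One command simulates a full study and runs every stage:

```sh
stemomics run --seed 17 --out demo
```

prints (abridged):

```json
{
  "metabolomics": {
    "n_significant_p05": 10,
    "naad_fold_change": 2.0687268323880645,
    "naad_p_value": 1.927861646318164e-07
  },
  "plsda": {
    "R2X": 0.26980262174110603,
    "R2Y": 0.9853741477043517,
    "Q2": 0.883161997780119,
    "permutation_p_Q2": 0.009900990099009901,
    "n_discriminant": 10
  },
  "diffnet": {
    "n_genes": 30,
    "n_selected_edges": 78,
    "hubs": ["PPP2R5C", "CSNK2B", "SIAH1", "CACYBP", "CSNK1A1"]
  }
}
```

Reading: the generator planted a 2-fold NAAD⁺ elevation and the *t*-test
recovers a fold change of 2.07 at *p* ≈ 2·10⁻⁷; the PLS-DA model explains
98.5% of class variance with a cross-validated *Q²* of 0.88, and its
permutation *p* of 1/101 means no label shuffle matched the observed
predictability; the differential network over the 30-gene Wnt panel selects
78 edges whose top hubs are planted module genes. All artifacts (matrices,
sample sheet, GMT sets, model JSON, edge lists, GraphML, cluster report)
are written under `demo/`.

Each stage is also available as a library function
(`stemomics.fit_plsda`, `stemomics.build_diffnet`, …) and as its own
subcommand (`simulate`, `metab`, `plsda`, `de`, `enrich`, `diffnet`,
`integrate`).

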