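# bcellsig

Tools for dissecting heterogeneity in a case/control B-cell expression
cohort. The package grew out of a recurring pattern in autoimmune
transcriptomics: when patients with quiescent disease are compared to
healthy controls as one group, almost nothing is differentially
expressed — yet an unsupervised look at the samples reveals an outlier
patient subgroup with a strong, coherent signature that can then be
traced back to a candidate extrinsic stimulus (a ligand-response
imprint). `bcellsig` implements that entire analysis as a tested,
reusable library, together with a synthetic-data generator that plants
exactly the structure the analysis assumes, so every stage can be
validated by parameter recovery without access to the original cohort.

## What it computes

**Expression filtering.** Probe sets on a log2 scale are kept when
their group mean reaches a threshold (default 4) in at least one of
the two groups; roughly a third of a whole-genome array survives this
in purified B cells.

**Differential expression (permutation FDR).** The moderated
difference statistic

    d_i = (x̄_A,i − x̄_B,i) / (s_i + s0)

where `s_i` is the pooled standard error of the mean difference and
`s0` is a fudge factor chosen by a percentile search that minimizes
the coefficient of variation of `|d|` across variance windows.
Significance comes from permuting group labels over distinct splits
(enumerated exactly when feasible): the FDR at a cut `Δ` is
`π0 · (median #{|d_perm| ≥ Δ} + 1) / #called`, and a gene's q-value is
the smallest FDR at which it is called. A Wilcoxon rank-sum screen,
Benjamini–Hochberg adjustment and an immunoglobulin-locus filter
(IGH/IGK/IGL/IGJ/IG@ prefixes) round out the module.

**Subgroup discovery.** Complete-linkage hierarchical clustering of
samples on the expressed genes; the detector enumerates all maximal
patient-only subtrees (≥ 3 leaves), scores each by the mean silhouette
width of its members against the remaining samples, and reports the
best call above a floor of 0.05.

**Directional ligand-signature overlap.** Given a compendium of mouse
B-cell ligand-stimulation signatures (gene, log2 fold change at 4 h;
signature = |fold change| ≥ 1.5), each ligand is scored against the
subgroup's gene list inside the shared human/mouse gene universe by
the Representation Factor `RF = x /(n1·n2/N)`, the hypergeometric
tail `P(X ≥ x)`, a binomial sign-concordance test
`P(K ≥ k | x, ½)` on the overlapping genes' directions, and an
optional joint resampling null. Hypergeometric gene-set enrichment
with Bonferroni correction is included for pathway analysis, and a
comparative-Ct (ΔΔCt) helper supports qPCR follow-up.

## Worked example

`examples/03_subgroup_discovery.py` simulates the default study
(20,000 probes, 9 controls vs 17 patients, a hidden 5-patient subgroup
carrying an 800-gene ±1 log2 module) and recovers the subgroup:

```
planted subgroup:   ['P01', 'P02', 'P07', 'P08', 'P09']
detected subgroup:  ['P01', 'P02', 'P07', 'P08', 'P09']
silhouette width:   0.147
separation height:  55.1
```

`examples/04_ligand_overlap.py` continues to the ligand screen: the
subgroup-vs-control contrast yields a 695-gene directional list, and
ranking the 33-ligand compendium against it gives

```
   ligand  overlap  same_direction       rf      p_hyper       p_sign  significant
ligand_29      102              93 5.409134 1.440395e-54 4.988779e-19         True
ligand_11       18              11 1.502383 5.045780e-02 2.403412e-01        False
```

Only the planted target (`ligand_29`) survives Bonferroni on both the
overlap and the concordance test — 102 shared genes of which 93 move
in the same direction, against a chance expectation of ~19 shared
genes and 50% concordance. The decoys sit at RF ≈ 1 with null
p-values, which is exactly the specificity the method needs.

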