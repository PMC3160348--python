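# Methods

This note records the statistical model behind each stage, the
defaults and why they were chosen, and what the synthetic benchmark
does and does not establish.

## Data model

All expression values are log2-scale probe-set intensities (probes ×
samples) with a per-probe gene-symbol annotation; multiple probes may
map to one gene and probes without a symbol are allowed. Samples
carry a binary group label (control / patient) plus optional clinical
covariates that the statistics ignore. Matrices arriving on the
linear scale can be converted with `log2_transform(x, offset=1)`.
Probe-level background correction and summarization are out of scope:
the pipeline consumes already-normalized matrices, and provides only a
rank-based quantile normalization (every sample's sorted vector is
replaced by the across-sample mean of sorted vectors; ties receive
the mean of the reference values over their rank span) for synthetic
or raw-matrix inputs with array-level distribution shifts.

## Expression filter

A probe is dropped iff its mean falls below the threshold (default 4
on the log2 scale) in *both* groups; equivalently it is retained when
either group mean reaches the threshold. The group-mean reading is
one of several defensible operationalizations of "unexpressed in both
patients and controls"; `overall_mean`, `max` and `median` rules are
selectable. The filter is idempotent and permits (with a warning) an
empty result.

## Moderated-difference test with permutation FDR

For groups A and B the per-gene statistic is
`d = (x̄_A − x̄_B)/(s + s0)` with
`s = sqrt((1/n_A + 1/n_B) · SS_pooled/(n_A + n_B − 2))`.

* **Fudge factor `s0`.** Candidates are the 0, 5, …, 100th
  percentiles of the `s` distribution. For each candidate, genes are
  split into ≈`n/10` (2–100) quantile windows of `s`, and the
  coefficient of variation of the window-wise median `|d|` is
  computed; the candidate minimizing it is chosen. When all `s` are
  equal every candidate rescales `d` uniformly and the common value is
  returned (zero for all-zero `s`).
* **Permutation null.** Distinct label splits sampled without
  replacement (mandatory seed); when the number of distinct splits is
  at most `n_perm` the null is enumerated exactly. Per-gene `p_perm`
  uses the gene's own permuted `|d|` values, with add-one smoothing
  when the null is sampled rather than enumerated.
* **π0.** Estimated as `min(1, 2 · fraction of observed d inside the
  interquartile range of the pooled permuted d)`.
* **FDR and q.** Cut points are the observed `|d|` order statistics.
  At each cut, the number of permuted `|d|` values beyond it is
  summarized across permutations and scaled:
  `FDR = π0 · (median_count + 1)/n_called`, clipped at 1; a gene's q
  is the suffix-minimum of FDR over cuts at or below its `|d|`, which
  makes q monotone in `|d|`. The add-one smoothing is deliberate: the
  raw median count is 0 at the most extreme cut in roughly half of
  pure-noise datasets (fewer than half the permutations beat the
  observed maximum), which would assign FDR 0 to the top gene of a
  null experiment, while the mean count is inflated whenever sampled
  splits partially reconstruct a genuine group difference and then
  costs real power. The smoothed median keeps the estimator calibrated
  on nulls (median 0 genes called at FDR ≤ 0.10 across null cohorts)
  without sacrificing sensitivity (>80% of planted module genes
  recovered at FDR ≤ 0.01 under the default conditions); both raw
  counts are reported in `delta_grid` for inspection.
* **Contrast for the subgroup stage.** Default is subgroup patients
  vs controls; a flag adds the remaining patients to the reference
  side. The subgroup-vs-controls default keeps the reference group
  homogeneous and the contrast interpretable.

The Wilcoxon screen uses the exact rank-sum distribution when both
groups have ≤ 12 samples and the tie-corrected normal approximation
otherwise; constant probes get p = 1. Benjamini–Hochberg adjustment
is the standard step-up procedure. The immunoglobulin filter removes
symbols with prefixes IGH/IGK/IGL/IGJ and the IG@ cluster alias —
prefix-anchored so IGF1 or IGSF3 survive — because clonally variable
Ig transcripts otherwise dominate any B-cell contrast.

## Subgroup detection

Distances are euclidean over all expressed genes; linkage is
complete; both are configurable and were chosen as the common
defaults of the standard `dist`/`hclust`-style tools. The detector
enumerates maximal subtrees whose leaves are exclusively patients with
at least `min_size = 3` members, scores each by the mean silhouette
width of its members against all remaining samples (precomputed
distances), and returns the best call when it exceeds a floor of
0.05; otherwise it reports no subgroup. The rule replaces a
by-eye dendrogram reading with a reproducible criterion; the
silhouette floor is intentionally low because the procedure's purpose
is to nominate a candidate subgroup for the follow-up contrast, which
then stands on its own FDR footing. Equal-distance merges resolve
deterministically via the condensed-distance ordering (smallest leaf
index first), and the whole stage is seed-free.

## Directional ligand-signature overlap

A ligand's signature is the set of genes with |linear fold change| ≥
1.5 (|log2 FC| ≥ log2 1.5) at the 4 h timepoint, signed by direction.
Mouse symbols map to human by the case-insensitive same-symbol-name
rule unless an explicit homolog pair overrides it. The shared
universe is the intersection of expressed human genes (the pipeline's
proxy for "present on the human array") with the homolog-mapped mouse
panel; both lists are restricted to it before counting. Scores per
ligand:

* Representation Factor `RF = x/(n1·n2/N)` (0 when x = 0);
* hypergeometric tail `P(X ≥ x)` for `X ~ HG(N, n1, n2)`;
* sign concordance `P(K ≥ k | x, ½)`, one-sided binomial;
* optionally a joint resampling null: random directional gene sets of
  the signature's size drawn from the universe, with
  `p = (1 + #{x' ≥ x and k' ≥ k})/(n_resamples + 1)`. The joint
  statistic is used because overlap size and concordance carry
  complementary evidence; both component p-values are reported
  separately as well.

Ligands are ranked by hypergeometric p, then sign p, then RF
descending, then name; a ligand is declared significant when both
component p-values stay below 0.05 after Bonferroni correction across
the ligand panel. Gene collapsing from probes: a gene's direction is
that of its most significant probe, and genes whose significant
probes disagree in direction are dropped with a warning.

Gene-set enrichment is a hypergeometric over-representation test per
set with Bonferroni correction across tested sets; query, sets and
universe are intersected before testing and empty sets are skipped.

## Comparative Ct

`ΔCt = Ct_target − Ct_reference` per sample,
`ΔΔCt = ΔCt − ΔCt_calibrator`, relative quantity `2^(−ΔΔCt)`; the
calibrator's relative quantity is exactly 1 by construction.

## Synthetic studies

The generator plants the structure the analysis assumes and nothing
else:

* **Baselines.** Per-gene means drawn from a two-component log2
  mixture — "unexpressed" N(2.5, 0.5²) and "expressed" N(7, 1.5²) —
  reproducing the bimodal intensity histogram of whole-genome arrays.
  The mixture weight is solved in closed form so the expected fraction
  of genes clearing the threshold equals the target (default 0.33).
* **Cohort.** 9 controls and 17 patients share all baselines;
  i.i.d. gaussian noise, sd 0.4 log2 units, is added per measurement.
  Controls and non-subgroup patients are exchangeable by construction.
  The defaults for noise and effect size are calibration choices (the
  study design they emulate reports none): sd 0.4 is a typical
  residual spread for well-normalized arrays, and a ±1 log2 (2-fold)
  module shift is the canonical "clearly differential" magnitude.
* **Module.** 800 genes drawn from well-expressed baselines (at least
  0.5 log2 above threshold + effect, so the module survives filtering
  even when shifted down), each shifted ±1 log2 in the 5 subgroup
  patients only, direction Bernoulli(½) per gene.
* **Compendium.** 33 ligands on mouse-cased symbols at 4 h. The
  target ligand's signature contains exactly 112 module genes, of
  which round(112 · 101/112) = 101 carry the planted direction and
  the rest the opposite sign, plus 200 non-module genes; decoy
  signatures (80–400 genes) are uniform draws from the panel with
  random signs. All compendium fold changes exceed the 1.5-fold
  cutoff so planted counts are exact after signature building.
* An optional per-array additive shift (`array_effect_sd`) exercises
  quantile normalization; it is off by default because the analysis
  assumes normalized input.

Everything is driven by a single integer seed and is bit-reproducible.

**What the benchmark does not show.** The generator draws genes
independently apart from the planted module — no co-expression
blocks, probe-level effects, batch structure, or heavy-tailed noise —
and its subgroup is exactly exchangeable with the other patients
outside the module. Passing the recovery suite therefore
demonstrates that the statistics are implemented correctly and are
calibrated under their own assumptions, not that real cohorts will
yield subgroups this cleanly; on real arrays, correlated pathways and
array artifacts can both blur and fabricate cluster structure.

## Problem sizes used in the shipped checks

The automated checks run the full default study (20,000 genes, 26
samples) for subgroup recovery (50 studies), ligand recovery (50
studies) and module-gene power, and a reduced 2,000-gene panel for
the 20-run null-calibration sweep of the permutation FDR, with 200–300
sampled permutations per test — sizes at which every property of
interest is already stable.

## Known limitations

* The permutation FDR needs both groups ≥ 2; with 5-vs-9 contrasts the
  distinct-split space (2002) is small enough that results depend
  noticeably on `n_perm` below ~200.
* The subgroup detector returns at most one call; nested or multiple
  outlier groups are reported only through the best-scoring subtree.
* Symbol-based homology is deliberately naive; genes renamed between
  species silently drop out of the universe unless an explicit pair
  is supplied.
* GEO Series Matrix parsing covers the key-value + single-table
  dialect with one characteristics line defining the group; multi-
  channel series are not supported.
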