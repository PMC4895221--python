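# Methods

This note documents the statistical procedures implemented in neutronet,
the choices made where the conventions of the underlying study design were
open, and what the synthetic-data tests do and do not establish.

## Differential expression

Per feature, a two-sample t-test between two phenotypes. Welch's unequal
variance form is the default because the motivating designs have unequal
group sizes (e.g. 35 JIA vs 43 HC); a pooled-variance Student's t is
available via `flavor="pooled"`. Features with zero variance in both groups
are reported with t = 0, p = 1 rather than NaN. Group means are computed on
the log2 scale and carried into the signed linear fold change

    FC(a, b) = 2^(a−b)    if a ≥ b
             = −2^(b−a)   otherwise,

so |FC| ≥ 1 always and the sign encodes the direction; FC(x, x) = 1.
Swapping the groups flips the sign and preserves the magnitude.

### Rank-based FDR

The multiple-testing adjustment is the quotient

    fdr_i = p_i · N / R_i,

where N is the total number of tests in the family (an explicit argument —
it may exceed the length of the supplied list when only the significant
head of a family is adjusted) and R_i is the ascending rank of p_i, ties
broken stably by input order. This equals Benjamini–Hochberg step-up
*before* its cumulative-minimum monotonicity pass, and that pass is
deliberately **not** applied: the convention reproduces published
worked-example values that are non-monotone in p, which is impossible
under full BH. Consequences users should know: the reported fdr is not
monotone in p, and selecting `fdr ≤ q` is slightly more conservative than
BH for rows whose raw quotient overshoots a later minimum. The identity
`cummin(sorted fdr) = BH` is verified against statsmodels in the tests.

Selection presets follow the study conventions: genes at `p ≤ 0.001` and
`|FC| ≥ 1.5`; miRNAs at `fdr ≤ 0.1`.

### Clustering

Before clustering, each feature is normalized to its across-sample median —
implemented as subtraction, the natural reading for log2 data (a ratio mode
exists for linear-scale input). Samples are then clustered by average
linkage on Euclidean distances (scipy) and the tree is cut into k clusters.
Per-cluster majority accuracy is the modal-phenotype count over the cluster
size, the modal label resolved lexicographically on ties, reported both as
an exact proportion and a rounded whole percent (32 JIA + 13 HC → 71%).

## Splicing index and exon-level ANOVA

The gene-level signal is the unweighted mean of the gene's exon log2 values
per sample (the standard surrogate when probe-level summaries are not
available). The normalized intensity NI(e, s) = exon(e, s) − gene(g(e), s)
removes gene-level expression differences; the Splicing Index is the
difference of group-mean NI, computed group-mean-first (for balanced
log-scale data this coincides with per-sample-ratio-then-mean). The
exon-level test is a one-way ANOVA of NI across groups — the group-effect
test that the MiDAS program applies to gene-normalized exon signals —
reimplemented directly rather than wrapping vendor tooling, since only the
per-exon p-value is consumed. Selection keeps exons with `p ≤ 0.05` and
`|SI| ≥ 1.2`; the SI threshold is applied to the absolute value because
both inclusion directions are biologically meaningful. Exons of single-exon
genes have NI ≡ 0 by construction and are flagged, not errored. Selected
exons are also collapsed to a distinct-gene count.

## Three-level anti-correlation screen

The screen quantifies miRNA-mediated repression within one phenotype's
samples at three granularities. At the miRNA level, the point set pools
(miRNA value, target value) pairs over all of the miRNA's targets and all
samples — the anchor value is repeated once per member — and Pearson r and
Spearman ρ are computed on that pooled set (n = members × samples). This
pooling reading is what makes the tiny published miRNA-level cutoff
(−0.0075) sensible: pooled point sets have thousands of points. The gene
level pools symmetrically over all miRNAs targeting a gene; the pair level
is the plain per-pair correlation. Pooled Spearman ranks the pooled
coordinates globally with average ranks for the tied anchor repeats. For a
single-member set all three notions coincide. Degenerate (zero-variance)
point sets report 0 with a flag.

Internally every record reduces to a per-sample aggregate pair (fixed
vector, permutable vector) so that a permutation replicate is two inner
products per record; the bulk path is verified against explicit pooled
enumeration in the tests.

### Permutation p-values

Each replicate draws one random permutation of the phenotype's sample
order, shared by every record, and applies it to the miRNA matrix; the mRNA
matrix stays fixed, preserving its gene–gene covariance. (Permuting the
mRNA side instead is config-selectable.) All Pearson statistics are
recomputed and `perm_p` is the fraction of replicates at or beyond the
observed value in the requested tail (lower for anti-correlation). The
Pearson coefficient is the statistic that defines `perm_p`; Spearman is
recorded but not used for the p-value, keeping the selection rule
well-defined. No add-one correction is applied by default because the
selection rule `perm_p < 10⁻³` at 1,000 replicates deliberately demands
zero exceedances; a conservative `(k+1)/(n+1)` mode exists. Selection is
the conjunction `perm_p < p_max ∧ r ≤ r_max ∧ ρ ≤ rho_max` with the
published per-level bounds (−0.0075, −0.02, −0.3).

Cross-phenotype comparison of negative-correlation distributions pairs
records by entity, restricts to entities negative in at least one
phenotype, and applies the two-sided Wilcoxon signed-rank test, returning
the p-value, the sign of the median paired difference, and the pair count
(≥ 6 required; identical lists return the degenerate p = 1).

## RE-scores and the signature screen

Expression values are rank-ordered within each sample (ascending, average
ranks for ties); the RE-score of a gene set in a sample is the mean rank of
in-set genes minus the mean rank of the remaining genes, so a uniformly
random set scores 0 in expectation, positive scores mean
expressed-above-background, and the score is invariant to any strictly
monotone per-sample transform. The identity
`score = G/(G−k) · (mean_in − (G+1)/2)` is verified against brute force in
the tests. Sets are intersected with the matrix's features; empty or
all-gene intersections are errors naming the set.

The association screen correlates, across matched samples, the RE-score
vector of each miRNA's target set with that of each signature. The
permutation null shuffles the gene identity labels of the rank matrix once
per replicate — one shuffle shared by all sets, preserving inter-set
overlap structure — and recomputes both score matrices; `perm_p` counts
replicates with a larger correlation (for positive observed values) or a
smaller one (for negative). Selection applies `|r| ≥ 0.9` (on Pearson;
Spearman recorded) together with `perm_p < 10⁻³`, and returns per-miRNA and
per-signature tallies.

## Regulatory networks

Significant (miRNA, gene) pairs define a bipartite graph; PPI edges are
overlaid only between genes already present — the overlay illustrates
interactions among targets and never grows the node set. Direction-
consistent filtering keeps regulatory edges whose miRNA and gene are both
significant (raw p ≤ 0.05 — raw rather than adjusted, since the directional
filter is a secondary screen on an already-selected network) with opposite
signs in the requested mode; orphaned nodes are removed, and the output is
always a subgraph of the input. Hubs are the top ⌈5%⌉ of miRNA nodes by
degree, ties resolved by identifier so the hub list is deterministic.
Overlap significance is the exact hypergeometric upper tail P(X ≥ k); the
universe size is always an explicit argument because overlap p-values are
meaningless without naming the population. Exports: SIF
(`mirna  represses  gene` / `geneA  pp  geneB`, sorted; isolated nodes are
unrepresentable in SIF) and GraphML (carries node kind and direction).

## Synthetic-data generator

The generator emulates the three-phenotype design at configurable reduced
scale; the default `SimConfig` (1,000 genes, 40 miRNAs, 25 targets per
miRNA, groups JIA 12 / CF 8 / HC 14, 50 signatures of 30 genes, noise 0.5,
seed 0) keeps full-pipeline runs under a minute while preserving the
structural features each stage needs. Generation is a pure function of the
config including its seed.

Model: each feature draws a base level μ ~ N(8, 1.5) (log2 intensity
scale); mRNA and exon values add per-sample noise N(0, noise_sd), while
miRNA values add per-sample biological variation N(0, 1.5) — miRNAs must
vary across samples even in the noiseless-mRNA limit because they drive the
planted repression. Within the affected phenotype the generator plants:

* **DE** — signed shifts ±`de_log2_shift` on a fraction of genes and
  miRNAs (alternating sign);
* **repression** — for each regulated pair the target becomes
  μ_g − slope·(x_m − x̄_m) + noise, so the within-phenotype pair
  correlation is −slope·1.5/√(slope²·1.5² + noise_sd²), exactly −1 in the
  noiseless limit (regulated genes are kept distinct from DE genes, one
  regulating miRNA per gene);
* **splicing** — one exon per spliced gene offset by `si_magnitude`, so
  with E exons per gene the observable SI is attenuated to
  `si_magnitude·(1 − 1/E)`;
* **signature activity** — member genes of each active signature and the
  target genes of a designated miRNA (chosen among miRNAs without
  regulated pairs where possible) are shifted together in a random half of
  the phenotype's samples, giving both RE-score vectors a shared bimodal
  profile across samples and hence a strong positive correlation.

`null_dataset` runs the identical generator with every effect size forced
to zero and an empty truth record; under it the pair-level permutation
p-values are uniform (KS ≈ 0.02 at 2,000 records) and the gene preset
selects ≈ 0.1% of features.

What the generator does **not** model: probe effects, background and other
microarray noise structure, batch effects, correlated gene–gene baseline
covariance, realistic target-set overlap topology, and miRNA families with
shared seed sequences. Planted effects of different classes interact when
several are enabled at once (e.g. signature shifts add apparent DE);
recovery experiments therefore plant one effect class each, and passing
them shows the estimators recover their own generative model at the stated
signal-to-noise — not that real arrays behave this way.

## Problem sizes and test design

The recovery and calibration experiments use scaled problem sizes chosen to
exercise the full code paths at comfortable runtimes: 1,000 genes, 40
miRNAs, 20 seeds for recovery averages, 1,000 permutation replicates where
the `p < 10⁻³` rule requires them and 200 where only calibration is being
measured. Two recovery bars inherited from the study conditions are
reported honestly as failures by the acceptance tests: two-sided t-power at
p ≤ 0.001 with shift 1.0, noise 0.5 and groups 12/14 has a theoretical
ceiling of 88.7%, and the pair-level screen's zero-exceedance requirement
cannot reach 80% sensitivity at true r ≈ −0.6 with 14 samples (the observed
r must beat all 1,000 permutation draws, ≈ −0.81, which a true −0.6
correlation achieves only ~10–15% of the time). The same screen recovers
≥ 98% of pairs at the generator's default coupling (true r ≈ −0.95), which
is the regime the screen's published cutoffs imply.

## Numerical conventions

Tie-breaks: p-value ranks are stable by input order; cluster modal labels
and hub orderings are lexicographic. Degenerate inputs: zero-variance
features (t = 0, p = 1), degenerate correlations (0 with a flag, perm_p
naturally 1), zero-residual ANOVA (p = 1 with a warning), all-zero paired
differences (p = 1). Identifiers are opaque case-sensitive strings; target
genes absent from the expression matrix are dropped at analysis time with a
logged count, never at read time. Matrix round-trips write full-precision
`repr` floats so read(write(m)) is exact.
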