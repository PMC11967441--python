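# Methods

`earphase` implements a comparative-transcriptome candidate-gene analysis for
a quantitative trait: two inbred maize lines with contrasting kernel row
number (KRN) are profiled by bulk RNA-seq across five early ear developmental
stages (V6–V10, three biological replicates each, thirty libraries), genes
differentially expressed between the lines are clustered over developmental
time, the stages are partitioned into two regimes, and the early-phase
line-specific DEGs are intersected with compiled QTL and QTN evidence to call
high-probability candidate genes.

## Count model and differential expression

Fragment counts are modelled as negative binomial,

    K_gj ~ NB(mean = s_j · μ_g(group_j),  dispersion α_g),
    Var(K) = μ + α μ²,

with per-library size factors `s_j` from the median-of-ratios estimator
(reference genes = genes with strictly positive counts in all libraries;
`s_j = median_g counts_gj / geomean_g`).

**Dispersion.** Per-gene dispersions come from a method-of-moments estimator
on normalised counts, `α̂_g = (s² − m̄)/m̄²`, with `s²` the within-group
sample variance and `m̄` the mean normalised count. At three replicates per
group this raw estimator is far too noisy for a calibrated Wald test:
because the Wald statistic scales roughly as `1/√α`, a downward error in
`α̂` inflates the statistic much more than an upward error deflates it, and
the raw estimator produces a null rejection rate of about 0.10 at nominal
0.05. The default moderation (`shrinkage = 0.2`) therefore (i) computes a
central value as the 20% trimmed mean of log dispersions over genes whose
raw estimate is positive, (ii) shrinks each positive log estimate toward
that center, (iii) never lets a moderated estimate fall below the center,
and (iv) assigns the center to genes whose raw estimate is non-positive
(data indistinguishable from Poisson at this replication, which is mostly
sampling noise). With `shrinkage = 0` the raw floored estimator
(`α_floor = 1e-8`) is returned unchanged. The moderated test's null
rejection rate is 0.04–0.06 across seeds and its power for a planted
two-fold change at mean 200 and α = 0.05 with n = 3 per group is ≈ 0.97.
The center is a scalar, not a mean-dispersion trend; at this design size a
trend fit would be estimated from the same four degrees of freedom per gene
and adds little.

**Wald test.** For each tested gene the two group means are fitted by
Newton iteration on the exact NB log-likelihood with the dispersion held
fixed, size factors entering as offsets. A pseudo-mean of 0.5 normalised
counts is added to both fitted means before forming the fold change, so
all-zero groups stay finite. The statistic is
`z = log(μ̂_B + ε) − log(μ̂_A + ε)` over its standard error from the
expected Fisher information `I = Σ_j m_j/(1 + α m_j)` per group, with a
two-sided normal p-value. Genes with total normalised count below
`min_count = 10` are not tested and are excluded from the
Benjamini–Hochberg correction (which is delegated to statsmodels). The
contrast direction is second group level over the first, by order of
appearance in the sample sheet.

**DEG call.** A gene is differentially expressed iff `|log2FC| ≥ 1`
(fold change ≥ 2, inclusive) and `padj < 0.05` (strict). Line-specific DEGs
come from the between-line contrast at each stage; development-specific DEGs
from contrasts of consecutive stages within one line. Stage-wise Venn
regions assign each gene of the union to exactly one membership signature.

## FPKM, QC and replicate exclusion

FPKM is `counts · 10⁹ / (L_g · N_j)` with `L_g` the exonic length from the
annotation and `N_j` the per-library total of assigned fragments (column
sum); mapping-based totals are not available to a count-matrix consumer and
the difference is a per-library constant that cancels in correlation, PCA
and fold changes. Stage expression is the mean FPKM over surviving
replicates. Abundance bins are left-closed: not expressed < 1, low [1, 10),
moderate [10, 100), high ≥ 100.

Sample QC computes pairwise correlations on `log2(x+1)` FPKM (Pearson for
the global heat map, Spearman for the replicate check) and sample PCA on
centred `log2(x+1)` values of genes expressed in at least one sample. A
replicate is excluded when even its **best** same-group sibling correlation
falls below 0.95 (Spearman): requiring agreement with at least one sibling
means a single corrupted replicate is flagged alone rather than dragging its
two healthy siblings below a mean-based threshold. Groups of one are never
flagged and a non-positive threshold disables the check. The 2^-ΔΔCt
utility implements relative qPCR expression against a reference gene and a
calibrator sample.

## Trajectory clustering and the phase split

Per-line stage profiles of the line-specific DEG union (log2 of stage-mean
FPKM + 1) are z-scored per gene (population SD; constant rows are masked)
and clustered by fuzzy c-means: centroids `v_k = Σ u_ik^m x_i / Σ u_ik^m`,
memberships `u_ik = 1/Σ_j (d_ik/d_ij)^{2/(m−1)}` with Euclidean distance,
iterated until `max|Δu| < 1e-6` or 1,000 iterations. Defaults are c = 4
(the four temporal archetypes observed in ear development: rise-to-V8,
late spike at V10, spike at V9, monotone decline), fuzzifier m = 2, ten
Dirichlet-initialised restarts keeping the best objective, all reproducible
from one integer seed. A point coincident with a centroid takes full
membership there.

The two-phase partition makes the usual visual judgement explicit: every
contiguous split of the ordered stages is scored as mean between-phase over
pooled mean within-phase pairwise distance of the per-stage profile vectors,
the maximising split wins, and ties break toward the earlier split. On data
shaped like real ear development this selects Phase I = V6–V8,
Phase II = V9–V10; an explicit override (`phase: "V6,V7,V8|V9,V10"`) is
available in the pipeline config.

## Genetic-architecture integration

All coordinates are 1-based inclusive. Compiled QTL intervals are validated
(swapped ends normalised, duplicates collapsed, unknown chromosomes
rejected) and merged per chromosome by single linkage, where overlap means
≥ 1 shared basepair — abutment (`start = end + 1`) does not merge. A merged
cluster is a **hotspot** iff it contains ≥ 2 member QTLs from ≥ 2 distinct
studies (the study requirement is a toggle; repeated detection within one
study is weaker evidence than cross-study replication). Each QTN gets a
±100 kb flanking window clamped to the chromosome; windows are never merged
so per-QTN evidence stays attributable. A gene overlaps a region when they
share ≥ 1 bp.

Candidates among the Phase-I line-specific DEG union: tier 1 = the gene
lies in ≥ 1 hotspot or ≥ 1 QTN window (a set union, each gene counted
once); **common region** = the gene lies in a hotspot that itself contains
a QTN whose window also covers the gene. The same-hotspot binding is the
strictest reading of "within QTLs where QTNs also exist"; an `any_hotspot`
mode relaxes it. TF families are joined from a user-supplied table and
tallied per family and, when directions are given, per stage and direction.

## Synthetic data and what it does (not) show

The generator reproduces the study design with ground truth: NB counts for
2 lines × 5 stages × 3 replicates, a configurable DE fraction (default
0.15) with planted `|log2FC| = 1 + Exponential(0.7)`, log-normal
dispersions (median 0.05, log-SD 0.5), log-normal base means (median 50,
log-SD 1.5), library totals scaled into 1–2 M fragments, four temporal
archetypes whose regime changes between stages 3 and 4, non-overlapping
gene spans (log-normal lengths around 3 kb) on ten 20 Mb chromosomes, and
QTL/QTN maps in which each planted hotspot is realised by `support` QTLs
from distinct studies covering the planted span while background QTLs are
placed pairwise disjoint. One integer seed drives named substreams per
component, so counts, annotation and maps regenerate independently and
byte-identically.

These choices are plausible for maize ear RNA-seq but not matched to any
particular dataset (the study supplies no library-size or dispersion
characteristics). Passing the planted-structure and calibration checks
therefore demonstrates correctness of the estimators under the stated
model — NB counts, archetypal trajectories, clean interval geometry — not
robustness to batch effects, outlier genes, shared-count correlation or
reference-annotation error, none of which the generator emulates.

## Numerical choices and limitations

- Newton iterations for the NB mean are clipped to one decade per step and
  fall back to the normalised-count mean on non-convergence; all-zero
  groups return a zero mean and rely on the pseudo-mean guard.
- Fuzzy c-means records its objective after every iteration; the trace is
  non-increasing by construction of the alternating updates.
- Venn partitions are limited to six sets (the pipeline uses five stages).
- Problem sizes in the verification suite — 2,000-gene null panels,
  300-gene power panels over 200 seeds, 500 random interval instances on
  100 kb chromosomes, 20-seed round trips — were chosen so each check is
  statistically informative while the whole suite runs in well under a
  minute per component.
- Multi-factor designs, shrunken fold-change estimators, Cook's-distance
  outlier handling, GO enrichment and marker anchoring across genome builds
  are out of scope; the pipeline consumes coordinates already on one build.
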