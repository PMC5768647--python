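# Methods

This note documents the statistical models implemented in ndseq, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical and design decisions that were
genuinely open.

## Preprocessing

**Biotype filter.** The default allow-list is the thirteen polyadenylated
biotypes relevant to poly-A-selected libraries (protein_coding, lincRNA,
processed_transcript, sense_intronic, sense_overlapping and the IG/TR
V/D/J/C gene segments). Both the Ensembl spelling `sense_overlapping` and
the historical variant `sense_overlaping` are accepted, since annotation
tables in the wild carry either. Matching is exact string membership;
genes absent from the annotation are an error rather than silently kept
or dropped.

**Zero-count filter.** A gene is removed when *more than half* (strictly)
of the pooled-disease samples, or more than half of the control samples,
have zero counts. The pooled-disease group (HD ∪ PD) defines one shared
gene universe used by all three contrasts, including the single-disease
ones; this keeps the HD, PD and ND DE lists directly comparable (the
alternative — a per-contrast universe — would make the rank-aggregation
and partition steps ill-defined).

**Normalization.** Median-of-ratios size factors: the reference set is
the genes with strictly positive counts in every sample; geometric means
are computed in log space; the per-sample factor is exp of the median log
ratio. This is the standard bulk RNA-seq convention, and the
implementation is cross-checked in the test suite against DESeq2's
`estimateSizeFactorsForMatrix` on a random matrix. Note that with an even
number of reference genes the log-space median is the geometric mean of
the two central ratios, so the "median normalized ratio = 1" identity is
exact only for odd reference counts.

**Outlier trimming.** The upstream literature this pipeline follows
delegates its trimming procedure to prior work without formulas, so the
procedure here is a documented stand-in chosen for determinism and scale
robustness: per gene and per condition group, values whose robust z-score
|x − median| / (1.4826·MAD) exceeds `z_max` (default 3) are winsorized to
the boundary median ± z_max·1.4826·MAD. Groups with fewer than three
samples are skipped with a warning; zero-MAD (near-constant) genes are
left untouched. Winsorization never moves the group median and never
widens the group range, and it adjusts values, not samples, so the cohort
size entering the regression is unchanged. Trimming is configurable and
can be disabled (`z_max=None` / `trim_z: null`).

## Firth logistic differential expression

Each gene is fit separately: y_i ∈ {0,1} is disease status, the predictor
is the gene's winsorized normalized abundance standardized to mean 0 and
sample SD 1 (denominator n−1), plus optional covariates (continuous ones
standardized the same way, categorical ones dummy-coded against the first
level). The penalized log-likelihood is

  l*(β) = l(β) + ½·log det I(β),  I(β) = X'WX, W = diag(p(1−p)),

maximized by Newton–Raphson on the Firth-modified score
U*(β) = X'(y − p + h(½ − p)), h the hat-matrix diagonal, with
step-halving whenever a full step would decrease l*. Convergence is
declared when the score sup-norm falls below 1e−6 (at most 50
iterations); iteration then continues briefly (to a 1e−10 sup-norm or a
stall) purely to polish the coefficients, so that the estimate itself is
accurate to well below the convergence tolerance. For a single binary
covariate this estimator provably equals the add-½ cell-corrected 2×2
log odds ratio, which the tests exploit as an independent oracle,
including under complete separation (where classical ML diverges and the
Firth estimate is finite — the reason this model family is usable for DE
at all).

**Test statistic.** P-values come from the penalized likelihood-ratio
test: the restricted model holds the count coefficient at zero *while
keeping the full design's information matrix in the penalty*, i.e. the
profile of the same penalized likelihood, and 2(l*_full − l*_restricted)
is referred to χ²(1). This profile form matters: penalizing the
restricted model with its own lower-dimensional information matrix
changes the penalty by ≈ ½·log Σwx² and grossly inflates the statistic
(empirically ~34% rejections at the nominal 5% level under the null,
versus ~4–5% for the profile form). A Wald variant is available behind
`method="wald"`. When no covariates are present the restricted problem is
identical for every gene (constant weights at its optimum plus a
standardized count column), so it is solved once per contrast; with
covariates it is solved per gene.

The reported LOR is the count-column coefficient: log-odds change per 1
SD of abundance, positive = more abundant in cases. BH adjustment runs
over the genes whose fit converged (failed fits get missing p/q and do
not deflate the denominator); DE is called at q < 0.01. The default
covariate set is empty — the source study names candidates (RIN, PMI,
age) without fixing a final design, so covariates are a configuration
choice; the simulator generates them effect-free so the design-matrix
path is exercised without contaminating the planted truth.

**Batch diagnostic.** Rather than modelling batch, the pipeline reports
the Spearman correlation of per-gene LORs between model families with and
without a categorical batch covariate. On simulated cohorts with no
planted batch effect this concordance is ≈ 0.99; a batch factor that
exactly reproduces the case/control split is rejected as confounded.

## Preranked GSEA

The ranking is every tested gene ordered by descending standardized LOR
(ties by gene id). For a set S of size m in a universe of N, walking the
ranked list accumulates |score|^p / Σ_S |score|^p at members and
−1/(N−m) at non-members; the ES is the signed maximum deviation. The
default weight is p = 1 (p = 0 gives the unweighted statistic). The
running sum is piecewise linear between member positions, so only the
values immediately after each hit (candidate maxima) and immediately
before (candidate minima) are evaluated; an exact tie between the
positive and negative extreme resolves positive, with a 1e−9 tolerance so
the choice is stable under float noise.

Because the ranked list is fixed, the permutation null is gene sampling:
`n_perm` (default 1000) random same-size draws from the universe, shared
across all sets of equal size and drawn in sorted size order so results
do not depend on collection ordering. NES = ES / mean(|null ES| of
matching sign); the nominal p is the same-sign exceedance fraction with a
+1 pseudocount (so p ∈ (0,1], and the attainable floor is ≈ 2/n_perm —
raise `n_perm` if collections are small and this floor binds). FDR is BH
across the collection rather than the original GSEA permutation FDR,
keeping the q-value convention uniform across the whole pipeline; q-values
from tools implementing the original FDR will differ in detail. Sets
overlapping the universe in fewer than `min_size` genes (default 5) are
skipped with a log entry.

## Robust rank aggregation

Inputs are the three contrast lists ordered by significance: ascending
raw p, ties by descending |LOR|, then gene id. (Raw rather than
BH-adjusted p, since step-up adjustment creates plateaus of tied q-values
that would coarsen ranks; the aggregate is rank-based, so any monotone
transform of p gives the same answer.) For gene g with normalized ranks
r_i = position_i / N and order statistics r_(1) ≤ … ≤ r_(n),

  β_k = P(Bin(n, r_(k)) ≥ k),  ρ = min_k β_k,  score = min(1, n·ρ).

Binomial tails are exact (scipy survival function) — with n = 3 lists a
normal approximation has nothing to offer. The min over k is
Bonferroni-corrected by n only; the refinement of the exact null of the
minimum (as in the original algorithm's significance scores) is not
reproduced, making the score conservative: under independent uniform
lists the corrected score is stochastically ≥ Uniform(0,1), which the
tests verify (≈0.7% of genes below 0.01 under the null). Consensus genes
are called at score < 0.01.

## Disease comparison

DE partitions are plain set algebra (HD\PD, PD\HD, HD∩PD) over the
shared gene universe of all genes passing preprocessing — the tested
universe, not the genome, which is the correct background for the
hypergeometric test. Each partition × collection block is BH-adjusted
separately. Enriched sets are grouped when their DE-gene sharing fraction
strictly exceeds 20%; the fraction is the overlap coefficient
|A∩B| / min(|A|,|B|) by default (a small set nested in a large one should
group), with Jaccard available. Groups are connected components, so
chains group transitively. Direction concordance examines every set
significant (q < 0.05) in ≥ 2 GSEA contrasts and asks whether all its
significant NES signs agree; the per-subset significance counts behind a
Venn diagram are reported alongside.

## Synthetic cohorts

`simulate_dataset` draws negative-binomial counts with variance
μ + α·μ² (α = 0.1 by default) around per-gene baseline means drawn
log-uniformly from 20–2000, scaled by per-sample size factors from
0.7–1.4. Planted effects act multiplicatively on the mean as 2^lfc with a
fixed magnitude (default |log2FC| = 1) and random sign; genes are
labelled `shared` (same signed effect in both diseases, default 10%),
`d1_only` / `d2_only` (5% each) or `null`. Default group sizes are
29/29/49 with five sequencing batches (batch effect zero by default, so
the batch diagnostic has a clean reference), and the default gene count
is 1000 — large enough for stable BH behaviour and gene-set universes,
small enough that the full study runs in seconds. Covariates
(age-at-death, PMI, RIN) are Gaussian with cohort-like per-condition
means but no influence on counts. One RNG stream per dataset is keyed by
the seed and split into independent sub-streams (structure, counts,
covariates), so identical configs reproduce bit-for-bit.

`simulate_genesets` plants enrichment: each enriched set draws a fraction
`purity` (default 0.9) of its members from genes of one truth label with
one effect sign — capped by the pool size, so high purity needs
label fractions large enough to supply it — and the rest uniformly;
background sets sample the universe uniformly.

What the simulation does *not* emulate: real expression distributions
(no empirical baseline-mean or dispersion spectrum), gene–gene
correlation, library-composition artifacts, covariate–expression
coupling, or batch structure beyond a symmetric log-shift. Passing
recovery tests therefore demonstrate correctness of the machinery under
the stated model, not performance on real brain cohorts; calibration
results in particular assume independent genes.

## Reproducibility and problem sizes

The pipeline fans a single global seed into fixed per-stage sub-seeds, so
stages run individually or via `all` produce byte-identical tables
(floats are written with 10 significant digits). The acceptance script
re-measures, per run: the Firth/add-½ oracle gap over 200 random 2×2
tables, null calibration on a 200-gene × 80-sample all-null cohort,
recall/FDR on the default 1000-gene cohort, RRA null calibration over
2000 genes × 3 shuffled lists, GSEA/partition/concordance recovery on the
default study, and rerun byte-identity. These sizes were chosen as the
smallest at which the Monte-Carlo tolerances in the tests are meaningful.

## Known limitations

- The outlier-trimming rule is a stand-in (see above), not a reproduction
  of the historical procedure.
- GSEA q-values are BH over permutation p-values; they will not match
  implementations using the original GSEA FDR to the decimal.
- The RRA score uses the Bonferroni bound only and is conservative.
- Firth fits are per gene; multi-gene designs and negative-binomial
  count models are out of scope by design.
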