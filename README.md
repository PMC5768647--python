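# ndseq

Comparative case/control differential-expression analysis for bulk brain
mRNA-Seq, built around the design of a two-disease study: two
neurodegenerative-disease cohorts (Huntington's and Parkinson's disease
prefrontal cortex, 29 + 29 samples) compared against a shared pool of 49
controls, both separately and pooled as a single neurodegeneration (ND)
group. The package is aimed at analysts who start from a gene × sample
count matrix and want the full downstream chain — filtering,
normalization, per-gene inference, gene-set enrichment, cross-list
consensus, and disease comparison — as tested, reusable, seeded code.
A synthetic-cohort generator with planted ground truth drives every test.

## The analysis

1. **Preprocessing.** Genes are restricted to polyadenylated biotypes
   (protein_coding, lincRNA, …), genes with zero counts in more than half
   of the pooled-disease or control samples are dropped, counts are
   normalized by median-of-ratios size factors
   (s_j = median_g k_gj / (∏_j' k_gj')^(1/m) over all-positive genes),
   and extreme values are winsorized per gene within each condition group
   at robust z = |x − median| / (1.4826·MAD) > 3.

2. **Firth logistic differential expression.** For each gene, disease
   status is regressed on the standardized normalized abundance
   (optionally plus covariates such as RIN, PMI, age):
   maximize l*(β) = l(β) + ½·log det I(β). The Jeffreys-prior penalty
   keeps the estimate finite under complete separation, the failure mode
   of classical logistic regression on strongly differential genes. The
   per-gene statistic is the standardized log odds ratio (LOR): log-odds
   change per 1 SD of abundance, positive = more abundant in disease.
   P-values come from the penalized likelihood-ratio test (the restricted
   fit pins the count coefficient at zero while keeping the full
   information matrix); Benjamini–Hochberg q < 0.01 calls a gene DE.
   A Spearman concordance diagnostic compares LORs from models with and
   without a batch covariate.

3. **Preranked GSEA.** Each contrast's complete gene list, ranked by
   standardized LOR, is scored against a gene-set collection with the
   weighted running-sum enrichment score; significance comes from a
   gene-sampling permutation null (NES = ES / mean |null ES| of matching
   sign), BH-adjusted at q < 0.05.

4. **Robust rank aggregation.** The three contrast lists (ordered by
   significance) are aggregated per gene via binomial order statistics of
   the normalized ranks: ρ = min_k P(Bin(n, r_(k)) ≥ k), corrected score
   = min(1, n·ρ), consensus genes called at score < 0.01.

5. **Disease comparison.** The HD and PD DE lists are partitioned into
   disease-unique and common sets; each partition is tested for gene-set
   over-representation (upper-tail hypergeometric, BH within each
   collection); enriched sets sharing > 20% of their DE genes (overlap
   coefficient) are grouped by connected components; and sets significant
   in more than one GSEA contrast are checked for direction concordance.

## Worked example

Run the full synthetic study (the numbered scripts under `analysis/`
chain the same stages one at a time):

```sh
python analysis/01_simulate_cohort.py --outdir results/study --seed 7
python analysis/02_preprocess.py      --outdir results/study --seed 7
python analysis/03_differential_expression.py --outdir results/study --seed 7
python analysis/04_geneset_enrichment.py      --outdir results/study --seed 7
python analysis/05_rank_aggregation.py        --outdir results/study --seed 7
python analysis/06_disease_comparison.py      --outdir results/study --seed 7
```

The DE step prints, for the default cohort (1000 genes, 29/29/49 samples,
10% shared effects and 5% per-disease effects at |log2FC| = 1):

```
HD_vs_C: 150 DE genes at q<0.01; shared-gene recall 1.00; null fraction among calls 0.000
PD_vs_C: 151 DE genes at q<0.01; shared-gene recall 1.00; null fraction among calls 0.000
ND_vs_C: 187 DE genes at q<0.01; shared-gene recall 1.00; null fraction among calls 0.000
HD_vs_C: batch concordance Spearman rho = 0.997
PD_vs_C: batch concordance Spearman rho = 0.991
ND_vs_C: batch concordance Spearman rho = 0.996
```

i.e. essentially all planted shared-effect genes are recovered in every
contrast at q < 0.01, almost no planted nulls are called, and omitting
the (effect-free) batch covariate leaves the per-gene coefficients in
near-perfect rank agreement. The comparison step then reports that every
gene set significant in two or more contrasts is enriched in the same
direction, and that planted disease-unique sets enrich only their own DE
partition.

The same pipeline is available as a CLI over a YAML config
(`ndseq all --config config.yaml`, or per-stage subcommands
`simulate | preprocess | de | gsea | rra | compare`), and programmatically
via `ndseq.pipeline.run_pipeline`. Point the config at your own
counts/metadata/annotation TSVs and GMT collections to run in ingest mode
instead of simulation.

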