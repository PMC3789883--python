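# pathbvs

Integrated Bayesian enrichment analysis of variants and pathways for
case-control GWAS.

Standard pathway analyses tell you *whether* a gene set is enriched for
disease associations, but not *which* variants inside it drive the
enrichment, and they give no principled way to relax significance
thresholds for variants in an enriched set. `pathbvs` treats enrichment
as a parameter of a multi-marker disease model, so a single fit yields
both a Bayes factor for each candidate pathway and
enrichment-informed posterior inclusion probabilities (PIPs) that
promote variants inside enriched pathways. It is aimed at statistical
geneticists working with genotype dosage matrices, gene coordinates
(BED) and gene sets (GMT).

## Model

Disease status follows an additive log-odds model over p SNP dosages,

    log-odds(y_i = 1) = kappa + sum_j x_ij beta_j,

with a spike-and-slab prior on the coefficients:
beta_j is zero with probability 1 − pi_j and N(0, sigma_a²) otherwise
(default sigma_a = 0.1, placing 95% of odds ratios a priori in
0.82–1.22). A two-level prior couples inclusion to pathway membership
a_j ∈ {0, 1}:

    pi_j = sigmoid( log(10) · (theta0 + theta · a_j) ),

where theta0 is the genome-wide log10-odds that an arbitrary SNP enters
the model and theta is the log10-fold enrichment for annotated SNPs —
e.g. theta0 = −4, theta = 2 means 1 in 10,000 background SNPs but 1 in
100 pathway SNPs are included a priori. Both hyperparameters carry
uniform priors on discrete grids (theta0 ∈ [−6, −2], theta ∈ [0, 5],
spacing 0.1). The evidence for enrichment of an annotation a is

    BF(a) = p(y | X, a, theta > 0 allowed) / p(y | X, theta = 0),

with each marginal likelihood averaged over its grid. Posteriors are
approximated by a fully factorized variational family; the logistic
likelihood is handled by a per-observation quadratic (tangent) bound
with the flat-prior intercept integrated out analytically, and
coordinate ascent makes the lower bound monotone. PIPs, 50-SNP segment
statistics P(E ≥ n), and effect-size summaries are averaged over the
hyperparameter posterior, and optionally across enrichment models
weighted by their BFs. A two-stage fit and conditional Bayes factors
handle a dominant region such as the MHC.

## Worked example

`examples/02_enrichment_scan.py` simulates 800 individuals at 500 SNPs
with one truly enriched 80-SNP pathway (theta0 = −2.3, theta = 2) and
scores it against a decoy:

```
  true_pathway: log10 BF =   9.76   theta = 2.78 [2.2, 3.0]   P(enriched | 1:100 prior) = 1.000
 decoy_pathway: log10 BF =  -0.32   theta = 0.70 [0.0, 1.5]   P(enriched | 1:100 prior) = 0.005
```

The true pathway earns decisive evidence (BF ≈ 10^9.8) with the
log-fold enrichment estimated near its generative value, while the
decoy sits at BF ≈ 1. `examples/03_prioritize_variants.py` then shows
the promotion effect on the same data: the mean PIP of causal pathway
SNPs rises from 0.18 under the no-enrichment null to 0.87 under the
enriched model, while PIPs of null SNPs outside the pathway do not
rise (0.0094 → 0.0075).

The other examples cover data generation and QC
(`01_simulate_and_qc.py`) and MHC-style conditional analyses plus the
greedy pathway-combination search
(`04_conditional_and_combinations.py`). The same workflow is available
from the shell via the `pathbvs` command
(`simulate | qc | annotate | scan-null | enrich | condition | combine |
prioritize`), each subcommand writing TSV outputs and a JSON run
manifest.

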