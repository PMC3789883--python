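# Methods

## Model

Case-control status is modelled prospectively by logistic regression on
all p SNP dosages jointly,

    p(y_i = 1 | x_i) = sigmoid(kappa + x_i' beta),

with an improper flat prior on the intercept kappa and independent
spike-and-slab priors on the coefficients:

    beta_j ~ (1 - pi_j) delta_0 + pi_j N(0, sigma_a^2).

`sigma_a` is fixed rather than estimated: heterogeneous odds ratios
drag an estimated slab width toward the few largest effects, leaving
too little mass on the modest odds ratios that carry enrichment signal.
The default 0.1 puts 95% of odds ratios a priori in (0.82, 1.22).

Pathway enrichment enters through the prior inclusion probability.
With a_j = 1 marking SNPs assigned to the candidate pathway (within
100 kb of the transcribed region of a member gene, boundaries
inclusive),

    pi_j = sigmoid( ln(10) * (theta0 + theta * a_j) ),

where theta0 is the genome-wide log10-odds of inclusion and theta >= 0
the log10-fold enrichment. Negative theta (depletion) is not modelled:
with few real associations genome-wide, depleted pathways are neither
detectable nor interpretable. Both hyperparameters carry uniform priors
on discrete grids, by default theta0 in [-6, -2] and theta in [0, 5] at
spacing 0.1. The theta0 range is anchored at the high end by its
a-priori consequence — about 4,400 expected inclusions among 440,000
SNPs — and the theta range accommodates enrichments beyond
10,000-fold; both are configurable because the model is also used at
other scales.

The Bayes factor for enrichment of annotation a is the ratio of
marginal likelihoods of the enriched model (theta averaged over its
grid) and the null (theta = 0), each averaged over theta0 with uniform
weights and evaluated in log space by log-sum-exp. Posterior
probabilities of enrichment multiply the BF by prior odds chosen by the
analyst (1 / number-of-candidates is a conservative default).

## Variational approximation

The posterior over (beta, inclusion) at one grid point is approximated
by a fully factorized family: each SNP's factor is spike-and-slab with
free parameters (alpha_j, mu_j, s2_j) — the approximate posterior
inclusion probability and the conditional mean and variance of the
effect given inclusion. For the logistic likelihood every
observation's log-likelihood is bounded below by a quadratic in
z_i = kappa + x_i' beta, the tangent bound at a free parameter eta_i:

    log p(y_i | z_i) >= (y_i - 1/2) z_i - d_i z_i^2 / 2
                        + log sigmoid(eta_i) - eta_i/2 + d_i eta_i^2/2,
    d_i = (sigmoid(eta_i) - 1/2) / eta_i.

Under the bound the likelihood is Gaussian in (kappa, beta), so the
flat-prior intercept integrates out analytically; this is equivalent to
working with d-weighted centered responses and designs, and it
contributes the exact same flat-prior constant to every model, so
differences of bounds (hence BFs) are well defined.

Coordinate ascent visits SNPs in ascending index order (deterministic,
reproducible). The closed-form updates are

    s2_j   = sigma_a^2 / (sigma_a^2 * xdx_j + 1)
    mu_j   = s2_j * (residual correlation of SNP j under the bound)
    logit alpha_j = logit pi_j + [log(s2_j / sigma_a^2) + mu_j^2/s2_j]/2,

where xdx_j is the d-weighted centered second moment of dosage j, and
after each full sweep the bound parameters are re-tightened in closed
form, eta_i^2 = E_q[z_i^2]. Every step increases the lower bound on the
log marginal likelihood; the bound trace is recorded and asserted
non-decreasing (slack 1e-8) in the tests. Convergence requires both the
absolute bound change below `convergence_tol` (default 1e-4) and the
largest alpha change below 1e-4; non-converged states are flagged and
propagate a warning rather than an error. A NaN bound is a hard error.
Initialization is alpha = pi, mu = 0, s2 = sigma_a^2, eta = 1; grid
scans warm-start each fit from the neighbouring grid point (theta0
ascending for the null, theta ascending within each theta0 for the
enriched model). Warm and cold starts agree to ~1e-3 in the bound on
test problems.

A linear-regression mode (Gaussian likelihood, fixed residual variance,
same centering and updates) exists because it admits exact small-p
oracles: the marginal likelihood and PIPs can be enumerated over all
2^p models with closed-form Gaussian marginals. The tests verify that
the bound never exceeds the exact log marginal and that alphas track
exact PIPs within 0.05 on orthogonalized designs.

## Efficiency approximations for pathway scans

Scoring thousands of pathways would be intractable if every grid cell
refit all p SNPs. Two approximations, both on by default for enriched
fits and both yielding valid lower bounds:

- **Fixed outside the pathway.** The enriched fit at (theta0, theta)
  updates only the factors of annotated SNPs; all other factors stay at
  the null solution for the same theta0 (their priors are identical in
  both models, so their contributions are consistent). The theta = 0
  cell coincides with the null model exactly and reuses its state.
- **Frozen bound parameters.** The eta stay at the null solution's
  values during fixed-outside fits. Any eta gives a valid bound; not
  re-tightening it makes enriched-model bounds slightly conservative
  but leaves pathway rankings intact (the same handicap applies to
  every candidate), and it reduces per-cell cost from O(n p) to
  O(n p_pathway). An exact refit (`fixed_outside=False`, or
  `update_eta=True`) is available for small problems; on the test
  problems the exact and approximate BFs agree to a fraction of a
  log10 unit.

## Dominant regions (MHC-style analyses)

When one region carries very large effects, jointly modelling it can
mask associations elsewhere (conditioning on large non-confounding
covariates loses power in a prospective model of case-control data).
The two-stage fit therefore (1) fits all SNPs outside the region with
the region's factors pinned to exclusion — provably identical to
dropping the region's columns — and (2) fits the region's SNPs holding
the outside fixed. Conditional enrichment analyses fix the region's
enrichment at its MAP grid value (ties toward smaller theta) and score
candidates against the null that only the region is enriched; candidate
SNPs inside the region keep the region's enrichment level and are
excluded from the candidate's free set. A candidate entirely inside
the region is an error, not a BF of 1.

## Prioritization statistics

PIPs average alpha over the grid with the hyperparameter posterior
weights (softmax of the bounds times the uniform prior), and across
multiple enrichment models with BF-proportional weights computed in log
space. Segment statistics use overlapping 50-SNP windows with 25-SNP
overlap (equal SNP counts make the null prior probability of a hit
equal across segments); the final window per chromosome is anchored at
the chromosome end so every SNP is covered, and chromosomes shorter
than one window become a single segment. P(E >= n) treats the
inclusion indicators as independent — exact under the factorized
family, an approximation to the true posterior — and is computed by a
Poisson-binomial dynamic program, averaged over grid cells at the
probability level (the same convex averaging as the PIPs). Effect
sizes given inclusion are summarized by the weight-alpha mixture of
per-cell conditional normals; the smallest 95% interval is found by
bisection on the mixture CDF (tolerance 1e-6) with a refined search
over the tail mass. Credible intervals for theta0 and theta are the
smallest contiguous grid intervals about the posterior mean holding
95% mass, endpoints reported to the nearest 0.1.

## Single-SNP Bayes factors and QC

The single-SNP BF compares {intercept + one SNP, effect ~ N(0,
sigma^2)} to {intercept only}: the effect is integrated by adaptive
quadrature over +/-8 prior sds (absolute tolerance 1e-8) with the
intercept profiled out by a Laplace approximation at each node. It
backs the neighbourhood-support QC flag: a SNP whose single-SNP BF
exceeds 1e4 while no neighbour within 200 kb reaches 1% of that
threshold is flagged as a likely genotyping artifact. Real
associations in LD are echoed by neighbours; artifacts are not. The
flag is advisory — the underlying judgment is partly visual in
practice, so any fixed rule is a formalization and removal stays an
explicit analyst decision. Monomorphic SNPs (zero dosage variance) are
removed outright. Both filters are idempotent.

## Synthetic data

The generator produces exactly the structure the model assumes, so
recovery tests are well-posed. Haplotypes follow a first-order Markov
chain along the chromosome: per-SNP minor-allele frequencies uniform in
[0.05, 0.5] by default, neighbour allelic correlation `ld_rho`
(transition probabilities clipped to [0, 1], so pairs with very
unequal frequencies carry less than the nominal correlation — a
Frechet-bound limitation of Bernoulli margins, not a bug); dosage is
the sum of two independent haplotypes. Phenotypes: causal indicators
drawn from the two-level prior, effects N(0, sigma_beta^2), intercept
solved by bisection so the sample-average disease probability hits the
target prevalence (0.5 by default) within 1e-4, and y drawn
Bernoulli. Sampling is prospective; case-control ascertainment is not
simulated, matching the prospective likelihood the engine fits.
Fixture effect sds (0.4) deliberately exceed the analysis prior
sigma_a = 0.1 so that desk-scale sample sizes suffice; this mirrors the
slab-width robustness question and is intentional. What the generator
does not emulate: coalescent-realistic LD (block structure,
recombination hotspots), imputation uncertainty, genotyping error, and
population structure — so passing recovery tests demonstrates
correctness of the inference under its own assumptions, not robustness
to real-data violations of them.

## Study conditions used in the tests

The simulation studies run at n = 4,000 individuals, p = 5,000 SNPs, a
500-SNP pathway, theta0 = -3, theta = 2, effect sd 0.4, 20 seeded
replicates, for both the enriched and the no-effect (null-calibration)
studies. The inference grid in these studies spans the same support as
the defaults near the generative values (theta0 in [-4, -2], theta in
[0, 4]) at 0.5 spacing — the package's own robustness check shows
coarse and fine grids agree to < 0.5 log10 BF units, and the coarser
grid keeps the full 40-replicate suite to a few minutes.

## Known limitations

- The variational family factorizes over SNPs, so posterior
  correlations between tightly linked SNPs are not represented; PIPs
  in high-LD blocks spread support across neighbours (hence the
  segment-level statistics), and credible intervals can be modestly
  overconfident.
- Additive dosage coding only; dominant/recessive codings are not
  implemented.
- sigma_a is fixed, not estimated; sensitivity should be assessed by
  refitting at nearby values.
- The greedy combination search can miss jointly enriched pairs whose
  singles fall below the candidate threshold (BF 10 by default).
- Genotype imputation, population-structure correction and
  call-rate/HWE filters are out of scope and assumed handled upstream.
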