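"""Prioritize variants inside an enriched pathway.

Compares posterior inclusion probabilities (PIPs) under the
no-enrichment null with PIPs informed by the fitted enrichment, and
summarizes evidence over overlapping 50-SNP segments: the posterior
probability that a segment harbours at least one included SNP.
"""

import numpy as np

from pathbvs.annotate import AnnotationVector
from pathbvs.data import RunConfig
from pathbvs.enrichment import (
    HyperGrid, evaluate_pathway, hyper_posterior, scan_null,
)
from pathbvs.prioritize import averaged_pips, segment_scan
from pathbvs.simulate import simulate_genotypes, simulate_phenotype

geno = simulate_genotypes(800, 500, ld_rho=0.3, seed=2)
a = np.zeros(500, dtype=bool)
a[60:140] = True
ann = AnnotationVector(a, "true_pathway")
data, truth = simulate_phenotype(geno, ann, -2.3, 2.0, 0.6, seed=3)

cfg = RunConfig(theta0_grid=(-3.0, -2.0, 0.5), theta_grid=(0.0, 3.0, 0.5))
grid = HyperGrid.from_config(cfg)
null = scan_null(data, grid, cfg)
res = evaluate_pathway(data, ann, grid, null=null, config=cfg,
                       keep_scan=True)

w_null, _, _ = hyper_posterior(null.log_marginals, grid)
pips_null = averaged_pips(null.states, w_null.ravel())
states = [s for row in res.scan.states for s in row]
pips_enr = averaged_pips(states, res.posterior_weights.ravel())

causal_in = truth.gamma & a
print(f"mean PIP of causal pathway SNPs: "
      f"{pips_null[causal_in].mean():.3f} (null) -> "
      f"{pips_enr[causal_in].mean():.3f} (enriched)")
print(f"mean PIP of null SNPs outside:   "
      f"{pips_null[~a & ~truth.gamma].mean():.4f} (null) -> "
      f"{pips_enr[~a & ~truth.gamma].mean():.4f} (enriched)")

table = segment_scan(data.snp_map, pips_null, pips_enr)
top = table.sort_values("p_ge1_enriched", ascending=False).head(5)
print("\ntop segments by P(>=1 SNP included | enrichment):")
print(top[["start_bp", "end_bp", "p_ge1_null", "p_ge1_enriched",
           "top_snp", "top_pip"]].to_string(index=False))
print("\nEnrichment promotes variants inside the pathway (their PIPs "
      "rise) without inflating evidence elsewhere.")
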