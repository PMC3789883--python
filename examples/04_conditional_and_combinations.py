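"""Condition on a dominant region and search pathway combinations.

When one region (like the MHC in autoimmune disease) dwarfs all other
signals, candidate pathways are scored against the null that the region
alone is enriched, with the region's enrichment fixed at its MAP value.
The greedy combination search then asks whether two pathways enriched
together explain the data better than one.
"""

import numpy as np

from pathbvs.annotate import AnnotationVector
from pathbvs.data import GenotypeData, RunConfig
from pathbvs.enrichment import (
    HyperGrid, conditional_enrichment, evaluate_pathway, scan_null,
)
from pathbvs.search import greedy_combinations
from pathbvs.simulate import simulate_genotypes

rng = np.random.default_rng(4)
geno = simulate_genotypes(900, 400, ld_rho=0.2, seed=5)
beta = np.zeros(400)
beta[[5, 12, 25]] = [1.3, -1.1, 1.0]            # dominant "MHC" block
beta[[210, 225, 240, 255]] = [0.9, -0.9, 0.8, -0.8]  # pathway A
lin = geno.dosages @ beta
lin -= lin.mean()
y = (rng.random(900) < 1 / (1 + np.exp(-lin))).astype(np.int8)
data = GenotypeData(geno.dosages, geno.snp_map, y)

idx = np.arange(400)
mhc = AnnotationVector(idx < 50, "MHC")
path_a = AnnotationVector((idx >= 200) & (idx < 260), "pathway_A")
path_b = AnnotationVector((idx >= 300) & (idx < 360), "pathway_B")

cfg = RunConfig(theta0_grid=(-2.5, -2.0, 0.5), theta_grid=(0.0, 2.5, 0.5))
grid = HyperGrid.from_config(cfg)

for cand in (path_a, path_b):
    res = conditional_enrichment(data, mhc, cand, grid, config=cfg)
    print(f"{cand.label:>10} | {res.null_reference}: "
          f"log10 BF = {res.log10_bf:6.2f}")

null = scan_null(data, grid, cfg)


def score(ann):
    return evaluate_pathway(data, ann, grid, null=null,
                            config=cfg).log10_bf


singles = [(a.label, a, score(a)) for a in (mhc, path_a, path_b)]
stages = greedy_combinations(singles, score, threshold=10.0, depth=2)
print("\ngreedy pairs (BFs against the no-enrichment null):")
for c in stages[2]:
    print(f"  {'+'.join(c.set_ids):>20}: log10 BF = {c.log10_bf:6.2f} "
          f"(+{c.n_new_snps} SNPs)")
print("\nOnly pathway_A carries real signal beyond the MHC, so its "
      "conditional BF is large while pathway_B's sits near zero.")
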