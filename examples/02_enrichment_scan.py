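"""Score candidate pathways for enrichment of disease associations.

Simulates a study in which one 80-SNP gene set is truly enriched
(theta0=-2.3, theta=2: about 1 in 200 background SNPs and 1 in 3
pathway SNPs carry effects), then computes the Bayes factor for that
set and for a decoy, averaging the spike-and-slab variational bound
over the (theta0, theta) grid.
"""

import numpy as np

from pathbvs.annotate import AnnotationVector
from pathbvs.data import RunConfig
from pathbvs.enrichment import (
    HyperGrid, evaluate_pathway, posterior_odds, scan_null,
)
from pathbvs.simulate import simulate_genotypes, simulate_phenotype

geno = simulate_genotypes(800, 500, ld_rho=0.3, seed=2)
a_true = np.zeros(500, dtype=bool)
a_true[60:140] = True
ann_true = AnnotationVector(a_true, "true_pathway")
data, truth = simulate_phenotype(geno, ann_true, -2.3, 2.0,
                                 sigma_beta=0.6, seed=3)

cfg = RunConfig(theta0_grid=(-3.0, -2.0, 0.25), theta_grid=(0.0, 3.0, 0.25))
grid = HyperGrid.from_config(cfg)
null = scan_null(data, grid, cfg)

a_decoy = np.zeros(500, dtype=bool)
a_decoy[300:380] = True
for ann in (ann_true, AnnotationVector(a_decoy, "decoy_pathway")):
    res = evaluate_pathway(data, ann, grid, null=null, config=cfg)
    t = res.theta_summary
    print(f"{ann.label:>14}: log10 BF = {res.log10_bf:6.2f}   "
          f"theta = {t['mean']:.2f} [{t['ci95_lo']:.1f}, "
          f"{t['ci95_hi']:.1f}]   "
          f"P(enriched | 1:100 prior) = "
          f"{posterior_odds(res.log10_bf, 1 / 100):.3f}")

print("\nA log10 BF around 0 means the data do not favour enrichment; "
      "the true pathway should score decisively higher than the decoy, "
      "with its credible interval near the generative theta = 2.")
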