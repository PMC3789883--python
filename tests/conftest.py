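"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pandas as pd
import pytest

from pathbvs.data import GenotypeData, SnpMap
from pathbvs.simulate import simulate_genotypes, simulate_phenotype


def make_snp_map(positions, chromosome="1", start_id=1):
    n = len(positions)
    return SnpMap(pd.DataFrame({
        "snp_id": [f"snp{start_id + i}" for i in range(n)],
        "chromosome": chromosome if isinstance(chromosome, list)
        else [chromosome] * n,
        "position": list(positions),
    }))


@pytest.fixture(scope="session")
def toy_logistic():
    """Small case-control dataset with two real effects (n=200, p=30)."""
    geno = simulate_genotypes(200, 30, ld_rho=0.2, seed=11)
    beta = np.zeros(30)
    beta[4], beta[17] = 0.9, -0.8
    rng = np.random.default_rng(12)
    lin = 0.1 + geno.dosages @ beta
    y = (rng.random(200) < 1 / (1 + np.exp(-lin))).astype(np.int8)
    return GenotypeData(geno.dosages, geno.snp_map, y)


@pytest.fixture(scope="session")
def small_enriched_sim():
    """A modest enriched simulation shared by several behavioural tests.

    p=400 SNPs, 80-SNP pathway, theta0=-2.3, theta=2, effect sd 0.6 —
    small enough for second-scale grid scans.
    """
    from pathbvs.annotate import AnnotationVector

    geno = simulate_genotypes(600, 400, ld_rho=0.3, seed=21)
    a = np.zeros(400, dtype=bool)
    a[40:120] = True
    ann = AnnotationVector(a, "true_pathway")
    data, truth = simulate_phenotype(geno, ann, -2.3, 2.0, 0.6, seed=22)
    return data, ann, truth
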