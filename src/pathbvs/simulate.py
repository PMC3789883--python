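"""Synthetic GWAS generator with the exact structure the model assumes.

Genotypes are biallelic dosages built from pairs of haplotypes drawn from
a first-order Markov chain along the chromosome, giving local linkage
disequilibrium with tunable neighbour correlation.  Phenotypes follow the
sparse additive log-odds disease model: inclusion indicators drawn from
the two-level prior (genome-wide log-odds theta0, log-fold enrichment
theta inside an annotated pathway), normal effects for included SNPs, and
an intercept solved so the sample-average disease probability matches a
target prevalence.  Sampling is prospective — case-control ascertainment
is not simulated — which matches the prospective likelihood the engine
fits.  Ground truth is recorded for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .annotate import AnnotationVector
from .data import GeneTable, GenotypeData, SnpMap
from .enrichment import prior_inclusion

__all__ = [
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotype",
    "make_test_fixture",
]


@dataclass
class SimTruth:
    """Ground truth of one simulated phenotype draw."""

    gamma: np.ndarray            # bool causal indicators
    beta: np.ndarray             # effects (0 where gamma is False)
    theta0_true: float
    theta_true: float
    intercept: float
    annotation: AnnotationVector | None

    def __post_init__(self) -> None:
        if np.any(self.beta[~self.gamma] != 0):
            raise ValueError("beta must be zero wherever gamma is zero")

    def to_frame(self, snp_map: SnpMap) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": snp_map.snp_ids,
            "gamma": self.gamma.astype(int),
            "beta": self.beta,
        })


def simulate_genotypes(
    n: int,
    p: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    ld_rho: float = 0.0,
    seed: int = 1,
    spacing_bp: int = 5_000,
    chromosome: str = "1",
) -> GenotypeData:
    """Dosage matrix from Markov haplotypes with local LD.

    Each individual is the sum of two independent haplotypes; along a
    haplotype, allele j is Bernoulli with marginal frequency f_j drawn
    uniform in [maf_low, maf_high] and correlation ``ld_rho`` with the
    neighbouring allele.  SNPs sit every ``spacing_bp`` basepairs on one
    chromosome.  Deterministic given ``seed``.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if not (0 <= ld_rho < 1):
        raise ValueError("require 0 <= ld_rho < 1")
    rng = np.random.default_rng(seed)
    f = rng.uniform(maf_low, maf_high, size=p)
    H = np.empty((2 * n, p), dtype=np.int8)
    H[:, 0] = rng.random(2 * n) < f[0]
    sd = np.sqrt(f * (1.0 - f))
    for j in range(1, p):
        prob = f[j] + ld_rho * (sd[j] / sd[j - 1]) * (H[:, j - 1] - f[j - 1])
        np.clip(prob, 0.0, 1.0, out=prob)
        H[:, j] = rng.random(2 * n) < prob
    X = (H[:n] + H[n:]).astype(np.float64)
    snp_map = SnpMap(pd.DataFrame({
        "snp_id": [f"snp{j + 1}" for j in range(p)],
        "chromosome": chromosome,
        "position": spacing_bp * (np.arange(p) + 1),
    }))
    return GenotypeData(dosages=X, snp_map=snp_map, phenotype=None)


def _solve_intercept(logits_x: np.ndarray, prevalence: float,
                     tol: float = 1e-4) -> float:
    """Bisection for kappa s.t. mean sigmoid(kappa + logits_x) = prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = float(expit(mid + logits_x).mean())
        if abs(val - prevalence) <= tol:
            return mid
        if val < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_phenotype(
    geno: GenotypeData,
    annotation: AnnotationVector | None,
    theta0: float,
    theta: float = 0.0,
    sigma_beta: float = 0.4,
    prevalence_target: float = 0.5,
    seed: int = 1,
) -> tuple[GenotypeData, SimTruth]:
    """Draw a binary phenotype from the sparse log-odds disease model.

    gamma_j ~ Bernoulli of the two-level prior at (theta0, theta, a_j);
    beta_j | gamma_j=1 ~ N(0, sigma_beta^2); the intercept is solved by
    bisection so the sample-average disease probability equals
    ``prevalence_target`` within 1e-4; y_i ~ Bernoulli(sigmoid(kappa +
    x_i'beta)).  Raises if no causal SNP is drawn in 100 attempts.
    """
    if not (0 < prevalence_target < 1):
        raise ValueError("prevalence_target must lie in (0,1)")
    rng = np.random.default_rng(seed)
    p = geno.p
    a = annotation.a.astype(float) if annotation is not None \
        else np.zeros(p)
    pi = prior_inclusion(theta0, theta, a)
    gamma = None
    for _ in range(100):
        g = rng.random(p) < pi
        if g.any():
            gamma = g
            break
    if gamma is None:
        raise RuntimeError(
            "no causal SNP drawn in 100 attempts; raise theta0 or p"
        )
    beta = np.zeros(p)
    beta[gamma] = rng.normal(0.0, sigma_beta, size=int(gamma.sum()))
    logits_x = geno.dosages @ beta
    kappa = _solve_intercept(logits_x, prevalence_target)
    y = (rng.random(geno.n) < expit(kappa + logits_x)).astype(np.int8)
    data = GenotypeData(dosages=geno.dosages, snp_map=geno.snp_map,
                        phenotype=y)
    truth = SimTruth(
        gamma=gamma, beta=beta, theta0_true=theta0, theta_true=theta,
        intercept=kappa, annotation=annotation,
    )
    return data, truth


# ---------------------------------------------------------------------------
# Named fixture bundles

_SCENARIOS = ("null", "single-enriched", "two-enriched", "mhc-plus-pathway")


def _fixture_genes(snp_map: SnpMap, snps_per_gene: int = 10) -> GeneTable:
    """Tile consecutive SNPs into synthetic genes spanning their positions."""
    pos = snp_map.positions
    chrom = snp_map.chromosomes
    rows = []
    g = 0
    for start in range(0, snp_map.n_snps, snps_per_gene):
        end = min(start + snps_per_gene - 1, snp_map.n_snps - 1)
        rows.append({
            "gene_id": f"G{g + 1}",
            "chromosome": chrom[start],
            "start": int(pos[start]),
            "end": int(pos[end]),
        })
        g += 1
    return GeneTable(pd.DataFrame(rows))


def make_test_fixture(
    name: str,
    out_dir: str | Path,
    n: int = 400,
    p: int = 300,
    seed: int = 1,
    sigma_beta: float = 0.4,
) -> dict:
    """Write a named synthetic scenario bundle to disk.

    Files: dosages.txt, snps.map, pheno.txt, genes.bed, sets.gmt,
    truth.tsv, scenario.yaml.  Scenarios: "null" (theta = 0),
    "single-enriched" (one gene set covering the causal-enriched block),
    "two-enriched" (two disjoint enriched sets), "mhc-plus-pathway"
    (a large-effect region plus an enriched pathway elsewhere).
    Returns the paths plus the in-memory objects.
    """
    from . import io as pio
    from .annotate import build_annotation

    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from "
                         f"{_SCENARIOS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    geno = simulate_genotypes(n, p, ld_rho=0.3, seed=seed)
    genes = _fixture_genes(geno.snp_map)
    n_genes = len(genes.table)
    if n_genes < 5:
        raise ValueError("fixture needs at least 50 SNPs (5 genes)")
    ids = list(genes.gene_ids)
    k = max(1, n_genes // 6)  # genes per set; disjoint thirds of the map
    blocks = {
        "S_true": ids[:k],
        "S_second": ids[n_genes // 3:n_genes // 3 + k],
        "S_decoy": ids[2 * n_genes // 3:2 * n_genes // 3 + k],
    }
    gmt_path = out / "sets.gmt"
    with open(gmt_path, "w") as fh:
        for sid, gg in blocks.items():
            fh.write("\t".join([sid, "synthetic", *gg]) + "\n")
    sets = pio.read_gmt(gmt_path)

    def ann_for(set_ids):
        return build_annotation(geno.snp_map, genes, sets, set_ids,
                                window_bp=0)

    theta0, theta = -2.3, 1.5
    if name == "null":
        # no effects at all: y is a fair coin, independent of X
        annotation = None
        rng = np.random.default_rng(seed + 1)
        y = (rng.random(n) < 0.5).astype(np.int8)
        data = GenotypeData(geno.dosages, geno.snp_map, y)
        truth = SimTruth(np.zeros(p, bool), np.zeros(p), theta0, 0.0,
                         0.0, None)
    elif name == "single-enriched":
        annotation = ann_for(["S_true"])
        data, truth = simulate_phenotype(
            geno, annotation, theta0, theta, sigma_beta, seed=seed + 1,
        )
    elif name == "two-enriched":
        annotation = ann_for(["S_true", "S_second"])
        data, truth = simulate_phenotype(
            geno, annotation, theta0, theta, sigma_beta, seed=seed + 1,
        )
    else:  # mhc-plus-pathway
        from .annotate import RegionSpec, region_annotation
        region = RegionSpec("1", 1, int(geno.snp_map.positions[49]))
        mhc = region_annotation(geno.snp_map, region, label="MHC")
        pathway = ann_for(["S_second"])
        combined = mhc.union(pathway)
        data, truth = simulate_phenotype(
            geno, combined, theta0, theta, sigma_beta, seed=seed + 1,
        )
        annotation = combined

    paths = {
        "dosages": out / "dosages.txt",
        "map": out / "snps.map",
        "pheno": out / "pheno.txt",
        "genes": out / "genes.bed",
        "gmt": gmt_path,
        "truth": out / "truth.tsv",
    }
    pio.write_genotypes(data, paths["dosages"], paths["map"], paths["pheno"])
    pio.write_bed_genes(genes, paths["genes"])
    tdf = truth.to_frame(geno.snp_map)
    tdf.insert(0, "scenario", name)
    tdf["theta0_true"] = truth.theta0_true
    tdf["theta_true"] = truth.theta_true
    tdf["intercept"] = truth.intercept
    tdf.to_csv(paths["truth"], sep="\t", index=False)
    return {
        "paths": paths,
        "data": data,
        "genes": genes,
        "sets": sets,
        "annotation": annotation,
        "truth": truth,
    }
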