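"""Core in-memory containers for the enrichment analysis.

Genotypes are minor-allele dosages in [0, 2] (observed counts or imputed
expectations), phenotypes are binary case/control labels, and SNPs carry a
map of (id, chromosome, 1-based position). All internal genomic coordinates
are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SnpMap",
    "GenotypeData",
    "GeneTable",
    "GeneSetCollection",
    "RunConfig",
]


@dataclass(frozen=True)
class SnpMap:
    """Per-SNP map: identifier, chromosome and 1-based basepair position.

    Positions must be sorted (strictly increasing within chromosome) and
    identifiers unique; :meth:`validate` enforces both.
    """

    table: pd.DataFrame  # columns: snp_id, chromosome, position

    REQUIRED = ("snp_id", "chromosome", "position")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"SNP map missing columns: {missing}")

    def validate(self) -> "SnpMap":
        t = self.table
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate SNP identifier: {dup!r}")
        for chrom, grp in t.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        return self

    def sort(self) -> "SnpMap":
        """Return a copy sorted by (chromosome, position)."""
        t = (
            self.table.sort_values(["chromosome", "position"], kind="stable")
            .reset_index(drop=True)
        )
        return SnpMap(t)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy()


@dataclass
class GenotypeData:
    """Dosage matrix plus phenotype and SNP map; the regression design.

    ``dosages`` is n x p with entries in [0, 2] and no missing values
    (mean-fill is applied at load time).  ``phenotype`` is a length-n
    0/1 vector (1 = case), or None for genotype-only bundles.
    """

    dosages: np.ndarray
    snp_map: SnpMap
    phenotype: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-dimensional")
        if self.dosages.shape[1] != self.snp_map.n_snps:
            raise ValueError(
                f"dosage matrix has {self.dosages.shape[1]} columns but SNP "
                f"map has {self.snp_map.n_snps} rows"
            )
        if self.phenotype is not None:
            y = np.asarray(self.phenotype)
            if y.shape != (self.dosages.shape[0],):
                raise ValueError(
                    f"phenotype length {y.shape} does not match "
                    f"{self.dosages.shape[0]} individuals"
                )
            vals = np.unique(y)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError(f"phenotype labels must be 0/1, got {vals}")
            self.phenotype = y.astype(np.int8)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    def require_phenotype(self) -> np.ndarray:
        if self.phenotype is None:
            raise ValueError("operation requires a phenotype")
        y = self.phenotype
        if len(np.unique(y)) < 2:
            raise ValueError("phenotype must contain both cases and controls")
        return y

    def subset_snps(self, idx: np.ndarray) -> "GenotypeData":
        idx = np.asarray(idx)
        return GenotypeData(
            dosages=self.dosages[:, idx],
            snp_map=SnpMap(self.snp_map.table.iloc[idx].reset_index(drop=True)),
            phenotype=self.phenotype,
        )


@dataclass(frozen=True)
class GeneTable:
    """Gene coordinates, 1-based inclusive over the transcribed region."""

    table: pd.DataFrame  # columns: gene_id, chromosome, start, end

    REQUIRED = ("gene_id", "chromosome", "start", "end")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        t = self.table
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if (t["end"] < t["start"]).any():
            bad = t.loc[t["end"] < t["start"], "gene_id"].iloc[0]
            raise ValueError(f"gene {bad!r} has end < start")

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table["gene_id"].to_numpy()

    def row(self, gene_id: str) -> pd.Series:
        hit = self.table[self.table["gene_id"] == gene_id]
        if hit.empty:
            raise KeyError(gene_id)
        return hit.iloc[0]


@dataclass(frozen=True)
class GeneSet:
    name: str
    source: str
    gene_ids: tuple[str, ...]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (pathways); keys are unique set identifiers."""

    sets: Mapping[str, GeneSet]

    def __post_init__(self) -> None:
        for sid, gs in self.sets.items():
            if not gs.gene_ids:
                raise ValueError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __iter__(self):
        return iter(self.sets)

    def genes(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id].gene_ids


@dataclass
class RunConfig:
    """Tunable analysis parameters.

    sigma_a
        Prior standard deviation of the non-zero log-odds ratios (the
        "slab"); 0.1 places 95% of odds ratios a priori in (0.82, 1.22).
    theta0_grid, theta_grid
        [lo, hi, step] for the genome-wide log-odds theta0 and the
        log-fold enrichment theta, both on the base-10 log-odds scale.
    segment_size, segment_overlap
        Genome scan windows: 50-SNP segments overlapping by 25 SNPs.
    gene_window_bp
        A SNP is assigned to a gene when within this distance of the
        transcribed region (100 kb).
    bf_candidate_threshold
        Single-pathway BF above which a pathway enters the greedy
        multi-pathway search (10).
    prior_odds_enrichment
        Prior odds used to turn a BF into a posterior probability of
        enrichment; None means 1/(number of candidates) at use time.
    """

    sigma_a: float = 0.1
    theta0_grid: tuple[float, float, float] = (-6.0, -2.0, 0.1)
    theta_grid: tuple[float, float, float] = (0.0, 5.0, 0.1)
    segment_size: int = 50
    segment_overlap: int = 25
    gene_window_bp: int = 100_000
    bf_candidate_threshold: float = 10.0
    prior_odds_enrichment: float | None = None
    convergence_tol: float = 1e-4
    max_outer_iter: int = 10_000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sigma_a <= 0:
            raise ValueError("sigma_a must be positive")
        for name in ("theta0_grid", "theta_grid"):
            lo, hi, step = getattr(self, name)
            if step <= 0 or hi < lo:
                raise ValueError(f"{name} must satisfy lo <= hi, step > 0")
        if not (0 <= self.segment_overlap < self.segment_size):
            raise ValueError("require 0 <= segment_overlap < segment_size")

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def grid_values(spec: tuple[float, float, float]) -> np.ndarray:
    """Expand a [lo, hi, step] specification into an inclusive grid."""
    lo, hi, step = spec
    n = int(round((hi - lo) / step)) + 1
    vals = lo + step * np.arange(n)
    return np.round(vals, 10)
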