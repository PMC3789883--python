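"""SNP-to-gene and gene-to-pathway annotation.

A SNP is assigned to a gene when it lies within ``window_bp`` (default
100 kb) of the gene's transcribed region, inclusive at both boundaries.
A pathway annotation vector marks every SNP assigned to at least one
member gene; unions over several pathways are elementwise OR.  Genomic
intervals (e.g. the MHC and extended MHC on chromosome 6) can also be
used directly as annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GeneSetCollection, GeneTable, SnpMap

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationVector",
    "RegionSpec",
    "snps_near_gene",
    "build_annotation",
    "region_annotation",
    "write_annotation",
]


@dataclass(frozen=True)
class AnnotationVector:
    """Boolean per-SNP membership in a (set of) enriched pathway(s)."""

    a: np.ndarray  # bool, length p
    label: str
    source_sets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=bool))
        if self.a.ndim != 1:
            raise ValueError("annotation must be a 1-d boolean vector")

    @property
    def n_snps_in(self) -> int:
        return int(self.a.sum())

    def union(self, other: "AnnotationVector", label: str | None = None
              ) -> "AnnotationVector":
        if self.a.shape != other.a.shape:
            raise ValueError("annotation lengths differ")
        return AnnotationVector(
            a=self.a | other.a,
            label=label or f"{self.label}+{other.label}",
            source_sets=tuple(dict.fromkeys(self.source_sets + other.source_sets)),
        )


@dataclass(frozen=True)
class RegionSpec:
    """A genomic interval, 1-based inclusive."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")


def snps_near_gene(snp_map: SnpMap, gene: pd.Series, window_bp: int
                   ) -> np.ndarray:
    """Indices of SNPs within ``window_bp`` of the gene's transcribed region.

    Both boundaries are inclusive: a SNP exactly ``window_bp`` away is in.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    lo = gene["start"] - window_bp
    hi = gene["end"] + window_bp
    mask = (
        (snp_map.chromosomes == gene["chromosome"])
        & (snp_map.positions >= lo)
        & (snp_map.positions <= hi)
    )
    return np.flatnonzero(mask)


def build_annotation(
    snp_map: SnpMap,
    genes: GeneTable,
    sets: GeneSetCollection,
    set_ids: list[str] | tuple[str, ...],
    window_bp: int = 100_000,
) -> AnnotationVector:
    """Annotation vector for the union of one or more gene sets.

    a_j = 1 iff SNP j is within the window of at least one member gene of
    at least one of the named sets.  Genes without coordinates are skipped
    with a warning; an annotation with no member SNPs is an error.
    """
    a = np.zeros(snp_map.n_snps, dtype=bool)
    known = set(genes.gene_ids)
    for sid in set_ids:
        if sid not in sets.sets:
            raise KeyError(f"unknown gene set {sid!r}")
        missing = [g for g in sets.genes(sid) if g not in known]
        if missing:
            logger.warning(
                "set %s: %d gene(s) lack coordinates and are skipped: %s",
                sid, len(missing), ", ".join(missing[:5]),
            )
        for g in sets.genes(sid):
            if g in known:
                a[snps_near_gene(snp_map, genes.row(g), window_bp)] = True
    if not a.any():
        raise ValueError(
            f"annotation for {list(set_ids)} contains no SNPs; "
            "enrichment model would be unusable"
        )
    return AnnotationVector(a=a, label="+".join(set_ids),
                            source_sets=tuple(set_ids))


def region_annotation(snp_map: SnpMap, region: RegionSpec,
                      label: str | None = None) -> AnnotationVector:
    """Annotation of all SNPs inside a genomic interval (e.g. the MHC)."""
    a = (
        (snp_map.chromosomes == region.chromosome)
        & (snp_map.positions >= region.start)
        & (snp_map.positions <= region.end)
    )
    if not a.any():
        raise ValueError(
            f"region {region.chromosome}:{region.start}-{region.end} "
            "contains no SNPs"
        )
    return AnnotationVector(
        a=a,
        label=label or f"{region.chromosome}:{region.start}-{region.end}",
        source_sets=(),
    )


def write_annotation(ann: AnnotationVector, snp_map: SnpMap,
                     path: str | Path) -> None:
    pd.DataFrame(
        {"snp_id": snp_map.snp_ids, "a": ann.a.astype(int)}
    ).to_csv(path, sep="\t", index=False)
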