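"""Data-hygiene computations applied before analysis.

Two filters: removal of monomorphic SNPs (no dosage variation in the
sample), and an advisory flag for SNPs whose large single-SNP Bayes
factor has no support from neighbouring SNPs — the signature of a
genotyping artifact rather than a real association, which in practice
calls for inspection rather than automatic removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeData
from .engine import single_snp_bf

logger = logging.getLogger(__name__)

__all__ = ["drop_monomorphic", "neighborhood_support_filter", "QCReport"]


@dataclass
class QCReport:
    table: pd.DataFrame  # snp_id, reason, statistic

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def drop_monomorphic(data: GenotypeData) -> tuple[GenotypeData, QCReport]:
    """Remove SNPs that exhibit no dosage variation in the sample."""
    var = data.dosages.var(axis=0)
    keep = var > 0.0
    if not keep.any():
        raise ValueError("all SNPs are monomorphic; nothing to analyse")
    dropped = np.flatnonzero(~keep)
    report = QCReport(pd.DataFrame({
        "snp_id": data.snp_map.snp_ids[dropped],
        "reason": "monomorphic",
        "statistic": var[dropped],
    }))
    if dropped.size:
        logger.info("dropping %d monomorphic SNP(s)", dropped.size)
    return data.subset_snps(np.flatnonzero(keep)), report


def neighborhood_support_filter(
    data: GenotypeData,
    bf_threshold: float = 1e4,
    support_ratio: float = 0.01,
    window_bp: int = 200_000,
    sigma: float = 0.1,
    single_bfs: np.ndarray | None = None,
) -> QCReport:
    """Flag isolated strong single-SNP associations.

    A SNP is flagged when its single-SNP BF exceeds ``bf_threshold``
    while no other SNP within ``window_bp`` on the same chromosome
    reaches ``support_ratio * bf_threshold``.  Flags are advisory: real
    associations in regions of linkage disequilibrium are echoed by
    neighbours, whereas genotyping errors are not, but the judgment call
    on removal is left to the analyst.
    """
    y = data.require_phenotype()
    if single_bfs is None:
        single_bfs = np.array([
            single_snp_bf(data.dosages[:, j], y, sigma)
            if np.ptp(data.dosages[:, j]) > 0 else 1.0
            for j in range(data.p)
        ])
    else:
        single_bfs = np.asarray(single_bfs, dtype=np.float64)
    chroms = data.snp_map.chromosomes
    pos = data.snp_map.positions
    support_bar = support_ratio * bf_threshold
    rows = []
    for j in np.flatnonzero(single_bfs > bf_threshold):
        near = (
            (chroms == chroms[j])
            & (np.abs(pos - pos[j]) <= window_bp)
        )
        near[j] = False
        max_neighbor = single_bfs[near].max() if near.any() else 0.0
        if max_neighbor < support_bar:
            rows.append({
                "snp_id": data.snp_map.snp_ids[j],
                "reason": "unsupported_single_snp_bf",
                "statistic": single_bfs[j],
                "max_neighbor_bf": max_neighbor,
            })
    table = pd.DataFrame(
        rows, columns=["snp_id", "reason", "statistic", "max_neighbor_bf"]
    )
    return QCReport(table)
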