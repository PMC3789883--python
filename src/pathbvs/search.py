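"""Greedy interrogation of multi-pathway enrichment models.

Exhaustive evaluation of pathway pairs and triples is impractical, so the
search is greedy: take the single pathway with the largest Bayes factor,
combine it (by OR of annotations, one shared enrichment level) with every
candidate whose single-pathway BF exceeds a threshold (default 10), keep
the best pair, and repeat once more for triples.  All BFs are against the
same no-enrichment null so they are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .annotate import AnnotationVector

logger = logging.getLogger(__name__)

__all__ = ["CombinationResult", "greedy_combinations"]


@dataclass
class CombinationResult:
    set_ids: tuple[str, ...]
    log10_bf: float
    n_new_snps: int
    n_new_genes: int | None
    parent: tuple[str, ...] | None
    annotation: AnnotationVector


def _pick_winner(results: Sequence) -> object:
    """Largest BF; ties broken by fewer SNPs (more parsimonious)."""
    def key(r):
        n = r.annotation.n_snps_in
        return (-r.log10_bf, n)
    return min(results, key=key)


def greedy_combinations(
    singles: Sequence,
    score_fn: Callable[[AnnotationVector], float],
    threshold: float = 10.0,
    depth: int = 3,
    genes_by_set: dict[str, set] | None = None,
) -> dict[int, list[CombinationResult]]:
    """Evaluate pathway pairs (and triples) seeded by the single-pathway
    ranking.

    Parameters
    ----------
    singles
        Scored single pathways: objects with ``set_ids`` (or a set id via
        ``source_sets``/``label``), ``log10_bf`` and ``annotation``.
        Accepts tuples ``(set_id, annotation, log10_bf)`` as well.
    score_fn
        Callable scoring a (union) annotation against the same null as
        the singles, returning log10 BF.
    threshold
        Candidates must have single-pathway BF > threshold (on the BF
        scale, not log10) to enter a combination stage.
    depth
        2 evaluates pairs; 3 also evaluates triples built on the top pair.
    genes_by_set
        Optional set_id -> set of gene ids, enabling the incremental gene
        counts alongside incremental SNP counts.

    Returns a mapping stage depth -> list of CombinationResult (stage 1
    echoes the singles).
    """
    if depth not in (2, 3):
        raise ValueError("depth must be 2 or 3")

    stage1: list[CombinationResult] = []
    for item in singles:
        if isinstance(item, tuple):
            sid, ann, bf = item
        else:
            sid = item.source_sets[0] if getattr(item, "source_sets", None) \
                else item.label
            ann, bf = item.annotation, item.log10_bf
        genes = genes_by_set.get(sid) if genes_by_set else None
        stage1.append(CombinationResult(
            set_ids=(sid,),
            log10_bf=float(bf),
            n_new_snps=ann.n_snps_in,
            n_new_genes=len(genes) if genes is not None else None,
            parent=None,
            annotation=ann,
        ))

    log10_thr = np.log10(threshold)
    candidates = [r for r in stage1 if r.log10_bf > log10_thr]
    out: dict[int, list[CombinationResult]] = {1: stage1}
    if not candidates:
        logger.warning("no candidate pathway has BF > %g; search is empty",
                       threshold)
        out[2] = []
        if depth == 3:
            out[3] = []
        return out

    winner = _pick_winner(stage1)
    for d in range(2, depth + 1):
        stage: list[CombinationResult] = []
        covered_genes: set = set()
        if genes_by_set:
            for sid in winner.set_ids:
                covered_genes |= genes_by_set.get(sid, set())
        for cand in candidates:
            sid = cand.set_ids[0]
            if sid in winner.set_ids:
                continue
            union = winner.annotation.union(cand.annotation)
            n_new = int((cand.annotation.a & ~winner.annotation.a).sum())
            n_new_genes = None
            if genes_by_set:
                n_new_genes = len(genes_by_set.get(sid, set())
                                  - covered_genes)
            bf = float(score_fn(union))
            stage.append(CombinationResult(
                set_ids=winner.set_ids + (sid,),
                log10_bf=bf,
                n_new_snps=n_new,
                n_new_genes=n_new_genes,
                parent=winner.set_ids,
                annotation=union,
            ))
        out[d] = stage
        if not stage:
            logger.warning("stage %d evaluated no combinations", d)
            if d < depth:
                out[d + 1] = []
            break
        winner = _pick_winner(stage)
    return out
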